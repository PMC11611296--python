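"""State populations and relative free energies.

Populations come either from frame-count occupancy of the idealized paths
(the default: the same model as the kinetics, so P and tau are internally
consistent) or from a Gaussian-mixture fit of the pooled FRET histogram.  A
population ratio converts to a relative free energy via

    ddG_ab = -R * T * ln(P_b / P_a)

with state a the control (reference) and state b the observed state: a
positive ddG means b is less populated, hence less stable, than a.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .hmm import HMMResults, IdealizedPath
from .traces import FRETTrace

__all__ = [
    "PopulationEstimate",
    "FreeEnergyResult",
    "R_KCAL_PER_MOL_K",
    "R_KJ_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "fret_histogram",
    "state_populations",
    "fit_gaussian_mixture",
    "delta_delta_g",
    "normalized_folded_series",
]

R_KCAL_PER_MOL_K = 1.9872e-3  # kcal mol^-1 K^-1
R_KJ_PER_MOL_K = 8.31446261815324e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 293.15  # measurements at 20 C


@dataclass
class PopulationEstimate:
    """Per-state fractions for one experimental condition."""

    condition: str
    fractions: np.ndarray
    sds: np.ndarray
    method: str
    n_molecules: int
    state_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("state fractions must sum to 1")
        if not self.state_labels:
            self.state_labels = [f"state{i}" for i in range(len(self.fractions))]

    @property
    def folded_fraction(self) -> float:
        """Fraction of the highest-FRET (last, canonical order) state."""
        return float(self.fractions[-1])


@dataclass(frozen=True)
class FreeEnergyResult:
    """ddG of state b relative to control state a, with delta-method SD."""

    delta_delta_g: float
    sd: float
    temperature_k: float
    gas_constant: float
    unit: str


def fret_histogram(
    data: Sequence[FRETTrace] | Sequence[IdealizedPath] | np.ndarray,
    bin_width: float = 0.02,
    first_n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised FRET histogram over [0, 1] from all valid frames.

    ``first_n_frames`` restricts each trace to its first N valid frames (a
    common guard against photophysics late in traces).  Returns (probability
    per bin summing to 1, bin edges).
    """
    if not 0.0 < bin_width < 1.0:
        raise ValueError("bin_width must be in (0, 1)")
    values = _pool_efret(data, first_n_frames)
    if values.size == 0:
        raise ValueError("no valid frames to histogram")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(values, 0.0, 1.0), bins=edges)
    return counts / counts.sum(), edges


def _pool_efret(data, first_n_frames=None) -> np.ndarray:
    if isinstance(data, np.ndarray):
        vals = data[np.isfinite(data)]
        return vals[: first_n_frames] if first_n_frames else vals
    pooled = []
    for item in data:
        if isinstance(item, FRETTrace):
            v = item.valid_values()
        elif isinstance(item, IdealizedPath):
            v = item.fitted_mean[np.isfinite(item.fitted_mean)]
        else:
            v = np.asarray(item, dtype=float)
            v = v[np.isfinite(v)]
        if first_n_frames is not None:
            v = v[:first_n_frames]
        pooled.append(v)
    return np.concatenate(pooled) if pooled else np.empty(0)


def state_populations(
    paths: Sequence[IdealizedPath],
    model: HMMResults,
    condition: str = "",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> PopulationEstimate:
    """Occupancy populations: P_s = fraction of valid frames decoded as s.

    Uncertainty is the SD of the occupancy over bootstrap resamples of whole
    molecules (molecules, not frames, are the independent unit).
    """
    K = model.K
    per_mol = np.array(
        [np.bincount(p.valid_states(), minlength=K) for p in paths], dtype=float
    )
    totals = per_mol.sum(axis=0)
    if totals.sum() == 0:
        raise ValueError("no valid decoded frames")
    fractions = totals / totals.sum()
    rng = np.random.default_rng(seed)
    n_mol = len(paths)
    boots = np.empty((n_bootstrap, K))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_mol, size=n_mol)
        c = per_mol[idx].sum(axis=0)
        boots[b] = c / c.sum() if c.sum() > 0 else fractions
    return PopulationEstimate(
        condition=condition,
        fractions=fractions,
        sds=boots.std(axis=0),
        method="occupancy",
        n_molecules=n_mol,
    )


def fit_gaussian_mixture(
    data, K: int, seed: int = 0, condition: str = "", n_init: int = 5
) -> PopulationEstimate:
    """Histogram-free mixture populations: EM fit of K Gaussians to pooled E.

    Component weights are the population estimate; components are reported in
    canonical order of ascending mean.  Means/SDs are attached as attributes
    ``means`` / ``component_sds`` on the returned estimate.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    values = _pool_efret(data).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=K, covariance_type="full", random_state=seed, n_init=n_init
    ).fit(values)
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_[order]
    est = PopulationEstimate(
        condition=condition,
        fractions=weights / weights.sum(),
        sds=np.zeros(K),
        method="gaussian-mixture",
        n_molecules=0,
    )
    est.means = gm.means_.ravel()[order]  # type: ignore[attr-defined]
    est.component_sds = np.sqrt(gm.covariances_.reshape(K)[order])  # type: ignore[attr-defined]
    est.converged = bool(gm.converged_)  # type: ignore[attr-defined]
    return est


def delta_delta_g(
    p_a: float,
    p_b: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    sd_a: float = 0.0,
    sd_b: float = 0.0,
    unit: str = "kcal/mol",
) -> FreeEnergyResult:
    """Relative free energy ddG_ab = -R*T*ln(P_b/P_a).

    State a is the control; a positive result means state b is the less
    populated (less stable) one.  Uncertainty is propagated from the
    population SDs by the delta method (covariance between P_a and P_b is
    neglected).  Zero populations are rejected: add a pseudocount or report a
    bound instead.
    """
    if p_a <= 0 or p_b <= 0:
        raise ValueError(
            "populations must be > 0 for a finite ddG; add a pseudocount or "
            "report a one-sided bound for unobserved states"
        )
    if unit == "kcal/mol":
        R = R_KCAL_PER_MOL_K
    elif unit == "kJ/mol":
        R = R_KJ_PER_MOL_K
    else:
        raise ValueError(f"unknown unit {unit!r}")
    rt = R * temperature_k
    # log(a) - log(b) rather than log(b/a): antisymmetry is then exact in floats
    ddg = rt * (np.log(p_a) - np.log(p_b))
    sd = rt * np.hypot(sd_a / p_a, sd_b / p_b)
    return FreeEnergyResult(float(ddg), float(sd), temperature_k, R, unit)


def normalized_folded_series(
    estimates: Sequence[PopulationEstimate],
    normalization: str = "max",
    reference_index: int = 0,
) -> pd.DataFrame:
    """Folded-fraction series rescaled by a declared rule.

    normalization "max": divide the series by its maximum (max entry -> 1).
    normalization "paired_difference": (x - x_ref) / x_ref against the entry
    at ``reference_index`` (constant series -> all zeros).  The rule used is
    recorded in the table's ``attrs["normalization"]``.
    """
    folded = np.array([e.folded_fraction for e in estimates], dtype=float)
    conditions = [e.condition for e in estimates]
    if normalization == "max":
        ref = folded.max()
        if ref == 0:
            raise ValueError("cannot normalise: series maximum is zero")
        norm = folded / ref
    elif normalization == "paired_difference":
        ref = folded[reference_index]
        if ref == 0:
            raise ValueError("cannot normalise: reference entry is zero")
        norm = (folded - ref) / ref
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    out = pd.DataFrame(
        {"condition": conditions, "folded_fraction": folded, "normalized": norm}
    )
    out.attrs["normalization"] = normalization
    return out
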