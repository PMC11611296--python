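"""Ligand titration fitting and the co-transcriptional window summary.

Two response models are fitted to titration tables by nonlinear least
squares on a log-concentration axis:

* Hill:      response = floor + (ceiling - floor) * c^n / (c^n + EC50^n)
* one-site:  the same with n fixed at 1 (a hyperbolic binding isotherm,
             midpoint reported as K_d)

Replicates enter the loss individually.  The optimiser is multi-started over
a grid of log-spaced midpoint seeds spanning the tested concentration range,
so the reported optimum does not depend on a single starting guess; standard
errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .thermo import PopulationEstimate

__all__ = [
    "TitrationTable",
    "DoseResponseFit",
    "WindowSummary",
    "HillModel",
    "fit_hill",
    "fit_binding",
    "summarize_transcription_window",
    "readthrough_fraction",
]


@dataclass
class TitrationTable:
    """Tidy titration data: concentration, unit, replicate, response."""

    table: pd.DataFrame
    condition: dict | None = None

    def __post_init__(self) -> None:
        required = {"concentration", "replicate", "response"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"titration table missing columns {sorted(missing)}")
        c = self.table["concentration"].to_numpy(dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if len(np.unique(c)) < 4:
            raise ValueError("need >= 4 distinct concentrations to fit")

    @property
    def concentrations(self) -> np.ndarray:
        return self.table["concentration"].to_numpy(dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return self.table["response"].to_numpy(dtype=float)

    @property
    def unit(self) -> str:
        if "unit" in self.table.columns:
            return str(self.table["unit"].iloc[0])
        return ""

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "TitrationTable":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), **kw)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DoseResponseFit:
    """Fitted dose-response curve: midpoint (EC50 or K_d), slope, plateaus."""

    model: str  # "hill" | "one_site"
    midpoint: float
    midpoint_se: float
    hill_n: float
    hill_n_se: float
    floor: float
    floor_se: float
    ceiling: float
    ceiling_se: float
    residual_ss: float
    n_points: int
    unit: str = ""
    warning: str | None = None

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        cn = c**self.hill_n
        return self.floor + (self.ceiling - self.floor) * cn / (
            cn + self.midpoint**self.hill_n
        )

    def summary(self) -> str:
        name = "EC50" if self.model == "hill" else "K_d"
        lines = [
            f"{self.model} dose-response fit ({self.n_points} points)",
            f"  {name} = {self.midpoint:.4g} +/- {self.midpoint_se:.2g} {self.unit}",
            f"  hill_n = {self.hill_n:.3g} +/- {self.hill_n_se:.2g}",
            f"  floor = {self.floor:.4g} +/- {self.floor_se:.2g}"
            f"   ceiling = {self.ceiling:.4g} +/- {self.ceiling_se:.2g}",
            f"  residual SS = {self.residual_ss:.4g}",
        ]
        if self.warning:
            lines.append(f"  WARNING: {self.warning}")
        return "\n".join(lines)


class HillModel:
    """Hill / one-site dose-response model over a TitrationTable.

    ``fix_hill_n`` pins the slope (1.0 gives the one-site binding isotherm).
    """

    def __init__(self, table: TitrationTable, fix_hill_n: float | None = None):
        self.data = table
        self.fix_hill_n = fix_hill_n

    @staticmethod
    def _residual(params, logc, y):
        logm = params["log_midpoint"].value
        n = params["hill_n"].value
        floor = params["floor"].value
        amp = params["amplitude"].value
        pred = floor + amp / (1.0 + np.exp(n * (logm - logc)))
        return pred - y

    def fit(self, n_starts: int = 7) -> DoseResponseFit:
        c = self.data.concentrations
        y = self.data.responses
        logc = np.log(c)
        lo, hi = np.log(c.min() / 10.0), np.log(c.max() * 10.0)
        starts = np.linspace(np.log(c.min()), np.log(c.max()), n_starts)

        best = None
        for s in starts:
            params = Parameters()
            params.add("log_midpoint", value=float(s), min=lo, max=hi)
            if self.fix_hill_n is None:
                params.add("hill_n", value=1.0, min=0.1, max=10.0)
            else:
                params.add("hill_n", value=float(self.fix_hill_n), vary=False)
            params.add("floor", value=float(np.clip(y.min(), 0, 1)), min=0.0, max=1.0)
            params.add(
                "amplitude",
                value=float(np.clip(y.max() - y.min(), 1e-3, 1.0)),
                min=1e-6,
                max=1.0,
            )
            out = minimize(self._residual, params, args=(logc, y), method="leastsq")
            if best is None or out.chisqr < best.chisqr:
                best = out
        assert best is not None

        p = best.params
        midpoint = float(np.exp(p["log_midpoint"].value))
        se_logm = p["log_midpoint"].stderr or np.nan
        midpoint_se = midpoint * se_logm if np.isfinite(se_logm) else np.nan
        floor = float(p["floor"].value)
        amp = float(p["amplitude"].value)
        floor_se = p["floor"].stderr or np.nan
        amp_se = p["amplitude"].stderr or np.nan
        cov_fa = 0.0
        if best.covar is not None and p["floor"].vary and p["amplitude"].vary:
            names = [n for n in p if p[n].vary]
            try:
                i, j = names.index("floor"), names.index("amplitude")
                cov_fa = float(best.covar[i, j])
            except ValueError:
                pass
        ceiling_se = (
            float(np.sqrt(max(floor_se**2 + amp_se**2 + 2 * cov_fa, 0.0)))
            if np.isfinite(floor_se) and np.isfinite(amp_se)
            else np.nan
        )
        warning = None
        if not best.success:
            warning = "optimizer did not report convergence"
        elif not c.min() <= midpoint <= c.max():
            warning = "fitted midpoint lies outside the tested concentration range"

        return DoseResponseFit(
            model="one_site" if self.fix_hill_n == 1.0 else "hill",
            midpoint=midpoint,
            midpoint_se=midpoint_se,
            hill_n=float(p["hill_n"].value),
            hill_n_se=float(p["hill_n"].stderr or 0.0) if self.fix_hill_n is None else 0.0,
            floor=floor,
            floor_se=float(floor_se) if np.isfinite(floor_se) else np.nan,
            ceiling=floor + amp,
            ceiling_se=ceiling_se,
            residual_ss=float(best.chisqr),
            n_points=len(y),
            unit=self.data.unit,
            warning=warning,
        )


def fit_hill(table: TitrationTable, fix_hill_n: float | None = None) -> DoseResponseFit:
    """Four-parameter Hill fit (floor, ceiling, EC50, n); n optionally fixed."""
    return HillModel(table, fix_hill_n=fix_hill_n).fit()


def fit_binding(table: TitrationTable) -> DoseResponseFit:
    """One-site saturation fit; the midpoint is reported as K_d (Hill n = 1)."""
    return HillModel(table, fix_hill_n=1.0).fit()


@dataclass
class WindowSummary:
    """Folded-fraction response of halted elongation complexes vs RNA length."""

    table: pd.DataFrame
    normalization: str

    @property
    def argmax_length(self) -> int:
        """Nascent-RNA length with the largest ligand-induced increase."""
        return int(self.table.loc[self.table["increase"].idxmax(), "length"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_transcription_window(
    without_ligand: Mapping[int, PopulationEstimate],
    with_ligand: Mapping[int, PopulationEstimate],
    normalization: str = "max",
) -> WindowSummary:
    """Tabulate the ligand response of the folded state across EC lengths.

    For each nascent-RNA length the folded fraction without and with ligand,
    their absolute increase, and the increase normalised by the declared rule
    ("max": divide by the largest increase; "paired_difference": relative to
    the no-ligand fraction) are reported, along with the arg-max length.
    """
    missing = sorted(
        set(without_ligand).symmetric_difference(with_ligand)
    )
    if missing:
        raise ValueError(f"unmatched ligand conditions for lengths {missing}")
    lengths = sorted(without_ligand)
    rows = []
    for L in lengths:
        f0 = without_ligand[L].folded_fraction
        f1 = with_ligand[L].folded_fraction
        rows.append((int(L), f0, f1, f1 - f0))
    df = pd.DataFrame(rows, columns=["length", "folded_without", "folded_with", "increase"])
    if normalization == "max":
        mx = df["increase"].abs().max()
        df["normalized_increase"] = df["increase"] / mx if mx > 0 else 0.0
    elif normalization == "paired_difference":
        ref = df["folded_without"].to_numpy()
        if np.any(ref == 0):
            raise ValueError("paired_difference rule undefined: zero reference fraction")
        df["normalized_increase"] = df["increase"] / ref
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    df.attrs["normalization"] = normalization
    return WindowSummary(df, normalization)


def readthrough_fraction(terminated: float, full_length: float) -> float:
    """Read-through fraction from band intensities: FL / (FL + T)."""
    if terminated < 0 or full_length < 0:
        raise ValueError("band intensities must be nonnegative")
    total = terminated + full_length
    if total <= 0:
        raise ValueError("terminated + full_length must be > 0")
    return full_length / total
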