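"""Synthetic single-molecule FRET trajectory generation.

Emulates the dynamics of a dual-labelled riboswitch: a molecule hops among a
small number of conformational states (a continuous-time Markov chain), each
state has a characteristic FRET efficiency, and the microscope records noisy
donor/acceptor intensities on a fixed frame clock until one of the dyes
photobleaches.  Every generator stores its ground truth so that the whole
downstream analysis (idealization, kinetics, populations, dose-response) can
be validated by recovery tests without any experimental data.

Units: time in seconds, rates in s^-1, intensities in arbitrary fluorescence
units, concentrations in whatever unit the caller declares (only ratios to the
titration midpoint matter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .traces import FluorescenceTrace

__all__ = [
    "StateSpec",
    "KineticModel",
    "EmissionConfig",
    "TitrationLaw",
    "StatePath",
    "TraceSet",
    "three_state_model",
    "default_states",
    "default_emission",
    "simulate_state_path",
    "discretize_path",
    "emit_intensities",
    "simulate_ensemble",
    "simulate_titration",
    "simulate_readthrough_assay",
    "hill_response",
    "load_config",
]


@dataclass(frozen=True)
class StateSpec:
    """One conformational state and its FRET signature.

    Parameters
    ----------
    label : str
        Short name, e.g. ``"unfolded"`` / ``"pre-folded"`` / ``"folded"``.
    efret_mean : float
        Mean proximity ratio of the state, in [0, 1].
    efret_sd : float
        Molecule-to-molecule / frame-to-frame spread of the state's FRET
        value (conformational jitter), > 0.
    """

    label: str
    efret_mean: float
    efret_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efret_mean <= 1.0:
            raise ValueError(f"efret_mean must be in [0, 1], got {self.efret_mean}")
        if self.efret_sd <= 0:
            raise ValueError(f"efret_sd must be > 0, got {self.efret_sd}")


@dataclass(frozen=True)
class EmissionConfig:
    """Detection model: total brightness, additive noise, frame clock, bleaching."""

    total_intensity: float = 1000.0
    intensity_noise_sd: float = 50.0
    frame_interval: float = 0.1
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ValueError("bleach rates must be >= 0")


@dataclass(frozen=True)
class TitrationLaw:
    """Hill (or one-site, hill_n=1) law tying a response fraction to ligand concentration."""

    midpoint: float
    hill_n: float = 1.0
    floor: float = 0.0
    ceiling: float = 1.0
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValueError("midpoint must be > 0")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if not (0.0 <= self.floor < self.ceiling <= 1.0):
            raise ValueError("need 0 <= floor < ceiling <= 1")

    def response(self, concentration):
        return hill_response(
            concentration, self.midpoint, self.hill_n, self.floor, self.ceiling
        )


def hill_response(c, midpoint, hill_n, floor, ceiling):
    """floor + (ceiling-floor) * c^n / (c^n + midpoint^n)."""
    c = np.asarray(c, dtype=float)
    cn = c**hill_n
    return floor + (ceiling - floor) * cn / (cn + midpoint**hill_n)


@dataclass
class KineticModel:
    """Continuous-time Markov chain over conformational states.

    ``rate_matrix[i, j]`` (i != j) is the transition rate i -> j in s^-1;
    the diagonal holds minus the row sum so each row sums to zero.  The
    exit rate of state i is ``-rate_matrix[i, i]`` = 1/tau_i.
    """

    states: list[StateSpec]
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.rate_matrix, dtype=float)
        K = len(self.states)
        if Q.shape != (K, K):
            raise ValueError(f"rate_matrix must be {K}x{K}, got {Q.shape}")
        off = Q[~np.eye(K, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("rate_matrix rows must sum to 0")
        self.rate_matrix = Q

    @property
    def n_states(self) -> int:
        return len(self.states)

    def lifetimes(self) -> np.ndarray:
        """Expected dwell time per state, 1 / exit rate (inf for absorbing states)."""
        exit_rates = -np.diag(self.rate_matrix)
        with np.errstate(divide="ignore"):
            return np.where(exit_rates > 0, 1.0 / exit_rates, np.inf)

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalised: pi @ Q = 0, sum(pi) = 1."""
        K = self.n_states
        # solve pi Q = 0 with the normalisation row appended
        A = np.vstack([self.rate_matrix.T, np.ones(K)])
        b = np.zeros(K + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def with_folded_occupancy(
        self, target: float, folded_index: int = -1
    ) -> "KineticModel":
        """Rescale the folded state's exit (unfolding) rates so its stationary
        occupancy equals ``target``, leaving the lifetimes of every other state
        untouched.

        Slowing the unfolding rate is how a stabilising ligand is modelled
        here: occupancy of the folded state is strictly decreasing in the
        scale factor, so a 1-D root-find pins it exactly.
        """
        if not 0.0 < target < 1.0:
            raise ValueError(f"target occupancy must be in (0, 1), got {target}")
        K = self.n_states
        fidx = folded_index % K
        if -self.rate_matrix[fidx, fidx] <= 0:
            raise ValueError("folded state is absorbing; occupancy cannot be tuned")

        def occ(log_gamma: float) -> float:
            Q = self.rate_matrix.copy()
            Q[fidx, :] *= np.exp(log_gamma)
            m = replace(self, rate_matrix=Q)
            return m.stationary_distribution()[fidx] - target

        lo, hi = -35.0, 35.0
        if occ(lo) < 0 or occ(hi) > 0:
            raise ValueError("target occupancy unreachable for this rate matrix")
        root = brentq(occ, lo, hi, xtol=1e-13)
        Q = self.rate_matrix.copy()
        Q[fidx, :] *= np.exp(root)
        return replace(self, rate_matrix=Q)


@dataclass(frozen=True)
class StatePath:
    """Continuous-time trajectory: state k occupied on [entry_times[k], entry_times[k+1])."""

    states: np.ndarray  # int, segment state indices
    entry_times: np.ndarray  # float, entry_times[0] == 0
    duration: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.entry_times, t, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def dwell_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(state, duration) of every completed segment; the final (censored)
        segment runs to ``duration``."""
        ends = np.append(self.entry_times[1:], self.duration)
        return self.states, ends - self.entry_times


def simulate_state_path(
    model: KineticModel, duration: float, seed: int | np.random.Generator
) -> StatePath:
    """Exact stochastic (Gillespie) simulation of the chain over [0, duration].

    Holding time in state i is Exponential(-Q[i, i]); the next state is drawn
    with probability proportional to the off-diagonal rates of row i.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    rng = np.random.default_rng(seed)
    Q = model.rate_matrix
    K = model.n_states
    pi0 = model.stationary_distribution() if K > 1 else np.ones(1)
    state = int(rng.choice(K, p=pi0))
    states = [state]
    times = [0.0]
    t = 0.0
    while True:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:
            break  # absorbing: single segment to the end
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= exit_rate
        state = int(rng.choice(K, p=probs))
        states.append(state)
        times.append(t)
    return StatePath(np.array(states, dtype=int), np.array(times), float(duration))


def discretize_path(
    path: StatePath, frame_interval: float, n_frames: int
) -> np.ndarray:
    """Per-frame state sequence by point-sampling the state at each frame midpoint."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if path.duration < n_frames * frame_interval:
        raise ValueError(
            f"path duration {path.duration} s shorter than "
            f"{n_frames} x {frame_interval} s"
        )
    mids = (np.arange(n_frames) + 0.5) * frame_interval
    return path.state_at(mids)


def emit_intensities(
    state_seq: np.ndarray,
    states: Sequence[StateSpec],
    emission: EmissionConfig,
    seed: int | np.random.Generator,
    molecule_id: str = "mol",
) -> FluorescenceTrace:
    """Turn a per-frame state sequence into noisy donor/acceptor intensities.

    Per frame in state s: a FRET value E is drawn from Normal(mean_s, sd_s)
    truncated to [0, 1]; acceptor = I*E + noise, donor = I*(1-E) + noise.
    Dye bleach times are exponential; after acceptor bleach all excitation is
    emitted by the donor, after donor bleach both channels drop to background.
    """
    state_seq = np.asarray(state_seq, dtype=int)
    if state_seq.size == 0:
        raise ValueError("state_seq must be nonempty")
    rng = np.random.default_rng(seed)
    n = state_seq.size
    I0 = emission.total_intensity

    mu = np.array([states[s].efret_mean for s in state_seq])
    sd = np.array([states[s].efret_sd for s in state_seq])
    # truncated-normal E per frame via inverse-CDF sampling
    from scipy.stats import truncnorm

    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    efret = truncnorm.ppf(rng.uniform(size=n), a, b, loc=mu, scale=sd)

    acceptor = I0 * efret
    donor = I0 * (1.0 - efret)

    def _bleach_frame(rate: float) -> int | None:
        if rate <= 0:
            return None
        t = rng.exponential(1.0 / rate)
        f = int(np.floor(t / emission.frame_interval))
        return f if f < n else None

    bleach_a = _bleach_frame(emission.acceptor_bleach_rate)
    bleach_d = _bleach_frame(emission.donor_bleach_rate)

    if bleach_a is not None:
        acceptor[bleach_a:] = 0.0
        if bleach_d is None or bleach_d > bleach_a:
            donor[bleach_a:] = I0  # all excitation now leaves via the donor
    if bleach_d is not None:
        donor[bleach_d:] = 0.0
        acceptor[bleach_d:] = 0.0

    if emission.intensity_noise_sd > 0:
        donor = donor + rng.normal(0.0, emission.intensity_noise_sd, size=n)
        acceptor = acceptor + rng.normal(0.0, emission.intensity_noise_sd, size=n)

    time = np.arange(n) * emission.frame_interval
    return FluorescenceTrace(
        molecule_id=molecule_id,
        time=time,
        donor=donor,
        acceptor=acceptor,
        bleach_frame_donor=bleach_d,
        bleach_frame_acceptor=bleach_a,
    )


@dataclass
class TraceRecord:
    """One simulated molecule with its ground truth."""

    trace: FluorescenceTrace
    path: StatePath
    state_seq: np.ndarray


@dataclass
class TraceSet:
    """Ensemble of simulated molecules under one condition."""

    records: list[TraceRecord]
    model: KineticModel
    emission: EmissionConfig
    condition: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def traces(self) -> list[FluorescenceTrace]:
        return [r.trace for r in self.records]

    def true_state_seqs(self) -> list[np.ndarray]:
        return [r.state_seq for r in self.records]

    def true_occupancy(self) -> np.ndarray:
        """Frame-weighted ground-truth state fractions over the ensemble."""
        counts = np.zeros(self.model.n_states)
        for r in self.records:
            counts += np.bincount(r.state_seq, minlength=self.model.n_states)
        return counts / counts.sum()

    def write(self, out_dir: str | Path) -> None:
        """One TSV per molecule plus a ground-truth sidecar TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r in self.records:
            t = r.trace
            df = pd.DataFrame(
                {
                    "frame": np.arange(len(t.time)),
                    "time_s": t.time,
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
            df.to_csv(out / f"{t.molecule_id}.tsv", sep="\t", index=False)
            truth = pd.DataFrame(
                {"frame": np.arange(len(r.state_seq)), "state": r.state_seq}
            )
            truth.to_csv(out / f"{t.molecule_id}.truth.tsv", sep="\t", index=False)


def default_states() -> list[StateSpec]:
    """The three-state riboswitch signature: unfolded / pre-folded / folded."""
    return [
        StateSpec("unfolded", 0.2, 0.05),
        StateSpec("pre-folded", 0.5, 0.05),
        StateSpec("folded", 0.8, 0.05),
    ]


def three_state_model(
    taus: Sequence[float] = (0.69, 0.11, 0.40),
    states: Sequence[StateSpec] | None = None,
    chain: bool = True,
) -> KineticModel:
    """Three-state kinetic model with the given per-state lifetimes.

    Default lifetimes are the aptamer values at 2 mM Mg2+ (unfolded 0.69 s,
    pre-folded 0.11 s, folded 0.40 s).  With ``chain=True`` the connectivity is
    the linear pathway unfolded <-> pre-folded <-> folded (no direct
    low<->high FRET rate); otherwise the middle state's exits split and the
    unfolded state may also fold directly.
    """
    if states is None:
        states = default_states()
    k = 1.0 / np.asarray(taus, dtype=float)
    Q = np.zeros((3, 3))
    if chain:
        Q[0, 1] = k[0]
        Q[1, 0] = 0.5 * k[1]
        Q[1, 2] = 0.5 * k[1]
        Q[2, 1] = k[2]
    else:
        Q[0, 1] = 0.7 * k[0]
        Q[0, 2] = 0.3 * k[0]
        Q[1, 0] = 0.5 * k[1]
        Q[1, 2] = 0.5 * k[1]
        Q[2, 0] = 0.3 * k[2]
        Q[2, 1] = 0.7 * k[2]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return KineticModel(list(states), Q)


def default_emission() -> EmissionConfig:
    return EmissionConfig()


def simulate_ensemble(
    model: KineticModel,
    states: Sequence[StateSpec] | None = None,
    emission: EmissionConfig | None = None,
    n_traces: int = 100,
    trace_length: int = 600,
    seed: int | np.random.Generator = 0,
    condition: dict | None = None,
) -> TraceSet:
    """Simulate ``n_traces`` independent molecules under one condition.

    Ground-truth continuous paths and frame-sampled state sequences are kept
    alongside the noisy traces for recovery testing.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if states is None:
        states = model.states
    if emission is None:
        emission = default_emission()
    rng = np.random.default_rng(seed)
    duration = trace_length * emission.frame_interval
    records = []
    for i in range(n_traces):
        path = simulate_state_path(model, duration * (1 + 1e-9) + 1e-12, rng)
        seq = discretize_path(path, emission.frame_interval, trace_length)
        trace = emit_intensities(seq, states, emission, rng, molecule_id=f"mol{i:04d}")
        records.append(TraceRecord(trace, path, seq))
    return TraceSet(records, model, emission, condition=dict(condition or {}))


def simulate_titration(
    base_model: KineticModel,
    states: Sequence[StateSpec] | None,
    emission: EmissionConfig | None,
    law: TitrationLaw,
    concentrations: Sequence[float],
    n_traces: int = 100,
    trace_length: int = 600,
    seed: int = 0,
    folded_index: int = -1,
) -> dict[float, TraceSet]:
    """Simulate one TraceSet per ligand concentration.

    At concentration c the folded state's stationary occupancy follows the
    titration law; the rate matrix is retuned per concentration by rescaling
    the folded state's unfolding rates (see KineticModel.with_folded_occupancy),
    so the ligand shifts populations, not the FRET values of the states.
    """
    concentrations = [float(c) for c in concentrations]
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    out: dict[float, TraceSet] = {}
    for c in concentrations:
        occ = float(law.response(c))
        if occ >= 1.0:
            raise ValueError(f"requested folded occupancy {occ} >= 1 at c={c}")
        model_c = base_model.with_folded_occupancy(occ, folded_index=folded_index)
        child_seed = int(rng.integers(0, 2**31 - 1))
        out[c] = simulate_ensemble(
            model_c,
            states=states,
            emission=emission,
            n_traces=n_traces,
            trace_length=trace_length,
            seed=child_seed,
            condition={"concentration": c, "unit": law.unit},
        )
    return out


def simulate_readthrough_assay(
    law: TitrationLaw,
    concentrations: Sequence[float],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Transcription read-through fractions vs ligand concentration.

    The mean response follows the Hill law; replicate scatter is additive
    Gaussian, clipped to [0, 1] (fractions cannot leave the unit interval).
    Returns a tidy table with columns concentration, unit, replicate, response.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        mean = float(law.response(c))
        for rep in range(n_replicates):
            resp = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((float(c), law.unit, rep, float(np.clip(resp, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["concentration", "unit", "replicate", "response"])


def load_config(path: str | Path) -> dict:
    """Load a YAML simulation config into constructor-ready objects.

    Keys: ``states`` (list of {label, efret_mean, efret_sd}), ``rate_matrix``
    (KxK list), ``emission`` (EmissionConfig fields), optional ``titration``
    (TitrationLaw fields), optional ``n_traces``/``trace_length``/``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    states = [StateSpec(**s) for s in raw["states"]]
    Q = np.asarray(raw["rate_matrix"], dtype=float)
    # the diagonal is redundant (rows must sum to 0): recompute it so configs
    # may carry rounded diagonals or omit them entirely
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    model = KineticModel(states, Q)
    emission = EmissionConfig(**raw.get("emission", {}))
    cfg = {
        "model": model,
        "states": states,
        "emission": emission,
        "n_traces": int(raw.get("n_traces", 100)),
        "trace_length": int(raw.get("trace_length", 600)),
        "seed": int(raw.get("seed", 0)),
    }
    if "titration" in raw:
        cfg["titration"] = TitrationLaw(**raw["titration"])
    return cfg
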