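"""Intensity traces, FRET efficiency, photobleach detection and rule-based QC.

The observable is the uncorrected proximity ratio E = I_A / (I_A + I_D)
computed per frame from the donor and acceptor channels; no gamma factor,
crosstalk or background model is applied beyond an optional constant offset
per channel.  Frames at or after the earliest photobleach are masked out, not
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "FRETTrace",
    "QCCriteria",
    "compute_efret",
    "detect_bleach",
    "select_traces",
    "read_traces",
    "write_traces",
]


@dataclass
class FluorescenceTrace:
    """Donor/acceptor intensities of one molecule on a uniform frame grid."""

    molecule_id: str
    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    bleach_frame_donor: int | None = None
    bleach_frame_acceptor: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time/donor/acceptor must have equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time must be strictly increasing with constant step")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) >= 2 else np.nan

    def first_bleach_frame(self) -> int | None:
        frames = [
            f for f in (self.bleach_frame_donor, self.bleach_frame_acceptor) if f is not None
        ]
        return min(frames) if frames else None


@dataclass
class FRETTrace:
    """Per-frame FRET efficiency with a validity mask (pre-bleach, finite)."""

    molecule_id: str
    time: np.ndarray
    efret: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.efret = np.asarray(self.efret, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (len(self.time) == len(self.efret) == len(self.valid_mask)):
            raise ValueError("time/efret/valid_mask must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    def valid_values(self) -> np.ndarray:
        return self.efret[self.valid_mask]


@dataclass(frozen=True)
class QCCriteria:
    """Rule-based trace selection standing in for learned trace classification.

    Rules are evaluated in the declared order and a rejected trace is labelled
    with the first failing rule.  Set a field to None to disable the rule.
    """

    min_length: int | None = 50
    min_total_intensity: float | None = None
    max_efret_sd_prebleach: float | None = None
    require_single_bleach: bool = False

    def __post_init__(self) -> None:
        if self.min_length is not None and self.min_length < 2:
            raise ValueError("min_length must be >= 2")


def compute_efret(
    trace: FluorescenceTrace,
    donor_background: float = 0.0,
    acceptor_background: float = 0.0,
) -> FRETTrace:
    """Proximity ratio E[t] = I_A[t] / (I_A[t] + I_D[t]).

    Frames with nonpositive total intensity and frames at/after the earliest
    bleach frame are marked invalid.  E is scale-invariant in the channel pair.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    donor = trace.donor - donor_background
    acceptor = trace.acceptor - acceptor_background
    total = donor + acceptor
    valid = total > 0
    efret = np.full(len(trace), np.nan)
    np.divide(acceptor, total, out=efret, where=valid)
    valid &= np.isfinite(efret)
    # E is a physical ratio in [0, 1]; frames pushed outside by noise are corrupt
    valid &= (efret >= 0.0) & (efret <= 1.0)
    bleach = trace.first_bleach_frame()
    if bleach is not None:
        valid[bleach:] = False
    return FRETTrace(trace.molecule_id, trace.time.copy(), efret, valid)


def _detect_bleach_channel(
    x: np.ndarray, drop_threshold: float, window: int
) -> int | None:
    """Earliest frame f where x stays below drop_threshold * mean(x[:f]) for
    >= window frames."""
    n = len(x)
    if n < window + 1:
        return None
    csum = np.cumsum(x)
    for f in range(1, n - window + 1):
        lead_mean = csum[f - 1] / f
        if lead_mean <= 0:
            continue
        if np.all(x[f : f + window] < drop_threshold * lead_mean):
            return f
    return None


def detect_bleach(
    trace: FluorescenceTrace, drop_threshold: float = 0.25, window: int = 10
) -> tuple[int | None, int | None]:
    """Detect single-step photobleaching per channel.

    Returns (donor_bleach_frame, acceptor_bleach_frame); None where no
    sustained drop below ``drop_threshold`` times the pre-drop mean is found.
    The default threshold (0.25) sits below the lowest conformational level of
    a FRET pair (E in [0.2, 0.8] keeps each channel above ~20% of the total),
    so state dynamics do not masquerade as bleaching while a bleached channel
    (background + noise) stays under it.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    d = _detect_bleach_channel(trace.donor, drop_threshold, window)
    a = _detect_bleach_channel(trace.acceptor, drop_threshold, window)
    return d, a


def _qc_reason(trace: FluorescenceTrace, criteria: QCCriteria) -> str | None:
    if criteria.min_length is not None and len(trace) < criteria.min_length:
        return "min_length"
    bleach = trace.first_bleach_frame()
    end = bleach if bleach is not None else len(trace)
    if criteria.min_total_intensity is not None:
        total = trace.donor[:end] + trace.acceptor[:end]
        if end == 0 or float(np.mean(total)) < criteria.min_total_intensity:
            return "min_total_intensity"
    if criteria.max_efret_sd_prebleach is not None:
        et = compute_efret(trace)
        vals = et.valid_values()
        if len(vals) < 2 or float(np.std(vals)) > criteria.max_efret_sd_prebleach:
            return "max_efret_sd_prebleach"
    if criteria.require_single_bleach:
        n_bleached = sum(
            f is not None
            for f in (trace.bleach_frame_donor, trace.bleach_frame_acceptor)
        )
        if n_bleached != 1:
            return "require_single_bleach"
    return None


def select_traces(
    traces: list[FluorescenceTrace], criteria: QCCriteria
) -> tuple[list[FluorescenceTrace], dict[str, str]]:
    """Deterministic rule-based filtering.

    Returns the accepted traces and a map molecule_id -> first failing rule
    for every rejected trace.
    """
    accepted: list[FluorescenceTrace] = []
    rejected: dict[str, str] = {}
    for tr in traces:
        reason = _qc_reason(tr, criteria)
        if reason is None:
            accepted.append(tr)
        else:
            rejected[tr.molecule_id] = reason
    return accepted, rejected


def write_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    """Write an ensemble to one concatenated TSV with a molecule_id column."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.time,
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read traces from a directory of per-molecule TSVs or one concatenated TSV."""
    p = Path(path)
    if p.is_dir():
        out = []
        for f in sorted(p.glob("*.tsv")):
            if f.name.endswith(".truth.tsv"):
                continue
            df = pd.read_csv(f, sep="\t")
            out.append(
                FluorescenceTrace(
                    molecule_id=f.stem,
                    time=df["time_s"].to_numpy(),
                    donor=df["donor"].to_numpy(),
                    acceptor=df["acceptor"].to_numpy(),
                )
            )
        return out
    df = pd.read_csv(p, sep="\t")
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        out.append(
            FluorescenceTrace(
                molecule_id=str(mol),
                time=grp["time_s"].to_numpy(),
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
            )
        )
    return out
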