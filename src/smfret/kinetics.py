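"""Dwell-time kinetics from idealized trajectories.

A dwell is one uninterrupted residence in a state between two transitions.
For a Markov state, dwells are exponential with mean lifetime tau and rate
constant k = 1/tau.  The default estimator is the exponential MLE (the mean
of the uncensored dwells) with the exact chi-square confidence interval; a
binned least-squares fit of the dwell-time histogram to A*exp(-t/tau) is also
provided, mirroring the classic plot-and-fit procedure.

First and last dwells of every trace (and of every contiguous valid run) are
flagged as censored — their start or end was not observed — and excluded from
the default fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .hmm import IdealizedPath
from .traces import FRETTrace

__all__ = [
    "DwellSet",
    "LifetimeFit",
    "TransitionDensity",
    "ExponentialDwellModel",
    "extract_dwells",
    "fit_dwell_exponential",
    "transition_density",
]


@dataclass
class DwellSet:
    """Table of dwells: molecule_id, state, duration_s, next_state,
    censored_left, censored_right."""

    table: pd.DataFrame

    COLUMNS = (
        "molecule_id",
        "state",
        "duration_s",
        "next_state",
        "censored_left",
        "censored_right",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"DwellSet table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    def for_state(self, state: int) -> pd.DataFrame:
        return self.table[self.table["state"] == state]

    def uncensored(self, state: int | None = None) -> np.ndarray:
        t = self.table
        sel = ~(t["censored_left"] | t["censored_right"])
        if state is not None:
            sel &= t["state"] == state
        return t.loc[sel, "duration_s"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DwellSet":
        return cls(pd.read_csv(path, sep="\t"))


def extract_dwells(
    paths: Sequence[IdealizedPath], frame_interval: float
) -> DwellSet:
    """Segment durations from idealized paths.

    duration = segment length (frames) * frame_interval.  The first segment of
    each contiguous valid run is left-censored, the last right-censored; a
    single-segment run is censored on both sides.  ``next_state`` is the state
    entered at the segment's end (-1 when censored).
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    rows = []
    for path in paths:
        segs = path.segments
        for i, (state, start, end) in enumerate(segs):
            left = i == 0 or segs[i - 1][2] != start  # run boundary before
            right = i == len(segs) - 1 or segs[i + 1][1] != end  # run boundary after
            next_state = -1 if right else segs[i + 1][0]
            rows.append(
                (
                    path.molecule_id,
                    int(state),
                    (end - start) * frame_interval,
                    int(next_state),
                    bool(left),
                    bool(right),
                )
            )
    return DwellSet(pd.DataFrame(rows, columns=list(DwellSet.COLUMNS)))


@dataclass
class LifetimeFit:
    """Exponential lifetime of one state: tau (s), k = 1/tau (1/s), CI, counts."""

    state: int
    tau: float
    tau_ci: tuple[float, float]
    n_dwells: int
    method: str

    @property
    def k(self) -> float:
        return 1.0 / self.tau

    def summary(self) -> str:
        lo, hi = self.tau_ci
        return (
            f"state {self.state}: tau = {self.tau:.4f} s "
            f"[{lo:.4f}, {hi:.4f}], k = {self.k:.4f} 1/s "
            f"({self.n_dwells} dwells, {self.method})"
        )


class ExponentialDwellModel:
    """First-order (single-exponential) dwell-time model for one state.

    Parameters
    ----------
    dwells : DwellSet
    state : int
        State index whose dwells are fitted.
    censoring_policy : {"exclude", "include_right"}
        "exclude" drops every censored dwell (default); "include_right" keeps
        right-censored dwells in the standard censored-exponential likelihood
        (they add observation time but no event).
    min_dwells : int
        Minimum number of uncensored dwells required (default 10).
    """

    def __init__(
        self,
        dwells: DwellSet,
        state: int,
        censoring_policy: str = "exclude",
        min_dwells: int = 10,
    ):
        if censoring_policy not in ("exclude", "include_right"):
            raise ValueError(f"unknown censoring_policy {censoring_policy!r}")
        self.dwells = dwells
        self.state = int(state)
        self.censoring_policy = censoring_policy
        self.min_dwells = int(min_dwells)

    def fit(self, method: str = "mle", bins: int = 30) -> LifetimeFit:
        """Estimate tau.

        method "mle": tau = mean of uncensored dwells (plus right-censored
        observation time under "include_right"); exact chi-square CI from
        2*n*tau_hat / tau ~ chi2(2n).  method "binned_lsq": least-squares fit
        of the dwell histogram to A*exp(-t/tau); CI from the Jacobian.
        """
        t = self.dwells.for_state(self.state)
        unc = t[~(t["censored_left"] | t["censored_right"])]["duration_s"].to_numpy()
        n_events = len(unc)
        if n_events < self.min_dwells:
            raise ValueError(
                f"state {self.state}: {n_events} uncensored dwells < "
                f"required {self.min_dwells}"
            )
        if method == "mle":
            total = float(unc.sum())
            if self.censoring_policy == "include_right":
                rc = t[t["censored_right"] & ~t["censored_left"]]["duration_s"]
                total += float(rc.sum())
            tau = total / n_events
            # 2*S/tau ~ chi2(2n): exact interval for the exponential mean
            lo = 2 * total / stats.chi2.ppf(0.975, 2 * n_events)
            hi = 2 * total / stats.chi2.ppf(0.025, 2 * n_events)
            tag = f"mle/{self.censoring_policy}"
            return LifetimeFit(self.state, tau, (lo, hi), n_events, tag)
        if method == "binned_lsq":
            counts, edges = np.histogram(unc, bins=bins)
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = counts > 0
            tau0 = float(unc.mean())

            def decay(tt, A, tau):
                return A * np.exp(-tt / tau)

            popt, pcov = curve_fit(
                decay,
                centers[keep],
                counts[keep],
                p0=(counts.max(), tau0),
                bounds=((0, 1e-9), (np.inf, np.inf)),
                maxfev=10000,
            )
            tau = float(popt[1])
            se = float(np.sqrt(pcov[1, 1]))
            return LifetimeFit(
                self.state, tau, (tau - 1.96 * se, tau + 1.96 * se), n_events,
                "binned_lsq",
            )
        raise ValueError(f"unknown method {method!r}")


def fit_dwell_exponential(
    dwells: DwellSet,
    state: int,
    censoring_policy: str = "exclude",
    method: str = "mle",
    min_dwells: int = 10,
) -> LifetimeFit:
    """Exponential lifetime fit for one state's dwell-time distribution."""
    return ExponentialDwellModel(
        dwells, state, censoring_policy=censoring_policy, min_dwells=min_dwells
    ).fit(method=method)


@dataclass
class TransitionDensity:
    """2-D histogram of (E before, E after) over all state changes."""

    counts: np.ndarray
    bin_edges: np.ndarray
    n_transitions: int

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.copy()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# bin_edges\t" + "\t".join(f"{e:.6g}" for e in self.bin_edges) + "\n")
            pd.DataFrame(self.counts).to_csv(fh, sep="\t", index=False, header=False)


def transition_density(
    paths: Sequence[IdealizedPath],
    fret_traces: Sequence[FRETTrace] | None = None,
    bin_width: float = 0.05,
) -> TransitionDensity:
    """Transition density plot from idealized paths.

    Each state change contributes one count at (mean E of the departing
    segment, mean E of the arriving segment).  With ``fret_traces`` supplied
    (matched by position), segment means are taken from the raw E values, so
    misassignment smear stays visible; otherwise the fitted state means are
    used.  Diagonal bins stay empty because the state must change.
    """
    if not 0.0 < bin_width < 1.0:
        raise ValueError("bin_width must be in (0, 1)")
    befores, afters = [], []
    for i, path in enumerate(paths):
        raw = None
        if fret_traces is not None:
            raw = np.asarray(fret_traces[i].efret, dtype=float)

        def seg_mean(seg):
            state, start, end = seg
            if raw is not None:
                vals = raw[start:end]
                vals = vals[np.isfinite(vals)]
                if len(vals):
                    return float(np.mean(vals))
            return float(path.fitted_mean[start])

        segs = path.segments
        for j in range(len(segs) - 1):
            if segs[j][2] != segs[j + 1][1]:
                continue  # masked gap: not an observed transition
            befores.append(seg_mean(segs[j]))
            afters.append(seg_mean(segs[j + 1]))
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _, _ = np.histogram2d(befores, afters, bins=(edges, edges))
    return TransitionDensity(counts, edges, len(befores))
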