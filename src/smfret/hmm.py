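"""Gaussian-emission hidden Markov modelling of FRET trajectories.

Idealization of smFRET time traces: each frame's proximity ratio E is modelled
as a Gaussian draw around the mean E of a hidden conformational state, and the
hidden state evolves as a first-order Markov chain on the frame clock.  One
model (shared emission parameters and transition matrix) is fitted jointly to
all traces of an experimental condition by maximum-likelihood EM (Baum-Welch);
the number of states is chosen by BIC; per-trace state paths come from Viterbi
decoding.

The implementation follows the statsmodels convention: ``GaussianHMM`` is the
model object, ``GaussianHMM.fit`` returns an ``HMMResults`` carrying the
estimates, fit diagnostics and decoding methods.  ``fit_hmm`` / ``viterbi`` /
``select_states`` are thin functional wrappers.

All recursions run in scaled (normalised) space, so likelihoods of long traces
do not underflow; states are always reported in canonical order of ascending
mean E.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .traces import FRETTrace

__all__ = [
    "GaussianHMM",
    "HMMResults",
    "HMMModel",
    "IdealizedPath",
    "fit_hmm",
    "viterbi",
    "select_states",
    "forward_log_likelihood",
]

SD_FLOOR = 1e-3  # emission SD floor; prevents likelihood divergence on noiseless data
_TINY = 1e-300

try:  # compiled E-step; the numpy path below is the reference implementation
    from ._hmm_kernels import estep_batch as _estep_batch_compiled
except Exception:  # pragma: no cover - numba missing or compile failure
    _estep_batch_compiled = None


def _as_sequences(traces) -> list[np.ndarray]:
    """Extract contiguous runs of valid E values from traces.

    Accepts FRETTrace objects or plain arrays.  Invalid frames split a trace
    into independent observation sequences (the Markov chain is not bridged
    across masked gaps).
    """
    seqs: list[np.ndarray] = []
    for tr in traces:
        if isinstance(tr, FRETTrace):
            x = tr.efret
            mask = tr.valid_mask & np.isfinite(x)
        else:
            x = np.asarray(tr, dtype=float)
            mask = np.isfinite(x)
        if not mask.any():
            continue
        # contiguous runs of True
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            seqs.append(x[run].astype(float))
    return seqs


def _emission_probs(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Gaussian density of each observation under each state; shape (..., K)."""
    z = (x[..., None] - means) / sds
    B = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sds)
    return np.maximum(B, _TINY)


def _forward_backward_batch(X: np.ndarray, startprob, transmat, means, sds):
    """Scaled forward-backward over a batch of equal-length sequences.

    X : (N, T).  Returns (loglik_total, gamma (N,T,K), xi_sum (K,K),
    gamma0_sum (K,)).
    """
    N, T = X.shape
    K = len(means)
    B = _emission_probs(X, means, sds)  # (N, T, K)
    alpha = np.empty((N, T, K))
    c = np.empty((N, T))
    a = startprob * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ transmat) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = float(np.log(c).sum())

    beta = np.empty((N, T, K))
    beta[:, -1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]  # (N, K)
        beta[:, t] = (bb @ transmat.T) / c[:, t + 1, None]
        # xi_t(i,j) proportional to alpha_t(i) A(i,j) bb(j) / c_{t+1}
        xi_sum += transmat * np.einsum(
            "ni,nj->ij", alpha[:, t], bb / c[:, t + 1, None]
        )
    gamma = alpha * beta
    return loglik, gamma, xi_sum, gamma[:, 0].sum(axis=0)


@dataclass
class IdealizedPath:
    """Viterbi decoding of one trace: per-frame states and dwell segmentation.

    ``states`` holds -1 at invalid frames.  ``segments`` is a list of
    (state, start_frame, end_frame_exclusive) partitioning the valid frames;
    segments never span a masked gap.
    """

    molecule_id: str
    states: np.ndarray
    fitted_mean: np.ndarray
    segments: list[tuple[int, int, int]]
    log_probability: float = np.nan

    def __len__(self) -> int:
        return len(self.states)

    def valid_states(self) -> np.ndarray:
        return self.states[self.states >= 0]


@dataclass
class HMMResults:
    """Fitted Gaussian-emission HMM for one experimental condition.

    States are in canonical order of ascending mean E.  ``bic`` uses
    p = (K^2 - K) + (K - 1) + 2K free parameters (transition off-diagonals,
    initial distribution, means and SDs) and the number of valid frames as n.
    """

    K: int
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    n_obs: int
    n_iter: int = 0
    converged: bool = True
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    # spec aliases
    @property
    def trans(self) -> np.ndarray:
        return self.transmat

    @property
    def init(self) -> np.ndarray:
        return self.startprob

    @property
    def n_parameters(self) -> int:
        K = self.K
        return (K * K - K) + (K - 1) + 2 * K

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * math.log(self.n_obs)

    def score(self, trace) -> float:
        """Forward log-likelihood of a trace under this model."""
        return sum(
            _forward_backward_batch(
                s[None, :], self.startprob, self.transmat, self.means, self.sds
            )[0]
            for s in _as_sequences([trace])
        )

    def viterbi(self, trace: FRETTrace) -> IdealizedPath:
        return viterbi(trace, self)

    def decode(self, traces: Sequence[FRETTrace]) -> list[IdealizedPath]:
        return [self.viterbi(tr) for tr in traces]

    def summary(self) -> str:
        lines = [
            "Gaussian-emission HMM (joint fit)",
            f"  states: {self.K}   frames: {self.n_obs}   "
            f"logL: {self.log_likelihood:.3f}   BIC: {self.bic:.3f}",
            f"  converged: {self.converged} in {self.n_iter} iterations",
            "  state    mean E    sd E    self-transition",
        ]
        for k in range(self.K):
            lines.append(
                f"  {k:5d}    {self.means[k]:.4f}   {self.sds[k]:.4f}"
                f"   {self.transmat[k, k]:.4f}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "K": self.K,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "HMMResults":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            K=d["K"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            transmat=np.asarray(d["transmat"]),
            startprob=np.asarray(d["startprob"]),
            log_likelihood=d["log_likelihood"],
            n_obs=d["n_obs"],
            converged=d.get("converged", True),
        )


# spec name for the fitted-parameter container
HMMModel = HMMResults


class GaussianHMM:
    """Gaussian-emission HMM over one or more FRET traces.

    Parameters
    ----------
    traces : sequence of FRETTrace or 1-D arrays
        Observations; invalid/masked frames split traces into independent
        sequences.  All traces share one emission model and transition matrix
        (one model per experimental condition).
    K : int
        Number of hidden states.
    sd_floor : float
        Lower bound on emission SDs (default 1e-3), preventing collapse on
        (near-)noiseless data.
    """

    def __init__(self, traces, K: int, sd_floor: float = SD_FLOOR):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = int(K)
        self.sd_floor = float(sd_floor)
        self.sequences = _as_sequences(traces)
        self.n_obs = int(sum(len(s) for s in self.sequences))
        if self.n_obs < 10 * self.K:
            raise ValueError(
                f"need >= {10 * self.K} valid frames for K={self.K}, got {self.n_obs}"
            )
        self._pooled = np.concatenate(self.sequences)

    # -- initialization -------------------------------------------------
    def _initial_params(self, rng: np.random.Generator, restart: int):
        K = self.K
        x = self._pooled
        q = (np.arange(K) + 0.5) / K
        means = np.quantile(x, q)
        pooled_sd = max(float(np.std(x)), self.sd_floor)
        if restart == 1 and K > 1:
            # range-spread start: robust when one state dominates the pooled
            # distribution and the quantiles all fall into its peak
            means = np.linspace(x.min(), x.max(), K + 2)[1:-1]
        elif restart >= 2:
            means = means + rng.normal(0.0, pooled_sd / max(K, 2), size=K)
        sds = np.full(K, max(pooled_sd / math.sqrt(K), self.sd_floor))
        if K == 1:
            transmat = np.ones((1, 1))
        else:
            transmat = np.full((K, K), 0.05 / (K - 1))
            np.fill_diagonal(transmat, 0.95)
        startprob = np.full(K, 1.0 / K)
        return means, sds, transmat, startprob

    # -- EM -------------------------------------------------------------
    def _em(self, means, sds, transmat, startprob, tol, max_iter):
        # group sequences by length so forward-backward can run batched
        by_len: dict[int, list[np.ndarray]] = {}
        for s in self.sequences:
            by_len.setdefault(len(s), []).append(s)
        batches = [np.stack(v) for v in by_len.values()]

        history = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            loglik = 0.0
            xi_sum = np.zeros((self.K, self.K))
            gamma0 = np.zeros(self.K)
            gsum = np.zeros(self.K)
            gx = np.zeros(self.K)
            gxx = np.zeros(self.K)
            for X in batches:
                if _estep_batch_compiled is not None:
                    ll, xi, g0, gs, gx_b, gxx_b = _estep_batch_compiled(
                        X, startprob, transmat, means, sds
                    )
                    loglik += ll
                    xi_sum += xi
                    gamma0 += g0
                    gsum += gs
                    gx += gx_b
                    gxx += gxx_b
                else:
                    ll, gamma, xi, g0 = _forward_backward_batch(
                        X, startprob, transmat, means, sds
                    )
                    loglik += ll
                    xi_sum += xi
                    gamma0 += g0
                    gsum += gamma.sum(axis=(0, 1))
                    gx += np.einsum("ntk,nt->k", gamma, X)
                    gxx += np.einsum("ntk,nt->k", gamma, X * X)
            history.append(loglik)

            # M-step
            startprob = gamma0 / gamma0.sum()
            if self.K > 1:
                rows = xi_sum.sum(axis=1, keepdims=True)
                transmat = np.where(rows > 0, xi_sum / np.maximum(rows, _TINY), 1.0 / self.K)
                transmat /= transmat.sum(axis=1, keepdims=True)
            means = gx / gsum
            var = gxx / gsum - means**2
            sds = np.sqrt(np.maximum(var, self.sd_floor**2))

            if loglik - prev < tol and it > 1:
                converged = True
                break
            prev = loglik
        return means, sds, transmat, startprob, history, converged, it

    def fit(
        self,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 3,
        seed: int | np.random.Generator = 0,
    ) -> HMMResults:
        """Fit by Baum-Welch EM, keeping the best of ``n_restarts`` by logL.

        The first restart starts from quantile-spaced means; later restarts
        jitter the means with seeded noise.  Deterministic for a given seed.
        The EM log-likelihood is non-decreasing across iterations.
        """
        rng = np.random.default_rng(seed)
        best: HMMResults | None = None
        for r in range(max(1, n_restarts)):
            means, sds, transmat, startprob = self._initial_params(rng, restart=r)
            means, sds, transmat, startprob, hist, converged, it = self._em(
                means, sds, transmat, startprob, tol, max_iter
            )
            res = HMMResults(
                K=self.K,
                means=means,
                sds=sds,
                transmat=transmat,
                startprob=startprob,
                log_likelihood=hist[-1],
                n_obs=self.n_obs,
                n_iter=it,
                converged=converged,
                loglik_history=np.asarray(hist),
            )
            if best is None or res.log_likelihood > best.log_likelihood:
                best = res
        assert best is not None
        if not best.converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations (K={self.K})",
                RuntimeWarning,
            )
        return _canonicalize(best)


def _canonicalize(res: HMMResults) -> HMMResults:
    """Sort states by ascending mean E (canonical order)."""
    order = np.argsort(res.means, kind="stable")
    res.means = res.means[order]
    res.sds = res.sds[order]
    res.transmat = res.transmat[np.ix_(order, order)]
    res.startprob = res.startprob[order]
    return res


def fit_hmm(
    traces,
    K: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
    sd_floor: float = SD_FLOOR,
) -> HMMResults:
    """Joint Baum-Welch fit of a K-state Gaussian HMM to a set of traces."""
    return GaussianHMM(traces, K, sd_floor=sd_floor).fit(
        tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
    )


def forward_log_likelihood(trace, model: HMMResults) -> float:
    """Forward-algorithm log-likelihood of a trace under a fitted model."""
    return model.score(trace)


def _viterbi_run(x: np.ndarray, model: HMMResults) -> tuple[np.ndarray, float]:
    """Max-probability state path for one contiguous sequence (log space).

    Ties break toward the lower state index (argmax returns the first max).
    """
    K = model.K
    logB = np.log(_emission_probs(x, model.means, model.sds))
    logA = np.log(np.maximum(model.transmat, _TINY))
    T = len(x)
    delta = np.log(np.maximum(model.startprob, _TINY)) + logB[0]
    psi = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    last = int(np.argmax(delta))
    logp = float(delta[last])
    path = np.empty(T, dtype=int)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, logp


def viterbi(trace: FRETTrace, model: HMMResults) -> IdealizedPath:
    """Maximum a posteriori state path of one trace; invalid frames get -1."""
    if isinstance(trace, FRETTrace):
        x = trace.efret
        mask = trace.valid_mask & np.isfinite(x)
        mol = trace.molecule_id
    else:
        x = np.asarray(trace, dtype=float)
        mask = np.isfinite(x)
        mol = "trace"
    T = len(x)
    states = np.full(T, -1, dtype=int)
    logp_total = 0.0
    idx = np.flatnonzero(mask)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            path, logp = _viterbi_run(x[run].astype(float), model)
            states[run] = path
            logp_total += logp
    fitted = np.where(states >= 0, model.means[np.clip(states, 0, None)], np.nan)
    segments: list[tuple[int, int, int]] = []
    if idx.size:
        start = idx[0]
        for i in range(1, len(idx) + 1):
            boundary = (
                i == len(idx)
                or idx[i] != idx[i - 1] + 1
                or states[idx[i]] != states[idx[i - 1]]
            )
            if boundary:
                segments.append((int(states[start]), int(start), int(idx[i - 1] + 1)))
                if i < len(idx):
                    start = idx[i]
    return IdealizedPath(mol, states, fitted, segments, log_probability=logp_total)


def select_states(
    traces,
    K_candidates: Sequence[int] = (1, 2, 3, 4, 5),
    criterion: str = "bic",
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, dict[int, HMMResults], dict[int, float]]:
    """Fit each candidate K and pick the one minimising BIC.

    Returns (best K, {K: HMMResults}, {K: BIC score}).  Deterministic for a
    given seed.
    """
    if criterion != "bic":
        raise ValueError("only the 'bic' criterion is implemented")
    if not K_candidates:
        raise ValueError("K_candidates must be nonempty")
    models: dict[int, HMMResults] = {}
    scores: dict[int, float] = {}
    for K in K_candidates:
        res = fit_hmm(traces, K, seed=seed, **fit_kwargs)
        models[K] = res
        scores[K] = res.bic
    best = min(scores, key=lambda k: (scores[k], k))
    return best, models, scores
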