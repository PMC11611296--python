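"""HMM inference against exhaustive-enumeration oracles and ground truth.

The forward likelihood and Viterbi path of small instances (T <= 8, K <= 3)
are checked against brute-force sums/maxima over all K^T state sequences;
larger fits are checked against the generator's ground truth and against
hmmlearn as an independent implementation of the same likelihood.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import smfret
from smfret.hmm import GaussianHMM, HMMResults, fit_hmm, select_states, viterbi
from tests.conftest import random_hmm_params


def make_results(means, sds, trans, start):
    return HMMResults(
        K=len(means),
        means=np.asarray(means, float),
        sds=np.asarray(sds, float),
        transmat=np.asarray(trans, float),
        startprob=np.asarray(start, float),
        log_likelihood=np.nan,
        n_obs=0,
    )


def enumerate_loglik(x, model):
    """Brute-force forward likelihood: sum over all K^T paths."""
    K, T = model.K, len(x)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.startprob[path[0]] * norm.pdf(x[0], model.means[path[0]], model.sds[path[0]])
        for t in range(1, T):
            p *= model.transmat[path[t - 1], path[t]] * norm.pdf(
                x[t], model.means[path[t]], model.sds[path[t]]
            )
        total += p
    return np.log(total)


def enumerate_viterbi(x, model):
    """Brute-force MAP path: max over all K^T paths, ties to the lexicographically
    smallest path (consistent with lower-state-index tie-breaking)."""
    K, T = model.K, len(x)
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        logp = np.log(model.startprob[path[0]]) + norm.logpdf(
            x[0], model.means[path[0]], model.sds[path[0]]
        )
        for t in range(1, T):
            logp += np.log(model.transmat[path[t - 1], path[t]]) + norm.logpdf(
                x[t], model.means[path[t]], model.sds[path[t]]
            )
        if logp > best_logp + 1e-12:
            best_logp, best_path = logp, path
    return best_logp, best_path


class TestForwardOracle:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_forward_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 4))
        T = int(rng.integers(1, 9))
        model = make_results(*random_hmm_params(rng, K))
        x = rng.uniform(0, 1, size=T)
        assert model.score(x) == pytest.approx(enumerate_loglik(x, model), abs=1e-8)

    def test_forward_matches_hmmlearn(self):
        # independent implementation of the same Gaussian-HMM likelihood
        from hmmlearn.hmm import GaussianHMM as RefHMM

        rng = np.random.default_rng(5)
        model = make_results(*random_hmm_params(rng, 3))
        x = rng.uniform(0, 1, size=500)
        ref = RefHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.means.reshape(-1, 1)
        ref.covars_ = (model.sds**2).reshape(-1, 1)
        assert model.score(x) == pytest.approx(ref.score(x.reshape(-1, 1)), abs=1e-6)


class TestViterbiOracle:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_viterbi_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 4))
        T = int(rng.integers(1, 9))
        model = make_results(*random_hmm_params(rng, K))
        x = rng.uniform(0, 1, size=T)
        path = viterbi(x, model)
        logp_ref, path_ref = enumerate_viterbi(x, model)
        assert path.log_probability == pytest.approx(logp_ref, abs=1e-8)
        assert tuple(path.states) == path_ref

    def test_well_separated_levels_decoded_exactly(self):
        truth = np.array([0, 0, 1, 1, 1, 0, 1, 0, 0, 1] * 10)
        x = np.where(truth == 0, 0.2, 0.8) + 0.0
        model = make_results(
            [0.2, 0.8], [0.05, 0.05], [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5]
        )
        path = viterbi(x, model)
        np.testing.assert_array_equal(path.states, truth)

    def test_decoding_accuracy_on_default_ensemble(
        self, fitted3, decoded_paths, small_ensemble
    ):
        # >= 95% per-frame accuracy on the three-state default conditions
        correct = total = 0
        for path, rec in zip(decoded_paths, small_ensemble.records):
            ok = path.states >= 0
            correct += int(np.sum(path.states[ok] == rec.state_seq[ok]))
            total += int(ok.sum())
        assert correct / total >= 0.95


class TestFit:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.1, size=2000)
        res = fit_hmm([x], 1, seed=0, n_restarts=1)
        assert res.means[0] == pytest.approx(x.mean(), abs=1e-9)
        assert res.sds[0] == pytest.approx(x.std(), abs=1e-6)  # MLE (ddof=0)

    def test_noiseless_two_level_recovery(self):
        truth = np.tile([0, 0, 0, 1, 1], 40)
        x = np.where(truth == 0, 0.2, 0.8) + 0.0
        res = fit_hmm([x], 2, seed=0, n_restarts=1)
        assert res.means == pytest.approx([0.2, 0.8], abs=1e-6)
        # observed switch frequency out of state 0: 1 change per 3 frames -> 1/3
        assert res.transmat[0, 1] == pytest.approx(1 / 3, abs=0.02)

    def test_em_monotone_loglik(self, small_efret):
        res = fit_hmm(small_efret[:20], 3, seed=1, n_restarts=1)
        diffs = np.diff(res.loglik_history)
        assert np.all(diffs >= -1e-7)

    def test_canonical_order_and_permutation_invariance(self, small_efret):
        a = fit_hmm(small_efret[:15], 3, seed=0, n_restarts=1)
        assert np.all(np.diff(a.means) > 0)
        b = fit_hmm(small_efret[:15], 3, seed=3, n_restarts=1)
        # different restart jitter, same canonical optimum
        assert b.means == pytest.approx(a.means, abs=1e-3)

    def test_parameter_recovery_on_ensemble(self, fitted3, default_model):
        assert fitted3.means == pytest.approx([0.2, 0.5, 0.8], abs=0.02)
        # transition probabilities vs the discretized chain: P = expm(Q*dt)
        from scipy.linalg import expm

        P_true = expm(default_model.rate_matrix * 0.1)
        off_true = P_true[~np.eye(3, dtype=bool)]
        off_fit = fitted3.transmat[~np.eye(3, dtype=bool)]
        rel = np.abs(off_fit - off_true) / np.maximum(off_true, 1e-12)
        # small ensemble: allow a bit beyond the 20% the full-size fit achieves
        assert np.median(rel) < 0.25

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            GaussianHMM([np.full(15, 0.5)], K=2)

    def test_sd_floor_prevents_collapse(self):
        x = np.tile([0.2, 0.2, 0.8], 50).astype(float)
        res = fit_hmm([x], 2, seed=0, n_restarts=1)
        assert np.all(res.sds >= 1e-3 - 1e-12)
        assert np.isfinite(res.log_likelihood)

    def test_json_roundtrip(self, fitted3, tmp_path):
        p = tmp_path / "model.json"
        fitted3.to_json(p)
        back = HMMResults.from_json(p)
        np.testing.assert_allclose(back.means, fitted3.means)
        np.testing.assert_allclose(back.transmat, fitted3.transmat)
        assert back.bic == pytest.approx(fitted3.bic)


class TestSelectStates:
    def test_one_state_data_selects_k1(self):
        rng = np.random.default_rng(2)
        seqs = [rng.normal(0.5, 0.05, size=300) for _ in range(5)]
        best, _, scores = select_states(seqs, K_candidates=[1, 2, 3], seed=0, n_restarts=1)
        assert best == 1

    def test_bic_reproducible_across_runs(self, small_efret):
        subset = small_efret[:10]
        _, _, s1 = select_states(subset, K_candidates=[2, 3], seed=7, n_restarts=2)
        _, _, s2 = select_states(subset, K_candidates=[2, 3], seed=7, n_restarts=2)
        assert s1 == s2

    def test_three_state_data_prefers_3_over_2(self, small_efret):
        _, _, scores = select_states(
            small_efret, K_candidates=[2, 3], seed=0, n_restarts=2
        )
        assert scores[3] < scores[2]
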