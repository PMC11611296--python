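"""Generator correctness: Gillespie law, discretization, emission inversion,
titration occupancy control, and seed determinism."""

import numpy as np
import pytest
from scipy import stats

import smfret
from smfret.simulate import (
    EmissionConfig,
    KineticModel,
    StateSpec,
    TitrationLaw,
    discretize_path,
    emit_intensities,
    simulate_readthrough_assay,
    simulate_state_path,
    three_state_model,
)


def two_state_model(k01=1.0, k10=1.0):
    states = [StateSpec("low", 0.2, 0.05), StateSpec("high", 0.8, 0.05)]
    Q = np.array([[-k01, k01], [k10, -k10]])
    return KineticModel(states, Q)


class TestStatePath:
    def test_single_state_spans_duration(self):
        m = KineticModel([StateSpec("only", 0.5, 0.05)], np.zeros((1, 1)))
        path = simulate_state_path(m, 10.0, seed=0)
        assert len(path.states) == 1
        assert path.entry_times[0] == 0.0
        assert path.duration == 10.0

    def test_all_exit_rates_zero_gives_single_segment(self):
        states = [StateSpec("a", 0.2, 0.05), StateSpec("b", 0.8, 0.05)]
        path = simulate_state_path(KineticModel(states, np.zeros((2, 2))), 5.0, seed=1)
        assert len(path.states) == 1

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_state_path(two_state_model(), -1.0, seed=0)

    def test_mean_holding_time_matches_rate(self):
        # symmetric 2-state chain at 1 s^-1: holding times ~ Exp(1)
        path = simulate_state_path(two_state_model(1.0, 1.0), 1e4, seed=42)
        _, dwells = path.dwell_times()
        dwells = dwells[:-1]  # last segment is right-censored
        se = dwells.std(ddof=1) / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 1.0) < 3 * se

    def test_holding_times_exponential_ks(self):
        # KS test against Exp(rate) on ~1e4 dwells must not reject at alpha=0.01
        m = two_state_model(2.0, 2.0)
        path = simulate_state_path(m, 5e3, seed=7)
        _, dwells = path.dwell_times()
        dwells = dwells[:-1]
        assert len(dwells) > 5_000
        p = stats.kstest(dwells, "expon", args=(0, 0.5)).pvalue
        assert p > 0.01

    def test_per_state_mean_dwell_matches_lifetimes(self):
        # aptamer lifetimes: unfolded 0.69 s, pre-folded 0.11 s, folded 0.40 s
        m = three_state_model()
        path = simulate_state_path(m, 2e3, seed=3)
        states, dwells = path.dwell_times()
        states, dwells = states[:-1], dwells[:-1]
        for s, tau in enumerate((0.69, 0.11, 0.40)):
            d = dwells[states == s]
            se = d.std(ddof=1) / np.sqrt(len(d))
            assert abs(d.mean() - tau) < 3.5 * se

    def test_stationary_distribution_is_null_vector(self):
        m = three_state_model()
        pi = m.stationary_distribution()
        assert np.allclose(pi @ m.rate_matrix, 0.0, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_occupancy_matches_stationary(self):
        m = two_state_model(1.0, 3.0)  # pi = (0.75, 0.25)
        path = simulate_state_path(m, 5e3, seed=11)
        seq = discretize_path(path, 0.05, 100_000)
        occ = np.bincount(seq, minlength=2) / len(seq)
        assert abs(occ[1] - 0.25) < 0.02


class TestDiscretize:
    def test_constant_path(self):
        m = KineticModel([StateSpec("only", 0.5, 0.05)], np.zeros((1, 1)))
        path = simulate_state_path(m, 10.0, seed=0)
        seq = discretize_path(path, 0.1, 100)
        assert np.all(seq == 0)

    def test_switch_at_frame_boundary(self):
        from smfret.simulate import StatePath

        path = StatePath(np.array([0, 1]), np.array([0.0, 0.5]), 1.0)
        seq = discretize_path(path, 0.1, 10)
        assert list(seq) == [0] * 5 + [1] * 5

    def test_too_short_path_rejected(self):
        from smfret.simulate import StatePath

        path = StatePath(np.array([0]), np.array([0.0]), 1.0)
        with pytest.raises(ValueError):
            discretize_path(path, 0.1, 11)


class TestEmission:
    def test_noiseless_inversion_exact(self):
        # zero noise, zero jitter -> E_obs = acceptor/(acceptor+donor) = mean exactly
        states = [StateSpec("s", 0.8, 1e-12)]
        em = EmissionConfig(intensity_noise_sd=0.0)
        tr = emit_intensities(np.zeros(50, dtype=int), states, em, seed=0)
        et = smfret.compute_efret(tr)
        assert np.allclose(et.efret, 0.8, atol=1e-9)

    def test_half_fret_means_equal_channels(self):
        states = [StateSpec("s", 0.5, 1e-12)]
        em = EmissionConfig(intensity_noise_sd=0.0)
        tr = emit_intensities(np.zeros(20, dtype=int), states, em, seed=0)
        assert np.allclose(tr.donor, tr.acceptor, atol=1e-6)

    def test_no_bleach_rates_no_flags(self):
        states = [StateSpec("s", 0.5, 0.05)]
        tr = emit_intensities(np.zeros(20, dtype=int), states, EmissionConfig(), seed=0)
        assert tr.bleach_frame_donor is None
        assert tr.bleach_frame_acceptor is None

    def test_acceptor_bleach_redirects_to_donor(self):
        states = [StateSpec("s", 0.8, 1e-12)]
        em = EmissionConfig(intensity_noise_sd=0.0, acceptor_bleach_rate=5.0)
        tr = emit_intensities(np.zeros(200, dtype=int), states, em, seed=1)
        f = tr.bleach_frame_acceptor
        assert f is not None
        assert np.allclose(tr.acceptor[f:], 0.0)
        assert np.allclose(tr.donor[f:], em.total_intensity)


class TestEnsembleAndTitration:
    def test_single_trace(self, default_model):
        ts = smfret.simulate_ensemble(default_model, n_traces=1, trace_length=50, seed=0)
        assert len(ts) == 1

    def test_seed_determinism(self, default_model):
        a = smfret.simulate_ensemble(default_model, n_traces=3, trace_length=100, seed=9)
        b = smfret.simulate_ensemble(default_model, n_traces=3, trace_length=100, seed=9)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.trace.donor, rb.trace.donor)
            np.testing.assert_array_equal(ra.trace.acceptor, rb.trace.acceptor)
            np.testing.assert_array_equal(ra.state_seq, rb.state_seq)

    def test_folded_occupancy_engineering(self, default_model):
        # emulates the ~90% folded ensemble seen at 20 mM Mg2+
        m = default_model.with_folded_occupancy(0.90)
        assert m.stationary_distribution()[-1] == pytest.approx(0.90, abs=1e-9)
        # non-folded lifetimes untouched
        assert np.allclose(m.lifetimes()[:-1], default_model.lifetimes()[:-1])
        ts = smfret.simulate_ensemble(m, n_traces=60, trace_length=400, seed=5)
        assert ts.true_occupancy()[-1] == pytest.approx(0.90, abs=0.03)

    def test_ensemble_histogram_modes_near_truth(self, small_efret):
        dens, edges = smfret.fret_histogram(small_efret, bin_width=0.02)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for mode in (0.2, 0.5, 0.8):
            window = (centers > mode - 0.1) & (centers < mode + 0.1)
            peak = centers[window][np.argmax(dens[window])]
            assert abs(peak - mode) <= 0.04

    def test_titration_occupancy_follows_hill(self, default_model):
        law = TitrationLaw(midpoint=100.0, hill_n=1.0, floor=0.1, ceiling=0.8)
        assert law.response(100.0) == pytest.approx(0.45)  # (floor+ceiling)/2
        assert law.response(1e-9) == pytest.approx(0.1, abs=1e-6)
        assert law.response(1e12) == pytest.approx(0.8, abs=1e-6)
        sets = smfret.simulate_titration(
            default_model, None, None, law, [30.0, 300.0],
            n_traces=40, trace_length=300, seed=8,
        )
        for c, ts in sets.items():
            assert ts.true_occupancy()[-1] == pytest.approx(
                float(law.response(c)), abs=0.05
            )


class TestReadthroughAssay:
    def test_noiseless_on_curve_and_shape(self):
        law = TitrationLaw(midpoint=68.7, hill_n=1.0, floor=0.1, ceiling=0.8)
        concs = [1.0, 10.0, 68.7, 500.0, 5000.0]
        df = simulate_readthrough_assay(law, concs, n_replicates=3, noise_sd=0.0, seed=0)
        assert len(df) == 3 * len(concs)
        expected = law.response(df["concentration"].to_numpy())
        np.testing.assert_allclose(df["response"].to_numpy(), expected, atol=1e-12)

    def test_noise_clipped_to_unit_interval(self):
        law = TitrationLaw(midpoint=10.0, floor=0.0, ceiling=1.0)
        df = simulate_readthrough_assay(
            law, [0.1, 1e4], n_replicates=200, noise_sd=0.3, seed=1
        )
        assert df["response"].between(0, 1).all()
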