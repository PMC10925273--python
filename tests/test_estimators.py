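"""Window estimators: Zwanzig, SOS, BAR, bootstrap errors, accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fepcycle as fc
from fepcycle.estimators import _pair_windows

from conftest import KBT, T_KBT

finite_samples = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=40
).map(np.asarray)


class TestZwanzig:
    def test_zero_perturbation(self):
        assert fc.zwanzig(np.zeros(100), 300.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_is_identity(self):
        assert fc.zwanzig([3.7], 300.0) == pytest.approx(3.7, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fc.zwanzig([], 300.0)

    def test_no_overflow_at_large_exponents(self):
        # |beta dU| ~ 700: naive exp would overflow, log-sum-exp must not
        dU = np.array([-700 * KBT, -699 * KBT])
        val = fc.zwanzig(dU, T_KBT)
        assert np.isfinite(val)
        assert val == pytest.approx(-700 * KBT, abs=KBT)

    def test_gaussian_closed_form(self, gaussian_window_pair):
        dU, _ = gaussian_window_pair
        expected = 1.0 - 0.5 / (2 * KBT)
        se = fc.bootstrap_stderr(dU, lambda s: fc.zwanzig(s, T_KBT), B=200, seed=0)
        assert abs(fc.zwanzig(dU, T_KBT) - expected) < 3 * se


class TestSOSWindow:
    def test_identical_hamiltonians(self):
        dg, se = fc.sos_window(np.zeros(50), np.zeros(50), 300.0)
        assert dg == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_constant_perturbation_identity(self):
        c = 2.31
        dg, _ = fc.sos_window(np.full(40, c), np.full(40, -c), 300.0)
        assert dg == pytest.approx(c, abs=1e-12)

    @pytest.mark.parametrize("bad", [([], [1.0]), ([1.0], [])])
    def test_empty_rejected(self, bad):
        with pytest.raises(ValueError, match="empty"):
            fc.sos_window(bad[0], bad[1], 300.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fc.sos_window([1.0, np.nan], [0.0], 300.0)

    @given(fwd=finite_samples, bwd=finite_samples)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_exact(self, fwd, bwd):
        a, _ = fc.sos_window(fwd, bwd, 310.0, n_bootstrap=2)
        b, _ = fc.sos_window(bwd, fwd, 310.0, n_bootstrap=2)
        assert a == pytest.approx(-b, abs=1e-12)

    @given(fwd=finite_samples, bwd=finite_samples,
           c=st.floats(min_value=-20, max_value=20, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_covariance(self, fwd, bwd, c):
        base, _ = fc.sos_window(fwd, bwd, 310.0, n_bootstrap=2)
        shifted, _ = fc.sos_window(fwd + c, bwd - c, 310.0, n_bootstrap=2)
        assert shifted - base == pytest.approx(c, abs=1e-9)


class TestBARWindow:
    def test_identical_hamiltonians(self):
        dg, _ = fc.bar_window(np.zeros(30), np.zeros(30), 300.0)
        assert dg == pytest.approx(0.0, abs=1e-7)

    def test_single_sample_constant(self):
        dg, _ = fc.bar_window([1.7], [-1.7], 300.0, n_bootstrap=2)
        assert dg == pytest.approx(1.7, abs=1e-7)

    def test_agrees_with_sos_on_gaussian_window(self, gaussian_window_pair):
        dU_f, dU_b = gaussian_window_pair
        sub_f, sub_b = dU_f[:20_000], dU_b[:20_000]
        sos, se_s = fc.sos_window(sub_f, sub_b, T_KBT, seed=1)
        bar, se_b = fc.bar_window(sub_f, sub_b, T_KBT, n_bootstrap=50, seed=2)
        assert abs(sos - bar) < 3 * np.hypot(se_s, se_b)


class TestBootstrap:
    def test_constant_samples_zero_stderr(self):
        se = fc.bootstrap_stderr(np.full(50, 2.0), np.mean, B=50, seed=0)
        assert se == 0.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        a = fc.bootstrap_stderr(x, np.mean, B=100, seed=7)
        b = fc.bootstrap_stderr(x, np.mean, B=100, seed=7)
        assert a == b

    def test_rejects_too_few_resamples(self):
        with pytest.raises(ValueError, match="B >= 2"):
            fc.bootstrap_stderr(np.ones(5), np.mean, B=1)

    def test_one_over_sqrt_n_scaling(self, gaussian_system):
        # quadrupling n should roughly halve the stderr of the window dG
        run_s = fc.sample_run(gaussian_system, fc.make_lambda_schedule(1), 2000, seed=31)
        run_l = fc.sample_run(gaussian_system, fc.make_lambda_schedule(1), 8000, seed=32)
        est = lambda s: fc.zwanzig(s, T_KBT)
        se_s = fc.bootstrap_stderr(run_s.windows[0].samples_dU, est, B=400, seed=1)
        se_l = fc.bootstrap_stderr(run_l.windows[0].samples_dU, est, B=400, seed=2)
        assert 1.6 < se_s / se_l < 2.4


class TestAccumulate:
    def test_null_mutation_is_zero(self):
        sys_ = fc.ToyAlchemicalSystem("harmonic", k0=2.0, k1=2.0, T=300.0)
        fwd = fc.sample_run(sys_, fc.make_lambda_schedule(4), 200, seed=1)
        bwd = fc.sample_run(sys_, fc.make_lambda_schedule(4, "backward"), 200, seed=2)
        est = fc.accumulate(fwd, bwd, n_bootstrap=10)
        assert est.value == pytest.approx(0.0, abs=1e-10)

    def test_swapping_roles_negates_exactly(self, harmonic_runs):
        fwd, bwd = harmonic_runs
        a = fc.accumulate(fwd, bwd, n_bootstrap=5, seed=1)
        b = fc.accumulate(bwd, fwd, n_bootstrap=5, seed=1)
        assert a.value == pytest.approx(-b.value, abs=1e-12)
        for (l0, l1, g, _), (m0, m1, h, _) in zip(a.per_window, reversed(b.per_window)):
            assert (l0, l1) == (m1, m0)
            assert g == pytest.approx(-h, abs=1e-12)

    def test_value_is_sum_of_windows(self, harmonic_runs):
        fwd, bwd = harmonic_runs
        est = fc.accumulate(fwd, bwd, n_bootstrap=5, seed=0)
        assert est.value == pytest.approx(sum(w[2] for w in est.per_window), abs=1e-9)

    def test_mismatched_schedules_fail_loudly(self, harmonic_system):
        fwd = fc.sample_run(harmonic_system, fc.make_lambda_schedule(4), 100, seed=1)
        bwd = fc.sample_run(harmonic_system, fc.make_lambda_schedule(5, "backward"),
                            100, seed=2)
        with pytest.raises(ValueError, match="schedules do not match"):
            fc.accumulate(fwd, bwd, n_bootstrap=5)

    def test_same_direction_rejected(self, harmonic_system):
        fwd = fc.sample_run(harmonic_system, fc.make_lambda_schedule(4), 100, seed=1)
        with pytest.raises(ValueError, match="opposite directions"):
            _pair_windows(fwd, fwd)

    def test_temperature_mismatch_rejected(self, harmonic_system):
        other = fc.ToyAlchemicalSystem("harmonic", k0=1.0, k1=4.0, T=350.0)
        fwd = fc.sample_run(harmonic_system, fc.make_lambda_schedule(4), 100, seed=1)
        bwd = fc.sample_run(other, fc.make_lambda_schedule(4, "backward"), 100, seed=2)
        with pytest.raises(ValueError, match="[Tt]emperature"):
            fc.accumulate(fwd, bwd, n_bootstrap=5)

    def test_estimator_consistency_sos_bar_zwanzig(self, harmonic_runs):
        # SOS, BAR and the average of the two directional Zwanzig estimates
        # must agree within combined statistical error on good overlap
        fwd, bwd = harmonic_runs
        sos = fc.accumulate(fwd, bwd, "sos", n_bootstrap=50, seed=3)
        bar = fc.accumulate(fwd, bwd, "bar", n_bootstrap=20, seed=4)
        zw_f = sum(fc.zwanzig(w.samples_dU, fwd.T) for w in fwd.windows)
        zw_b = -sum(fc.zwanzig(w.samples_dU, bwd.T) for w in bwd.windows)
        zw_mean = 0.5 * (zw_f + zw_b)
        assert abs(sos.value - bar.value) < 3 * np.hypot(sos.stderr, bar.stderr)
        assert abs(sos.value - zw_mean) < 3 * sos.stderr + 0.01


class TestOverlapDiagnostic:
    def test_identical_distributions_score_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 20_000)
        assert fc.overlap_diagnostic(x, -x) >= 0.98

    def test_disjoint_supports_score_zero(self):
        assert fc.overlap_diagnostic(np.full(100, 10.0), np.full(100, 10.0)) == 0.0

    def test_neighbor_windows_overlap_well(self, harmonic_runs):
        fwd, bwd = harmonic_runs
        bwd_map = {w.interval: w for w in bwd.windows}
        for wf in fwd.windows:
            score = fc.overlap_diagnostic(wf.samples_dU,
                                          bwd_map[wf.interval].samples_dU)
            assert score > 0.5
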