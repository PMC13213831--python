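import numpy as np
import pytest

from neqcycle import (
    SimSpec,
    WorkSet,
    bar,
    gaussian_estimate,
    jarzynski,
    kT,
    sample_works,
)

KT = kT(298.15)


class TestJarzynski:
    def test_single_sample_returns_it(self):
        assert jarzynski([1.5], n_bootstrap=0).value == pytest.approx(1.5, abs=1e-12)

    def test_degenerate_distribution(self):
        est = jarzynski([0.7, 0.7, 0.7], n_bootstrap=0)
        assert est.value == pytest.approx(0.7, abs=1e-12)

    def test_two_sample_closed_form(self):
        # ΔG = −kT ln((1 + e^(−1.185/kT))/2)
        expected = -KT * np.log((1 + np.exp(-1.185 / KT)) / 2)
        est = jarzynski([0.0, 1.185], temperature=298.15, n_bootstrap=0)
        assert est.value == pytest.approx(expected, abs=1e-9)
        assert est.value == pytest.approx(0.3355, abs=2e-4)

    @pytest.mark.parametrize("scale", [1e3, 1e5, -1e5])
    def test_logsumexp_never_overflows(self, scale):
        works = np.array([scale, scale * 0.999, scale * 1.001])
        assert np.isfinite(jarzynski(works, n_bootstrap=0).value)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            jarzynski([])

    def test_bootstrap_uncertainty_is_seeded(self):
        w = np.random.default_rng(1).normal(0, 1, 40)
        a = jarzynski(w, n_bootstrap=200, seed=5)
        b = jarzynski(w, n_bootstrap=200, seed=5)
        assert a.uncertainty == b.uncertainty > 0


class TestGaussian:
    def test_two_sample_formula(self):
        est = gaussian_estimate([1.0, 2.0], n_bootstrap=0)
        assert est.value == pytest.approx(1.5 - 0.5 / (2 * KT), abs=1e-9)

    def test_zero_variance(self):
        assert gaussian_estimate([3.3, 3.3], n_bootstrap=0).value == pytest.approx(3.3)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            gaussian_estimate([1.0])

    def test_unbiased_on_gaussian_works(self):
        # exact in expectation when the work distribution is Gaussian
        ws = sample_works(SimSpec(dG_true=-2.0, dissipation=1.0,
                                  n_forward=10_000, n_reverse=1, seed=3))
        est = gaussian_estimate(ws.forward, n_bootstrap=200, seed=3)
        assert abs(est.value - (-2.0)) < 3 * est.uncertainty


class TestBar:
    def test_constant_work_sets(self):
        ws = WorkSet(np.full(10, 2.0), np.full(10, 0.0))
        assert bar(ws).value == pytest.approx(1.0, abs=1e-8)

    def test_antisymmetry_under_direction_swap(self, crooks_workset):
        ws = crooks_workset
        fwd = bar(ws).value
        rev = bar(WorkSet(ws.reverse, ws.forward, ws.temperature)).value
        assert fwd == pytest.approx(-rev, abs=1e-6)

    def test_shift_covariance(self, crooks_workset):
        ws = crooks_workset
        c = 3.7
        shifted = WorkSet(ws.forward + c, ws.reverse - c, ws.temperature)
        assert bar(shifted).value == pytest.approx(bar(ws).value + c, abs=1e-6)

    def test_recovers_planted_dg_at_default_transition_count(self):
        ws = sample_works(SimSpec(dG_true=-2.0, dissipation=1.0,
                                  n_forward=50, n_reverse=50, seed=17))
        est = bar(ws)
        assert abs(est.value - (-2.0)) < 3 * est.uncertainty

    def test_unequal_sample_counts_supported(self):
        ws = sample_works(SimSpec(dG_true=1.0, dissipation=0.5,
                                  n_forward=80, n_reverse=40, seed=5))
        est = bar(ws)
        assert est.n_forward == 80 and est.n_reverse == 40
        assert abs(est.value - 1.0) < 4 * est.uncertainty

    def test_empty_direction_rejected(self):
        with pytest.raises(ValueError):
            bar(WorkSet(np.array([1.0]), np.array([])))

    def test_bootstrap_uncertainty_agrees_with_analytic(self, crooks_workset):
        a = bar(crooks_workset, uncertainty="analytic")
        b = bar(crooks_workset, uncertainty="bootstrap", n_bootstrap=200, seed=9)
        assert b.uncertainty == pytest.approx(a.uncertainty, rel=0.5)

    def test_finite_and_close_to_directional_jarzynski_bracket(self):
        # all three estimators stay finite on simulator batches, and BAR
        # never strays from the [forward-Jarzynski, negated reverse-
        # Jarzynski] interval by more than a few of its own standard
        # errors (finite-sample noise can break strict bracketing)
        for seed in range(40):
            ws = sample_works(SimSpec(dG_true=-1.0, dissipation=1.0,
                                      n_forward=100, n_reverse=100, seed=seed))
            jf = jarzynski(ws.forward, n_bootstrap=0).value
            jr = -jarzynski(ws.reverse, n_bootstrap=0).value
            g = gaussian_estimate(ws.forward, n_bootstrap=0).value
            est = bar(ws)
            assert all(np.isfinite(v) for v in (jf, jr, g, est.value))
            lo, hi = min(jf, jr), max(jf, jr)
            violation = max(lo - est.value, est.value - hi, 0.0)
            assert violation <= 4 * est.uncertainty

    def test_bias_vanishes_with_sample_size(self):
        # mean signed error over 200 seeds at n=500, dissipation ≤ 2 kT
        errs = []
        for seed in range(200):
            ws = sample_works(SimSpec(dG_true=-2.0, dissipation=2 * KT,
                                      n_forward=500, n_reverse=500, seed=seed))
            errs.append(bar(ws).value - (-2.0))
        assert abs(np.mean(errs)) < 0.05
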