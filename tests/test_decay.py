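import math

import numpy as np
import pytest

from ritfit import (
    FitOptions,
    SimConfig,
    bootstrap_half_life,
    fit_decay,
    grid_search_fit,
    half_life,
    loglinear_init,
    simulate_assay,
)
from ritfit.decay import DecayFit
from ritfit.errors import DegenerateFitError, HalfLifeUndefinedError, InitializationError
from ritfit.io import RITAssay, RITObservation

from conftest import make_exact_assay


def _assay_from_counts(times, counts, initial_count=20):
    return RITAssay(
        "g", "r1",
        [RITObservation(float(t), c) for t, c in zip(times, counts)],
        initial_count=initial_count,
    )


class TestFitDecay:
    @pytest.mark.parametrize("b", [0.02, 0.1, 0.5])
    def test_exact_recovery(self, b):
        """Data generated exactly by the model returns the generating parameters."""
        assay = make_exact_assay(A=20.0, b=b, times=np.arange(0.0, 72.0, 8.0))
        fit = fit_decay(assay)
        assert fit.converged
        assert fit.A_hat == pytest.approx(20.0, abs=1e-8)
        assert fit.b_hat == pytest.approx(b, abs=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_no_decay_is_degenerate(self):
        assay = _assay_from_counts([0, 8, 16, 24], [20, 20, 20, 20])
        with pytest.raises(DegenerateFitError, match="rate not identifiable"):
            fit_decay(assay)

    def test_too_few_observations(self):
        assay = _assay_from_counts([0, 8], [20, 10])
        with pytest.raises(DegenerateFitError):
            fit_decay(assay)

    def test_covariance_is_symmetric_psd_diagonal(self):
        fit = fit_decay(simulate_assay(SimConfig(true_b=0.1, seed=11), "r1"))
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert fit.cov[0, 0] >= 0 and fit.cov[1, 1] >= 0
        assert fit.b_hat >= 0 and fit.A_hat > 0

    def test_matches_grid_search_oracle(self):
        """Trust-region optimum agrees with a dense grid search to 3 decimals."""
        assay = simulate_assay(SimConfig(true_b=0.08, n_intervals=10, seed=1), "r1")
        fit = fit_decay(assay)
        oracle = grid_search_fit(assay)
        assert fit.A_hat == pytest.approx(oracle.A_hat, abs=1e-3)
        assert fit.b_hat == pytest.approx(oracle.b_hat, abs=1e-3)
        assert fit.rss <= oracle.rss + 1e-6

    def test_scale_equivariance(self):
        """Rescaling time by c divides b by c and multiplies rit50 and se by c."""
        assay = simulate_assay(SimConfig(true_b=0.1, seed=21), "r1")
        c = 10.0
        scaled = RITAssay(
            "g", "r1",
            [RITObservation(o.time_s * c, o.intact_count) for o in assay.observations],
            initial_count=assay.initial_count,
            interval_s=assay.interval_s * c,
        )
        f1, f2 = fit_decay(assay), fit_decay(scaled)
        assert f2.b_hat == pytest.approx(f1.b_hat / c, rel=1e-6)
        assert f2.A_hat == pytest.approx(f1.A_hat, rel=1e-6)
        h1 = half_life(f1, 20)
        h2 = half_life(f2, 20)
        assert h2.rit50_s == pytest.approx(h1.rit50_s * c, rel=1e-6)
        assert h2.se_s == pytest.approx(h1.se_s * c, rel=1e-4)


class TestLoglinearInit:
    def test_exact_loglinear_data(self):
        A0, b0 = loglinear_init(make_exact_assay(A=20, b=0.1))
        assert A0 == pytest.approx(20.0, abs=1e-10)
        assert b0 == pytest.approx(0.1, abs=1e-10)

    def test_two_point_closed_form(self):
        A0, b0 = loglinear_init(_assay_from_counts([0, 8], [20, 10]))
        assert A0 == pytest.approx(20.0, rel=1e-12)
        assert b0 == pytest.approx(math.log(2) / 8, rel=1e-12)  # 0.0866434

    def test_zero_counts_excluded(self):
        A0, b0 = loglinear_init(_assay_from_counts([0, 8, 16], [20, 10, 0]))
        assert A0 == pytest.approx(20.0, rel=1e-12)
        assert b0 == pytest.approx(math.log(2) / 8, rel=1e-12)

    def test_too_few_positive_counts(self):
        with pytest.raises(InitializationError):
            loglinear_init(_assay_from_counts([0, 8, 16], [20, 0, 0]))


def _fit(A, b, cov=None):
    return DecayFit(A, b, np.zeros((2, 2)) if cov is None else np.asarray(cov, float),
                    0.0, 9, True)


class TestHalfLife:
    def test_reduces_to_ln2_over_b_when_A_equals_N0(self):
        est = half_life(_fit(20.0, math.log(2) / 8), 20)
        assert est.rit50_s == pytest.approx(8.0, abs=1e-12)

    def test_closed_form_with_A_above_N0(self):
        est = half_life(_fit(22.0, 0.1), 20)
        assert est.rit50_s == pytest.approx(math.log(2.2) / 0.1, rel=1e-12)  # 7.8846

    def test_delta_se_single_free_parameter(self):
        """With var only on b, se = (rit50/b) * sd(b)."""
        est = half_life(_fit(20.0, 0.1, cov=[[0, 0], [0, 0.01**2]]), 20)
        assert est.se_s == pytest.approx(0.6931471805599452, rel=1e-12)
        assert est.ci_low_s == pytest.approx(est.rit50_s - 1.959963984540054 * est.se_s)
        assert est.ci_low_s <= est.rit50_s <= est.ci_high_s

    def test_fitted_definition_ignores_A(self):
        est = half_life(_fit(17.0, 0.1, cov=[[4.0, 0], [0, 0.01**2]]), 20,
                        definition="fitted")
        assert est.rit50_s == pytest.approx(math.log(2) / 0.1)
        assert est.se_s == pytest.approx(0.6931471805599452, rel=1e-12)

    def test_curve_never_reaching_half_is_undefined(self):
        with pytest.raises(HalfLifeUndefinedError, match="never reaches"):
            half_life(_fit(9.0, 0.1), 20)

    def test_zero_rate_is_undefined(self):
        with pytest.raises(HalfLifeUndefinedError):
            half_life(_fit(20.0, 0.0), 20)

    def test_ci_truncated_at_zero(self):
        est = half_life(_fit(20.0, 0.5, cov=[[0, 0], [0, 1.0]]), 20)
        assert est.ci_low_s == 0.0

    def test_monotone_decreasing_in_b(self):
        """Holding A = N0, the half-life strictly decreases as the rate grows."""
        rits = [half_life(_fit(20.0, b), 20).rit50_s for b in np.linspace(0.01, 1, 25)]
        assert all(x > y for x, y in zip(rits, rits[1:]))


class TestBootstrap:
    def test_matches_delta_se_on_model_data(self, exact_assay):
        """Parametric bootstrap SE validates the error-propagation SE (25%)."""
        fit = fit_decay(exact_assay)
        est = half_life(fit, 20)
        se_b, lo, hi = bootstrap_half_life(exact_assay, fit, n_boot=500, seed=7)
        assert se_b == pytest.approx(est.se_s, rel=0.25)
        assert lo < est.rit50_s < hi

    def test_deterministic_given_seed(self, exact_assay):
        fit = fit_decay(exact_assay)
        r1 = bootstrap_half_life(exact_assay, fit, n_boot=200, seed=3)
        r2 = bootstrap_half_life(exact_assay, fit, n_boot=200, seed=3)
        assert r1 == r2

    def test_monte_carlo_stability(self, exact_assay):
        fit = fit_decay(exact_assay)
        se1, *_ = bootstrap_half_life(exact_assay, fit, n_boot=200, seed=5)
        se2, *_ = bootstrap_half_life(exact_assay, fit, n_boot=400, seed=5)
        assert abs(se2 - se1) / se1 < 0.10

    def test_rejects_small_n_boot(self, exact_assay):
        fit = fit_decay(exact_assay)
        with pytest.raises(ValueError):
            bootstrap_half_life(exact_assay, fit, n_boot=50, seed=1)


def test_iid_covariance_option_understates_serial_correlation():
    """The textbook iid covariance is available but much smaller than the
    binomial sandwich on pathwise data (same pods re-counted)."""
    assay = simulate_assay(SimConfig(true_b=0.1, seed=9), "r1")
    sandwich = fit_decay(assay, FitOptions(cov_method="binomial"))
    iid = fit_decay(assay, FitOptions(cov_method="iid"))
    assert sandwich.b_hat == pytest.approx(iid.b_hat, rel=1e-9)
    assert iid.cov[1, 1] < sandwich.cov[1, 1]
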