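"""Causal estimators against closed-form oracles and invariance laws."""

import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from mrlink import (
    EggerRegression,
    IVWEstimator,
    MultivariableIVW,
    WeightedMedianEstimator,
    egger_estimate,
    ivw_estimate,
    multivariable_ivw_estimate,
    ratio_estimates,
    weighted_median,
    weighted_median_estimate,
)

from conftest import make_panel


def wm_grid_oracle(ratios, weights, resolution=1e-6):
    """Independent weighted-median oracle: scan candidate estimates on a
    fine value grid, returning the first whose cumulative-weight position
    reaches one half (plain-Python, loop-based)."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    positions = []
    running = 0.0
    for _, w in pairs:
        positions.append((running + w / 2.0) / total)
        running += w
    values = [v for v, _ in pairs]
    if 0.5 <= positions[0]:
        return values[0]
    if 0.5 >= positions[-1]:
        return values[-1]
    lo, hi = min(values), max(values)
    step = (hi - lo) * resolution
    b = lo
    while b <= hi:
        # position of candidate b on the piecewise-linear cumulative curve
        if b <= values[0]:
            pos = positions[0]
        elif b >= values[-1]:
            pos = positions[-1]
        else:
            for j in range(1, len(values)):
                if values[j] >= b:
                    span = values[j] - values[j - 1]
                    f = 0.0 if span == 0 else (b - values[j - 1]) / span
                    pos = positions[j - 1] + f * (positions[j] - positions[j - 1])
                    break
        if pos >= 0.5:
            return b
        b += step
    return values[-1]


class TestRatioEstimates:
    def test_direct_division(self):
        panel = make_panel([0.1], [0.02], sigma_y=[0.05])
        [(rsid, ratio, se)] = ratio_estimates(panel)
        assert ratio == pytest.approx(0.2)
        assert se == pytest.approx(0.5)

    def test_null_outcome_effect(self):
        panel = make_panel([0.1], [0.0], sigma_y=[0.05])
        [(_, ratio, se)] = ratio_estimates(panel)
        assert ratio == 0.0 and se == pytest.approx(0.5)

    def test_sign_propagation(self):
        panel = make_panel([0.1], [-0.03])
        assert ratio_estimates(panel)[0][1] == pytest.approx(-0.3)


class TestIVW:
    def test_single_snp_reduces_to_ratio(self):
        panel = make_panel([0.2], [0.05], sigma_y=[0.03])
        est = ivw_estimate(panel)
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(0.03 / 0.2)
        assert est.n_snps == 1

    def test_exact_fit_recovers_slope_regardless_of_weights(self):
        gamma = np.array([0.05, 0.1, 0.4, 0.22])
        panel = make_panel(gamma, 0.3 * gamma,
                           sigma_y=[0.01, 0.5, 0.002, 0.07])
        assert ivw_estimate(panel).beta == pytest.approx(0.3, rel=1e-14)

    def test_three_snp_closed_form(self):
        # sum(g*G)/sum(g^2) with equal weights = 0.037 / 0.14
        panel = make_panel([0.1, 0.2, 0.3], [0.03, 0.05, 0.08],
                           sigma_y=np.full(3, 0.01))
        assert ivw_estimate(panel).beta == pytest.approx(0.037 / 0.14, rel=1e-14)

    def test_matches_statsmodels_wls_through_origin(self):
        rng = np.random.default_rng(7)
        gamma = rng.uniform(0.05, 0.5, 8)
        Gamma = 0.2 * gamma + rng.normal(0, 0.02, 8)
        sy = rng.uniform(0.005, 0.05, 8)
        panel = make_panel(gamma, Gamma, sigma_y=sy)
        est = ivw_estimate(panel)
        fit = sm.WLS(Gamma, gamma, weights=sy ** -2.0).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-12)
        # fixed-effect SE is the unit-dispersion WLS standard error
        assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), rel=1e-12)

    def test_random_effects_never_shrinks_se(self):
        rng = np.random.default_rng(8)
        gamma = rng.uniform(0.05, 0.5, 10)
        Gamma = 0.2 * gamma + rng.normal(0, 0.1, 10)
        panel = make_panel(gamma, Gamma, sigma_y=np.full(10, 0.01))
        fixed = ivw_estimate(panel)
        random = ivw_estimate(panel, random_effects=True)
        assert random.beta == fixed.beta
        assert random.se >= fixed.se

    def test_equal_weights_equal_ols_through_origin(self):
        rng = np.random.default_rng(9)
        gamma = rng.uniform(0.05, 0.5, 6)
        Gamma = rng.normal(0, 0.1, 6)
        panel = make_panel(gamma, Gamma, sigma_y=np.full(6, 0.04))
        ols = float(gamma @ Gamma / (gamma @ gamma))
        assert ivw_estimate(panel).beta == pytest.approx(ols, rel=1e-12)


class TestEgger:
    def test_exact_affine_fit(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.45])
        panel = make_panel(gamma, 0.05 + 0.2 * gamma)
        est = egger_estimate(panel)
        assert est.intercept == pytest.approx(0.05, rel=1e-12)
        assert est.beta == pytest.approx(0.2, rel=1e-12)

    def test_duplicated_panel_shrinks_se_by_sqrt2(self):
        gamma = np.array([0.1, 0.2, 0.3])
        panel = make_panel(gamma, 0.05 + 0.2 * gamma)  # zero residual
        double = make_panel(
            np.tile(gamma, 2), 0.05 + 0.2 * np.tile(gamma, 2),
            rsids=[f"rs{j}" for j in range(6)],
        )
        e1, e2 = egger_estimate(panel), egger_estimate(double)
        assert e2.beta == pytest.approx(e1.beta, rel=1e-12)
        assert e2.se == pytest.approx(e1.se / np.sqrt(2), rel=1e-12)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(10)
        gamma = rng.uniform(0.05, 0.5, 9)
        Gamma = 0.03 + 0.15 * gamma + rng.normal(0, 0.05, 9)
        sy = rng.uniform(0.005, 0.05, 9)
        panel = make_panel(gamma, Gamma, sigma_y=sy)
        est = egger_estimate(panel)
        fit = sm.WLS(Gamma, sm.add_constant(gamma), weights=sy ** -2.0).fit()
        assert est.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
        unit_se = fit.bse[1] / np.sqrt(fit.scale)
        assert est.se == pytest.approx(
            unit_se * max(1.0, np.sqrt(fit.scale)), rel=1e-10
        )

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="3"):
            egger_estimate(make_panel([0.1, 0.2], [0.01, 0.02]))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        assert weighted_median(np.array([0.1, 0.2, 0.3]), np.ones(3)) == \
            pytest.approx(0.2)

    def test_degenerate_spread(self):
        panel = make_panel([0.1, 0.2, 0.4], [0.05, 0.1, 0.2],
                           sigma_x=np.full(3, 1e-8), sigma_y=np.full(3, 1e-8))
        est = weighted_median_estimate(panel, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.5)
        assert est.se < 1e-6

    @pytest.mark.parametrize("case", range(4))
    def test_unequal_weights_match_grid_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        ratios = rng.normal(0.2, 0.3, 4)
        weights = rng.uniform(0.1, 5.0, 4)
        ours = weighted_median(ratios, weights)
        oracle = wm_grid_oracle(list(ratios), list(weights))
        assert ours == pytest.approx(oracle, abs=1e-5)

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(11)
        gamma = rng.uniform(0.05, 0.5, 12)
        Gamma = rng.normal(0.0, 0.1, 12)
        panel = make_panel(gamma, Gamma, sigma_x=np.full(12, 0.01),
                           sigma_y=np.full(12, 0.02))
        ratios = Gamma / gamma
        est = weighted_median_estimate(panel, n_boot=200, seed=1)
        assert ratios.min() <= est.beta <= ratios.max()

    def test_bootstrap_reproducible(self):
        panel = make_panel([0.1, 0.2, 0.3, 0.4], [0.03, 0.05, 0.08, 0.1])
        a = weighted_median_estimate(panel, n_boot=300, seed=5)
        b = weighted_median_estimate(panel, n_boot=300, seed=5)
        assert a == b


class TestMultivariableIVW:
    def test_zero_second_exposure_reduces_to_univariable(self):
        rng = np.random.default_rng(12)
        gamma = rng.uniform(0.05, 0.5, 6)
        Gamma = 0.2 * gamma + rng.normal(0, 0.02, 6)
        sy = rng.uniform(0.01, 0.05, 6)
        est_uni = ivw_estimate(make_panel(gamma, Gamma, sigma_y=sy))
        est_mv = multivariable_ivw_estimate(
            np.column_stack([gamma, np.zeros(6)]), Gamma, sy,
            ["x1", "x2"], "x1",
        )
        assert est_mv.beta == pytest.approx(est_uni.beta, rel=1e-10)

    def test_exact_linear_model_recovered(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0.05, 0.5, size=(8, 2))
        y = 0.6 * X[:, 0] - 0.2 * X[:, 1]
        est = MultivariableIVW().fit(X, y, y_se=np.full(8, 0.01),
                                     exposure_names=["a", "b"])
        assert est.coef_ == pytest.approx([0.6, -0.2], rel=1e-12)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(0.05, 0.5, size=(10, 3))
        y = X @ np.array([0.5, -0.1, 0.3]) + rng.normal(0, 0.05, 10)
        sy = rng.uniform(0.005, 0.05, 10)
        est = MultivariableIVW().fit(X, y, y_se=sy ** 1.0)
        fit = sm.WLS(y, X, weights=sy ** -2.0).fit()
        assert est.coef_ == pytest.approx(fit.params, rel=1e-10)

    def test_rank_deficiency_names_collinear_exposures(self):
        X = np.column_stack([np.arange(1.0, 6.0), 2.0 * np.arange(1.0, 6.0)])
        with pytest.raises(np.linalg.LinAlgError, match="hdl.*ldl|ldl.*hdl"):
            MultivariableIVW().fit(X, np.ones(5), y_se=np.full(5, 0.1),
                                   exposure_names=["hdl", "ldl"])

    def test_needs_more_snps_than_exposures(self):
        X = np.ones((2, 2)) + np.eye(2)
        with pytest.raises(ValueError):
            MultivariableIVW().fit(X, np.ones(2), y_se=np.full(2, 0.1))


@pytest.mark.parametrize("c", [0.5, 3.0])
def test_outcome_scale_equivariance(c):
    """Multiplying all outcome betas and SEs by c scales every estimator's
    beta and SE by c."""
    rng = np.random.default_rng(15)
    gamma = rng.uniform(0.05, 0.5, 8)
    Gamma = 0.2 * gamma + rng.normal(0, 0.02, 8)
    sy = rng.uniform(0.01, 0.05, 8)
    base = make_panel(gamma, Gamma, sigma_y=sy)
    scaled = make_panel(gamma, c * Gamma, sigma_y=c * sy)
    for fn in (ivw_estimate, egger_estimate):
        e0, e1 = fn(base), fn(scaled)
        assert e1.beta == pytest.approx(c * e0.beta, rel=1e-10)
        assert e1.se == pytest.approx(c * e0.se, rel=1e-10)
    w0 = weighted_median_estimate(base, n_boot=200, seed=2)
    w1 = weighted_median_estimate(scaled, n_boot=200, seed=2)
    assert w1.beta == pytest.approx(c * w0.beta, rel=1e-10)


def test_sklearn_api_compat():
    est = IVWEstimator(random_effects=True)
    assert est.get_params() == {"random_effects": True}
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    wm = WeightedMedianEstimator(n_boot=500, random_state=3)
    assert clone(wm).get_params()["n_boot"] == 500
    est.set_params(random_effects=False)
    assert est.random_effects is False
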