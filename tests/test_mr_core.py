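"""Univariable MR estimators: hand-derived values, oracle equivalences,
invariances and bootstrap reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proxymr.mr_core import (
    _kde_mode,
    _weighted_median,
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.25, 0.05, 0.5, 0.1)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.4)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.25, 0.05, 0.0, 0.1).beta == 0.0

    def test_negative_exposure_flips_sign(self):
        assert wald_ratio(-0.25, 0.05, 0.5, 0.1).beta == pytest.approx(-2.0)

    def test_zero_exposure_is_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.05, 0.5, 0.1)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = make_harmonized([0.25], 0.05, [0.5], 0.1)
        est = ivw(h)
        ref = wald_ratio(0.25, 0.05, 0.5, 0.1)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_two_snp_hand_arithmetic(self):
        h = make_harmonized([1.0, 1.0], 0.05, [1.0, 3.0], 1.0)
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / np.sqrt(2))
        assert est.q_stat == pytest.approx(2.0)

    def test_zero_heterogeneity_random_equals_fixed(self):
        h = make_harmonized([0.2, 0.4, 0.5], 0.05, [0.3, 0.6, 0.75], [0.1, 0.2, 0.3])
        fx = ivw(h, model="fixed")
        re = ivw(h, model="multiplicative_random")
        assert fx.q_stat == pytest.approx(0.0, abs=1e-12)
        assert re.se == pytest.approx(fx.se)
        assert re.beta == pytest.approx(1.5)

    def test_zero_exposure_beta_lists_rsids(self):
        h = make_harmonized([0.2, 0.0], 0.05, [0.3, 0.1], 0.1)
        with pytest.raises(ZeroDivisionError, match="rs2"):
            ivw(h)

    def test_equals_zero_intercept_wls_oracle(self):
        """IVW must coincide with weighted least squares of beta_y on
        beta_x (no intercept, weights 1/se_y²) to 1e-10."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        h = make_harmonized(
            rng.uniform(0.1, 0.5, 12), rng.uniform(0.01, 0.05, 12),
            rng.normal(0.1, 0.2, 12), rng.uniform(0.05, 0.2, 12),
        )
        fit = sm.WLS(h.beta_y, h.beta_x, weights=1.0 / h.se_y**2).fit()
        assert ivw(h).beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_inflates_se_under_heterogeneity(self):
        h = make_harmonized([1, 1, 1, 1], 0.05, [0.5, 1.5, 3.0, 5.0], 0.2)
        assert ivw(h, "multiplicative_random").se > ivw(h, "fixed").se


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.05, 2.0 + 1.0 * bx, [0.1, 0.2, 0.15, 0.1])
        est = egger(h)
        assert est.beta == pytest.approx(1.0, abs=1e-10)
        assert est.intercept == pytest.approx(2.0, abs=1e-10)
        assert est.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_equals_wls_with_intercept_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.5, 15)
        h = make_harmonized(bx, 0.02, rng.normal(0.5 * bx + 0.01, 0.1),
                            rng.uniform(0.05, 0.2, 15))
        X = sm.add_constant(h.beta_x)
        fit = sm.WLS(h.beta_y, X, weights=1.0 / h.se_y**2).fit()
        est = egger(h)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        # same sandwich-free WLS covariance under the same scale convention
        scale = max(1.0, fit.scale * fit.df_resid / (len(bx) - 2))
        assert est.se == pytest.approx(fit.bse[1] * np.sqrt(scale / fit.scale), rel=1e-8)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.5, 8)
        by = rng.normal(0.8 * bx, 0.05)
        h1 = make_harmonized(bx, 0.02, by, 0.1)
        bx2, by2 = bx.copy(), by.copy()
        bx2[0], by2[0] = -bx2[0], -by2[0]
        h2 = make_harmonized(bx2, 0.02, by2, 0.1)
        assert egger(h1).beta == pytest.approx(egger(h2).beta, rel=1e-12)

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            egger(make_harmonized([0.1, 0.2], 0.02, [0.1, 0.2], 0.1))

    def test_intercept_calibrated_under_inside_null(self):
        """With balanced pleiotropy independent of instrument strength
        (InSIDE holds, intercept truth 0), the intercept estimate lies
        within 3 SE of zero in >= 95% of replicates."""
        rng = np.random.default_rng(42)
        n_snp, covered = 25, 0
        reps = 500
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.6, n_snp)
            alpha = rng.normal(0.0, 0.05, n_snp)
            se_y = np.full(n_snp, 0.05)
            by = alpha + 1.0 * bx + rng.normal(0, se_y)
            est = egger(make_harmonized(bx, 0.02, by, se_y))
            covered += abs(est.intercept) <= 3 * est.intercept_se
        assert covered / reps >= 0.95


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        assert _weighted_median(np.array([1.0, 2.0, 9.0]), np.ones(3)) == pytest.approx(2.0)

    def test_dominant_weight_hand_interpolation(self):
        r = np.array([5.0, 1.0, 2.0])
        w = np.array([0.98, 0.01, 0.01])
        # sorted ratios (1,2,5), cumulative midpoints (.005,.015,.51):
        # interpolate 0.5 between 2 and 5 -> 2 + (0.485/0.495)*3
        expected = 2 + (0.5 - 0.015) / (0.51 - 0.015) * 3
        assert _weighted_median(r, w) == pytest.approx(expected)
        assert _weighted_median(r, w) == pytest.approx(5.0, abs=0.15)

    def test_identical_ratios_any_weights(self):
        assert _weighted_median(np.full(5, 3.3), np.array([5, 1, 1, 1, 9.0])) == pytest.approx(3.3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=11).filter(lambda v: len(v) % 2 == 1))
    def test_equal_weights_equals_sample_median_odd_n(self, ratios):
        r = np.asarray(ratios)
        assert _weighted_median(r, np.ones(len(r))) == pytest.approx(np.median(r), abs=1e-12)

    def test_estimator_on_harmonized_set(self):
        h = make_harmonized([1, 1, 1], 0.02, [1.0, 2.0, 9.0], 1.0)
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(2.0)
        assert est.se > 0

    def test_bootstrap_seed_reproducibility(self):
        h = make_harmonized([0.2, 0.3, 0.4, 0.5], 0.02, [0.3, 0.4, 0.7, 0.9], 0.1)
        a = weighted_median(h, n_boot=300, seed=99)
        b = weighted_median(h, n_boot=300, seed=99)
        assert a.se == b.se


class TestMode:
    def test_cluster_dominates_outlier(self):
        h = make_harmonized([1, 1, 1, 1], 0.02, [1.0, 1.01, 0.99, 5.0], 0.1)
        est = mode_estimate(h, "simple", n_boot=50, seed=0)
        assert est.beta == pytest.approx(1.0, abs=0.05)

    def test_kde_argmax_matches_dense_grid_oracle(self):
        ratios = np.array([1.0, 1.01, 0.99, 5.0])
        w = np.ones(4)
        got = _kde_mode(ratios, w, phi=1.0)
        # independent oracle: brute-force argmax on a 20x denser grid
        n = len(ratios)
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.349) * n ** (-0.2)
        grid = np.linspace(ratios.min() - h, ratios.max() + h, 10240)
        dens = sum(np.exp(-0.5 * ((grid - r) / h) ** 2) for r in ratios)
        assert got == pytest.approx(grid[np.argmax(dens)], abs=2 * (grid[1] - grid[0]) + 0.02)

    def test_identical_ratios_return_common_value(self):
        h = make_harmonized([1, 1, 1], 0.02, [2.0, 2.0, 2.0], 0.1)
        assert mode_estimate(h, "simple", n_boot=50, seed=0).beta == pytest.approx(2.0)

    def test_weighted_pulled_toward_heavy_outlier(self):
        bx = np.array([0.1, 0.1, 0.1, 1.0])  # outlier carries ~100x weight
        by = np.array([0.1, 0.101, 0.099, 3.0])
        h = make_harmonized(bx, 0.02, by, 0.1)
        simple = mode_estimate(h, "simple", n_boot=50, seed=0).beta
        weighted = mode_estimate(h, "weighted", n_boot=50, seed=0).beta
        assert weighted > simple

    def test_phi_must_be_positive(self):
        h = make_harmonized([1, 1, 1], 0.02, [1, 2, 3], 0.1)
        with pytest.raises(ValueError):
            mode_estimate(h, "simple", phi=0.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.floats(0.1, 10.0))
def test_scale_equivariance_all_estimators(c):
    """Multiplying all outcome betas (and SEs) by c scales every
    estimator's beta and se by c."""
    rng = np.random.default_rng(8)
    bx = rng.uniform(0.1, 0.5, 7)
    by = rng.normal(0.5 * bx, 0.1)
    sy = rng.uniform(0.05, 0.2, 7)
    h1 = make_harmonized(bx, 0.02, by, sy)
    h2 = make_harmonized(bx, 0.02, c * by, c * sy)
    for fn in (
        lambda h: ivw(h),
        lambda h: egger(h),
        lambda h: weighted_median(h, n_boot=100, seed=4),
        lambda h: mode_estimate(h, "weighted", n_boot=100, seed=4),
    ):
        e1, e2 = fn(h1), fn(h2)
        assert e2.beta == pytest.approx(c * e1.beta, rel=1e-6, abs=1e-9)
        assert e2.se == pytest.approx(c * e1.se, rel=1e-6, abs=1e-9)
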