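"""Confidence bands, sup-t critical values and root intervals."""

import numpy as np
import pytest
from scipy import stats

import trtselect as ts
from trtselect.bands import (
    DegenerateRootError,
    effect_roots,
    pointwise_band,
    root_cis_delta,
    scheffe_bound,
    simultaneous_band,
    simultaneous_critical_value,
)

LEVELS = (0.5, 0.8, 0.9, 0.95, 0.99)
FAST = dict(draws=20_000)


class TestPointwiseBand:
    def test_halfwidth_is_critical_value_times_se(self, fitted_s1):
        band = pointwise_band(fitted_s1, 0.95)
        x = np.linspace(0, 1, 11)
        est, se = fitted_s1.predict_effect(x)
        assert np.allclose(band.upper(x) - est, band.critical_value * se)
        assert np.allclose(est - band.lower(x), band.critical_value * se)

    def test_level_zero_collapses_to_estimate(self, fitted_s1):
        band = pointwise_band(fitted_s1, 0.0)
        assert band.critical_value == 0.0
        est, _ = fitted_s1.predict_effect(0.3)
        assert band.lower(0.3) == band.upper(0.3) == pytest.approx(est)

    def test_critical_value_is_t_quantile(self, fitted_s1):
        band = pointwise_band(fitted_s1, 0.95)
        assert band.critical_value == pytest.approx(
            stats.t.ppf(0.975, fitted_s1.df_resid)
        )

    def test_monotone_in_level(self, fitted_s1):
        widths = [
            pointwise_band(fitted_s1, lev).critical_value for lev in LEVELS
        ]
        assert np.all(np.diff(widths) > 0)


class TestSimultaneousBand:
    def test_bracketed_by_pointwise_and_scheffe(self, fitted_s1, fitted_s3):
        for res in (fitted_s1, fitted_s3):
            c = simultaneous_critical_value(res, 0.95, **FAST)
            assert pointwise_band(res, 0.95).critical_value <= c
            assert c <= scheffe_bound(res, 0.95)

    def test_singleton_domain_recovers_pointwise_quantile(self, fitted_s1):
        c = simultaneous_critical_value(
            fitted_s1, 0.95, domain=(0.4, 0.4), grid_size=1, **FAST
        )
        # sup over one point; z vs t_{1496} differ only in the 3rd decimal
        assert c == pytest.approx(
            pointwise_band(fitted_s1, 0.95).critical_value, abs=0.02
        )

    def test_simultaneous_lower_below_pointwise_lower(self, fitted_s1):
        x = np.linspace(0, 1, 101)
        ls = simultaneous_band(fitted_s1, 0.95, **FAST).lower(x)
        lp = pointwise_band(fitted_s1, 0.95).lower(x)
        assert np.all(ls <= lp + 1e-12)

    def test_symmetric_about_estimate(self, fitted_s3):
        band = simultaneous_band(fitted_s3, 0.9, **FAST)
        x = np.linspace(0, 1, 21)
        est, _ = fitted_s3.predict_effect(x)
        assert np.allclose(band.upper(x) - est, est - band.lower(x))

    def test_monotone_in_level(self, fitted_s3):
        cs = [
            simultaneous_critical_value(fitted_s3, lev, **FAST)
            for lev in LEVELS
        ]
        assert np.all(np.diff(cs) > 0)

    def test_deterministic_given_fixed_subseed(self, fitted_s1):
        a = simultaneous_critical_value(fitted_s1, 0.95, **FAST)
        b = simultaneous_critical_value(fitted_s1, 0.95, **FAST)
        assert a == b

    def test_invalid_level_rejected(self, fitted_s1):
        with pytest.raises(ValueError):
            simultaneous_critical_value(fitted_s1, 1.0)


class TestRootCIs:
    def test_linear_delta_example(self, stub_results):
        # g = (-0.4, 0.8): root 0.5; gradient (-1/g1, g0/g1^2) = (-1.25, -0.625)
        res = stub_results([-0.4, 0.8], np.diag([0.01, 0.04]))
        (ci,) = root_cis_delta(res, 0.95)
        assert ci.root == pytest.approx(0.5)
        assert ci.se == pytest.approx(0.17678, abs=5e-6)

    def test_delta_se_matches_finite_difference_oracle(self, stub_results):
        rng = np.random.default_rng(17)
        for _ in range(30):
            d = rng.integers(2, 4)
            g = rng.normal(size=d)
            A = rng.normal(size=(d, d)) * 0.1
            Sigma = A @ A.T + 1e-6 * np.eye(d)
            res = stub_results(g, Sigma)
            try:
                cis = root_cis_delta(res, 0.95, domain=(-10, 10))
            except DegenerateRootError:
                continue
            for ci in cis:
                h = 1e-7
                grad_fd = np.empty(d)
                for k in range(d):
                    gp, gm = g.copy(), g.copy()
                    gp[k] += h
                    gm[k] -= h
                    rp = min(effect_roots(gp), key=lambda r: abs(r - ci.root))
                    rm = min(effect_roots(gm), key=lambda r: abs(r - ci.root))
                    grad_fd[k] = (rp - rm) / (2 * h)
                se_fd = np.sqrt(grad_fd @ Sigma @ grad_fd)
                assert ci.se == pytest.approx(se_fd, rel=1e-5)

    def test_zero_variance_collapses_to_point(self, stub_results):
        res = stub_results([-0.5, 1.0], np.zeros((2, 2)))
        (ci,) = root_cis_delta(res, 0.95)
        assert (ci.lower, ci.root, ci.upper) == pytest.approx((0.5, 0.5, 0.5))

    def test_negative_discriminant_gives_no_roots(self, stub_results):
        res = stub_results([0.5, 0.0, 0.1], 0.01 * np.eye(3))
        assert root_cis_delta(res, 0.95) == []

    def test_roots_outside_domain_dropped(self, stub_results):
        res = stub_results([-1.5, 1.0], 0.01 * np.eye(2))  # root at 1.5
        assert root_cis_delta(res, 0.95) == []

    def test_degenerate_double_root_raises(self, stub_results):
        res = stub_results([0.25, -1.0, 1.0], 0.01 * np.eye(3))  # (x-0.5)^2
        with pytest.raises(DegenerateRootError):
            root_cis_delta(res, 0.95)

    def test_interval_clipped_to_domain(self, stub_results):
        res = stub_results([-0.05, 0.1], np.diag([0.5, 0.5]))  # huge SE
        (ci,) = root_cis_delta(res, 0.95)
        assert ci.lower == 0.0 and ci.upper == 1.0

    def test_monotone_in_level(self, stub_results):
        res = stub_results([-0.4, 0.8], np.diag([0.01, 0.04]))
        widths = [
            root_cis_delta(res, lev)[0].upper - root_cis_delta(res, lev)[0].lower
            for lev in LEVELS
        ]
        assert np.all(np.diff(widths) > 0)


class TestHorizontalInversion:
    def test_band_never_crossing_threshold_gives_empty_set(self, stub_results):
        res = stub_results([1.0, 0.5], 1e-6 * np.eye(2))
        band = pointwise_band(res, 0.95)
        assert ts.invert_band_horizontally(band, 0.0).is_empty

    def test_poi_equals_est_minus_horizontal_inversion(self, fitted_s1, fitted_s3):
        # set identity {l_p >= 0} = {theta_hat >= 0} \ {band covers 0}
        for res in (fitted_s1, fitted_s3):
            band = pointwise_band(res, 0.95)
            poi = ts.rule_band(band)
            est = ts.rule_est(res)
            inv = ts.invert_band_horizontally(band, 0.0)
            identity = est.difference(inv)
            grid = np.linspace(0, 1, 2001)
            a = np.array([poi.contains(x, atol=1e-8) for x in grid])
            b = np.array([identity.contains(x, atol=1e-8) for x in grid])
            assert np.mean(a != b) < 2e-3  # disagreement only at boundaries


# ---------------------------------------------------------------------
# Monte Carlo coverage of the band machinery (shared replicates)
# ---------------------------------------------------------------------
class TestCoverage:
    def test_pointwise_coverage_at_fixed_x(self, s1_montecarlo):
        cover = s1_montecarlo["pointwise_cover_025"].mean()
        se = np.sqrt(0.95 * 0.05 / len(s1_montecarlo["pointwise_cover_025"]))
        assert abs(cover - 0.95) <= 3 * se

    def test_simultaneous_coverage_over_domain(self, s1_montecarlo):
        cover = s1_montecarlo["simultaneous_cover"].mean()
        assert 0.94 <= cover <= 0.97

    def test_simultaneous_at_least_pointwise_coverage(self, s1_montecarlo):
        assert (
            s1_montecarlo["simultaneous_cover"].mean()
            >= s1_montecarlo["pointwise_cover_025"].mean() - 0.01
        )

    def test_root_ci_covers_true_root(self, s1_montecarlo):
        cover = s1_montecarlo["root_ci_covers"].mean()
        assert 0.93 <= cover <= 0.97

    def test_horizontal_inversion_covers_true_root(self, s1_montecarlo):
        cover = s1_montecarlo["horizontal_covers"].mean()
        assert 0.93 <= cover <= 0.97
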