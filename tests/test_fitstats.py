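"""Lack-of-fit F-test, r-squared and confidence bands.

The lack-of-fit test is checked against a brute-force oracle that
enumerates replicate groups and sums squares directly.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from phagekit.errors import InputError, NotApplicableError
from phagekit.fitstats import (
    ReplicatedSeries,
    confidence_band,
    lack_of_fit_test,
    r_squared,
)
from phagekit.growth import fit_4pl, four_pl
from phagekit.synthetic import gen_osgc


def brute_force_lof(x, y, fitted_at_points, n_params):
    """Independent SS decomposition by direct group enumeration."""
    pts = sorted(set(x))
    ss_pe = 0.0
    ss_lof = 0.0
    for p, fhat in zip(pts, fitted_at_points):
        group = [yi for xi, yi in zip(x, y) if xi == p]
        mean = sum(group) / len(group)
        ss_pe += sum((yi - mean) ** 2 for yi in group)
        ss_lof += len(group) * (mean - fhat) ** 2
    return ss_pe, ss_lof, len(pts) - n_params, len(y) - len(pts)


class TestLackOfFit:
    def test_hand_worked_decomposition(self):
        # groups {0,2} at x=0 and {1,3} at x=1, constant model 1.5
        data = ReplicatedSeries(np.array([0.0, 0, 1, 1]), np.array([0.0, 2, 1, 3]))
        res = lack_of_fit_test(data, np.array([1.5, 1.5]), n_params=1)
        assert res.ss_pe == pytest.approx(4.0)
        assert res.df_pe == 2
        assert res.ss_lof == pytest.approx(1.0)
        assert res.df_lof == 1
        assert res.f_ratio == pytest.approx(0.5)

    def test_fitted_equal_group_means_gives_zero_lof(self):
        data = ReplicatedSeries(np.array([0.0, 0, 1, 1]), np.array([0.0, 2, 1, 3]))
        res = lack_of_fit_test(data, np.array([1.0, 2.0]), n_params=1)
        assert res.ss_lof == 0.0
        assert res.f_ratio == 0.0
        assert res.no_lack_of_fit

    def test_exact_fit_degenerate(self):
        data = ReplicatedSeries(np.array([0.0, 0, 1, 1]), np.array([1.0, 1, 2, 2]))
        res = lack_of_fit_test(data, np.array([1.0, 2.0]), n_params=1)
        assert res.degenerate
        assert np.isnan(res.f_ratio)

    def test_no_replication_not_applicable(self):
        data = ReplicatedSeries(np.array([0.0, 1, 2]), np.array([1.0, 2, 3]))
        with pytest.raises(NotApplicableError):
            lack_of_fit_test(data, np.array([1.0, 2, 3]), n_params=1)

    def test_overparameterized_not_applicable(self):
        data = ReplicatedSeries(np.array([0.0, 0, 1, 1]), np.array([0.0, 2, 1, 3]))
        with pytest.raises(NotApplicableError):
            lack_of_fit_test(data, np.array([1.0, 2.0]), n_params=2)

    def test_f_critical_and_p_value_consistency(self):
        data = ReplicatedSeries(
            np.repeat(np.arange(5.0), 3), np.arange(15.0) % 4 + np.repeat(np.arange(5.0), 3)
        )
        res = lack_of_fit_test(data, np.arange(5.0) + 1.4, n_params=2)
        assert res.f_critical == pytest.approx(stats.f.ppf(0.95, res.df_lof, res.df_pe))
        assert res.p_value + stats.f.cdf(res.f_ratio, res.df_lof, res.df_pe) == pytest.approx(
            1.0, abs=1e-9
        )

    @given(st.data())
    def test_agrees_with_brute_force_oracle(self, data):
        n_points = data.draw(st.integers(3, 6))
        reps = [data.draw(st.integers(1, 4)) for _ in range(n_points)]
        if sum(reps) <= n_points:
            reps[0] += 2
        xs, ys = [], []
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        for i, r in enumerate(reps):
            xs.extend([float(i)] * r)
            ys.extend(rng.normal(i, 1.0, size=r).tolist())
        fitted = rng.normal(0, 1, size=n_points)
        n_params = data.draw(st.integers(1, n_points - 1))
        series = ReplicatedSeries(np.array(xs), np.array(ys))
        res = lack_of_fit_test(series, fitted, n_params)
        ss_pe, ss_lof, df_lof, df_pe = brute_force_lof(xs, ys, fitted, n_params)
        assert res.ss_pe == pytest.approx(ss_pe, rel=1e-9, abs=1e-12)
        assert res.ss_lof == pytest.approx(ss_lof, rel=1e-9, abs=1e-12)
        assert (res.df_lof, res.df_pe) == (df_lof, df_pe)
        # conservation: ss_lof + ss_pe equals total residual SS about fitted values
        fitted_full = np.array([fitted[int(x)] for x in xs])
        total = float(((np.array(ys) - fitted_full) ** 2).sum())
        assert res.ss_lof + res.ss_pe == pytest.approx(total, rel=1e-9)


class TestRSquared:
    def test_reference_values(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestConfidenceBand:
    @staticmethod
    def _predict(t, theta):
        return four_pl(t, *theta)

    def test_noise_free_band_collapses(self):
        curve = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.0, n_reps=1)
        fit = fit_4pl(curve)
        band = confidence_band(self._predict, fit.params, fit.cov, np.linspace(0, 90, 10))
        assert np.all(band["upper"] - band["lower"] < 1e-6)

    def test_level_zero_band_has_zero_width(self):
        curve = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.05, n_reps=3, rng=3)
        fit = fit_4pl(curve)
        band = confidence_band(self._predict, fit.params, fit.cov, [10.0, 30.0], level=0.0)
        np.testing.assert_allclose(band["upper"], band["lower"])

    def test_95_band_covers_generating_curve(self):
        truth = (4.0, 6.0, 30.0, 8.0)
        t_eval = np.linspace(0, 90, 19)
        true_curve = four_pl(t_eval, *truth)
        covered = total = 0
        for seed in range(50):
            curve = gen_osgc(*truth, noise_sd=0.05, n_reps=3, rng=seed)
            fit = fit_4pl(curve)
            band = confidence_band(self._predict, fit.params, fit.cov, t_eval)
            covered += int(np.sum((band["lower"] <= true_curve) & (true_curve <= band["upper"])))
            total += t_eval.size
        assert covered / total >= 0.90

    def test_bootstrap_fallback_on_singular_covariance(self):
        curve = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.05, n_reps=3, rng=11)
        fit = fit_4pl(curve)

        def refit(x, y):
            from phagekit.growth import GrowthCurve

            return fit_4pl(GrowthCurve(x, y)).params

        bad_cov = np.full((4, 4), np.nan)
        with pytest.warns(UserWarning, match="bootstrap"):
            band = confidence_band(
                self._predict, fit.params, bad_cov, [20.0, 40.0],
                refit=refit, data=(curve.times_min, curve.log_titers), n_boot=19,
            )
        assert band["method"] == "bootstrap"
        assert np.all(band["upper"] >= band["lower"])
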