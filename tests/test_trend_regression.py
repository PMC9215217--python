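"""Seasonal-trend regression on pairwise distances."""

import numpy as np
import pytest

from oceanot import (
    DepthAxis,
    DistanceMatrix,
    ProbabilityField,
    fit_seasonal_trend,
    month_lag_features,
    reference_distance_series,
    slope_ratio,
)
from oceanot.trend_regression import peak_months

BETA2 = np.array([0.2, 0.1, 0.0, -0.05, -0.1, -0.1, -0.05])


def month_range(start, n):
    y0, m0 = start
    return [(y0 + (m0 - 1 + t) // 12, (m0 - 1 + t) % 12 + 1) for t in range(n)]


def synthetic_D(dates, beta0, beta1, beta2, noise=0.0, rng=None):
    n = len(dates)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            f = month_lag_features(dates[a], dates[b])
            D[a, b] = beta0 + beta1 * f.total_lag + beta2[f.calendar_lag]
            if noise > 0:
                D[a, b] += rng.normal(0.0, noise)
            D[a, b] = max(D[a, b], 0.0)
            D[b, a] = D[a, b]
    return DistanceMatrix(tuple(range(n)), D)


class TestMonthLagFeatures:
    @pytest.mark.parametrize(
        "a, b, total, calendar",
        [
            ((1998, 1), (1998, 3), 2, 2),
            ((1998, 1), (1998, 12), 11, 1),
            ((1998, 5), (1998, 5), 0, 0),
            ((1998, 1), (2000, 1), 24, 0),
            ((1998, 1), (1999, 7), 18, 6),
            ((2001, 10), (1998, 2), 44, 4),
        ],
    )
    def test_lags(self, a, b, total, calendar):
        f = month_lag_features(a, b)
        assert (f.total_lag, f.calendar_lag) == (total, calendar)

    def test_symmetry_and_fold_range(self, rng):
        for _ in range(50):
            a = (int(rng.integers(1990, 2010)), int(rng.integers(1, 13)))
            b = (int(rng.integers(1990, 2010)), int(rng.integers(1, 13)))
            f, g = month_lag_features(a, b), month_lag_features(b, a)
            assert (f.total_lag, f.calendar_lag) == (g.total_lag, g.calendar_lag)
            assert 0 <= f.calendar_lag <= 6
            # folded lag is congruent to the total lag on the 12-month circle
            assert min(f.total_lag % 12, 12 - f.total_lag % 12) == f.calendar_lag


class TestFitSeasonalTrend:
    def test_noiseless_recovery(self):
        dates = month_range((1998, 1), 36)
        D = synthetic_D(dates, 1.0, 0.01, BETA2)
        fit = fit_seasonal_trend(D, dates)
        assert fit.beta0 == pytest.approx(1.0, abs=1e-8)
        assert fit.beta1 == pytest.approx(0.01, abs=1e-8)
        np.testing.assert_allclose(fit.beta2, BETA2, atol=1e-8)
        assert abs(fit.beta2.sum()) < 1e-10

    def test_constant_distance_gives_flat_fit(self):
        dates = month_range((1998, 1), 24)
        D = synthetic_D(dates, 0.7, 0.0, np.zeros(7))
        fit = fit_seasonal_trend(D, dates)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.beta2, 0.0, atol=1e-10)

    def test_pure_trend(self):
        dates = month_range((1998, 1), 24)
        D = synthetic_D(dates, 0.0, 0.01, np.zeros(7))
        fit = fit_seasonal_trend(D, dates)
        assert fit.beta1 == pytest.approx(0.01, abs=1e-10)
        np.testing.assert_allclose(fit.beta2, 0.0, atol=1e-10)

    def test_projection_idempotence(self, rng):
        dates = month_range((1998, 3), 30)
        D = synthetic_D(dates, 1.0, 0.02, BETA2, noise=0.1, rng=rng)
        fit = fit_seasonal_trend(D, dates)
        fitted = np.zeros_like(D.D)
        n = len(dates)
        for a in range(n):
            for b in range(a + 1, n):
                f = month_lag_features(dates[a], dates[b])
                fitted[a, b] = fitted[b, a] = fit.predict(f.total_lag, f.calendar_lag)
        refit = fit_seasonal_trend(DistanceMatrix(tuple(range(n)), fitted), dates)
        assert refit.beta0 == pytest.approx(fit.beta0, abs=1e-10)
        assert refit.beta1 == pytest.approx(fit.beta1, abs=1e-10)
        np.testing.assert_allclose(refit.beta2, fit.beta2, atol=1e-10)

    def test_beta1_coverage_under_noise(self, rng):
        # noise sized for R^2 near 0.8; beta1-hat within 3 SE of truth >= 95%
        dates = month_range((1998, 1), 36)
        signal = synthetic_D(dates, 1.0, 0.01, BETA2).D
        iu = np.triu_indices(len(dates), 1)
        sigma = float(np.std(signal[iu]) / 2.0)  # var ratio 4:1 -> R^2 ~ 0.8
        hits = 0
        for _ in range(200):
            D = synthetic_D(dates, 1.0, 0.01, BETA2, noise=sigma, rng=rng)
            fit = fit_seasonal_trend(D, dates)
            if abs(fit.beta1 - 0.01) <= 3.0 * fit.se_beta1:
                hits += 1
        assert hits >= 190

    def test_too_few_pairs_rejected(self):
        dates = month_range((1998, 1), 3)
        D = synthetic_D(dates, 1.0, 0.0, np.zeros(7))
        with pytest.raises(ValueError, match="9 pairs"):
            fit_seasonal_trend(D, dates)

    def test_rank_deficient_design_names_missing_levels(self):
        # same calendar month every year: calendar lag always 0 -> singular
        dates = [(1998 + t, 6) for t in range(6)]
        D = synthetic_D(dates, 1.0, 0.01, np.zeros(7))
        with pytest.raises(ValueError, match="lags"):
            fit_seasonal_trend(D, dates)


class TestSlopeRatio:
    def _fit(self, beta1):
        dates = month_range((1998, 1), 24)
        return fit_seasonal_trend(synthetic_D(dates, 1.0, beta1, BETA2), dates)

    def test_identical_fits_ratio_one(self):
        f = self._fit(0.01)
        assert slope_ratio(f, f) == pytest.approx(1.0)

    def test_ratio_of_slopes(self):
        assert slope_ratio(self._fit(0.0085), self._fit(0.001)) == pytest.approx(
            8.5, rel=1e-6
        )

    def test_negative_denominator_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            r = slope_ratio(self._fit(0.005), self._fit(-0.005))
        assert r == pytest.approx(-1.0, rel=1e-6)

    def test_zero_denominator_flagged(self):
        from dataclasses import replace

        degenerate = replace(self._fit(0.01), beta1=0.0)
        with pytest.raises(ZeroDivisionError):
            slope_ratio(self._fit(0.01), degenerate)


class TestReferenceSeries:
    def _profiles(self, centers):
        axis = DepthAxis(np.arange(0.0, 200.0, 5.0))
        out = []
        for c in centers:
            vals = np.exp(-0.5 * ((axis.depths - c) / 20.0) ** 2)
            out.append(ProbabilityField(vals / vals.sum(), axis=axis))
        return out

    def test_reference_to_itself_is_zero_and_normalization(self):
        dates = month_range((1998, 1), 13)
        centers = [100.0 + 40.0 * np.sin(2 * np.pi * m / 12) for _, m in dates]
        series = reference_distance_series(
            self._profiles(centers), dates, reference=(1998, 1), normalize=True
        )
        assert series["dist"].min() == 0.0 and series["dist"].max() == 1.0
        jan = series[(series.year == 1998) & (series.month == 1)]
        assert jan["dist"].iloc[0] == 0.0

    def test_peak_month_tracks_maximal_displacement(self):
        dates = month_range((1998, 1), 12)
        # triangular displacement schedule with a unique maximum in August
        centers = [100.0 + 5.0 * min(m - 1, 15 - m) for _, m in dates]
        series = reference_distance_series(
            self._profiles(centers), dates, reference=(1998, 1)
        )
        peaks = peak_months(series)
        assert peaks["month"].iloc[0] == 8
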