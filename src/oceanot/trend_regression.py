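"""Seasonal-trend regression of pairwise distances on months apart.

Distances between monthly maps mix two time scales: a seasonal cycle (maps
from the same calendar month look alike) and a possible long-term drift in
the spatial pattern.  The model fitted here separates them:

    D_ab ~ beta0 + beta1 * |ym(a) - ym(b)|
              + sum_{k=0..6} beta2_k * 1(|m(a) - m(b)| = k),

where |ym(a) - ym(b)| is the year-aware number of months between maps a and
b, |m(a) - m(b)| in {0, ..., 6} is the circular calendar-month lag, and the
seasonal coefficients are constrained to sum to zero so that beta0 + beta1 *
lag is the de-seasonalized linear trend.  All N(N-1)/2 upper-triangle pairs
enter an ordinary least-squares fit (pairs sharing a map are statistically
dependent; no correction is applied -- see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .comparison import DistanceMatrix, pairwise_distance_matrix, rmse as _rmse
from .optimal_transport import solve_transport
from .scalar_fields import ProbabilityField

#: Calendar-month lags live on a circle of circumference 12: at most 6 apart.
N_SEASONAL_LEVELS = 7


@dataclass(frozen=True)
class MonthLagFeatures:
    """Lag features for one pair of (year, month) dates."""

    a: tuple[int, int]
    b: tuple[int, int]
    total_lag: int
    calendar_lag: int


def month_lag_features(a: tuple[int, int], b: tuple[int, int]) -> MonthLagFeatures:
    """Year-aware and circular calendar-month lags between two dates.

    total_lag = |12 (year_a - year_b) + (month_a - month_b)|;
    calendar_lag folds the month difference onto {0..6}:
    min(|m_a - m_b|, 12 - |m_a - m_b|).
    """
    for (_, m) in (a, b):
        if not 1 <= m <= 12:
            raise ValueError(f"month {m} outside 1..12")
    total = abs(12 * (a[0] - b[0]) + (a[1] - b[1]))
    dm = abs(a[1] - b[1])
    return MonthLagFeatures(a=a, b=b, total_lag=total,
                            calendar_lag=min(dm, 12 - dm))


@dataclass(frozen=True)
class SeasonalTrendFit:
    """Fitted coefficients of the seasonal-trend regression.

    ``beta2`` holds the seven seasonal coefficients (k = 0..6, sum-to-zero
    over observed lag levels); unobserved levels are reported as 0.
    """

    beta0: float
    beta1: float
    beta2: np.ndarray
    se_beta0: float
    se_beta1: float
    se_beta2: np.ndarray
    r_squared: float
    resid_std: float
    n_obs: int
    observed_levels: tuple[int, ...]

    def predict(self, total_lag, calendar_lag) -> np.ndarray:
        """Fitted mean (the seasonal "blue line") for given lags."""
        total_lag = np.asarray(total_lag)
        calendar_lag = np.asarray(calendar_lag, dtype=int)
        return self.beta0 + self.beta1 * total_lag + self.beta2[calendar_lag]

    def trend_line(self, total_lag) -> np.ndarray:
        """De-seasonalized linear trend (the "red line"): beta0 + beta1 * lag."""
        return self.beta0 + self.beta1 * np.asarray(total_lag)

    def report(self) -> str:
        lines = [
            f"intercept  beta0 = {self.beta0:.6g} (se {self.se_beta0:.3g})",
            f"trend      beta1 = {self.beta1:.6g} per month (se {self.se_beta1:.3g})",
            "seasonal   beta2 (calendar lag 0..6, sum-to-zero):",
        ]
        for k in range(N_SEASONAL_LEVELS):
            obs = "" if k in self.observed_levels else "  [unobserved]"
            lines.append(f"    k={k}: {self.beta2[k]: .6g} (se {self.se_beta2[k]:.3g}){obs}")
        lines.append(f"R^2 = {self.r_squared:.4f} on {self.n_obs} pairs")
        return "\n".join(lines)


def _pair_table(D: DistanceMatrix, dates: Sequence[tuple[int, int]]) -> pd.DataFrame:
    if len(dates) != D.n:
        raise ValueError("one (year, month) date required per label")
    rows = []
    for a in range(D.n):
        for b in range(a + 1, D.n):
            f = month_lag_features(dates[a], dates[b])
            rows.append((D.labels[a], D.labels[b], f.total_lag,
                         f.calendar_lag, D.D[a, b]))
    return pd.DataFrame(rows, columns=["a", "b", "total_lag", "calendar_lag", "dist"])


def fit_seasonal_trend(
    D: DistanceMatrix, dates: Sequence[tuple[int, int]]
) -> SeasonalTrendFit:
    """Least-squares fit of the seasonal-trend model to upper-triangle pairs.

    The sum-to-zero constraint on the seasonal coefficients is imposed by
    reparameterization: with observed lag levels k_0 < ... < k_L, the design
    carries columns 1(lag = k_l) - 1(lag = k_L) for l < L and the last
    coefficient is recovered as minus the sum of the others.

    Raises
    ------
    ValueError
        If fewer than 9 pairs or fewer than 2 distinct calendar lags are
        available, or the design is rank deficient (the message names the
        missing lag levels).
    """
    tab = _pair_table(D, dates)
    levels = tuple(sorted(tab["calendar_lag"].unique()))
    missing = sorted(set(range(N_SEASONAL_LEVELS)) - set(levels))
    if len(tab) < 9 or len(levels) < 2:
        raise ValueError(
            f"need >= 9 pairs spanning >= 2 calendar lags (got {len(tab)} pairs, "
            f"levels {levels}; missing lag levels {missing})"
        )
    L = len(levels)
    lag_pos = {k: i for i, k in enumerate(levels)}
    X = np.zeros((len(tab), 2 + L - 1))
    X[:, 0] = 1.0
    X[:, 1] = tab["total_lag"].to_numpy(dtype=float)
    for r, k in enumerate(tab["calendar_lag"]):
        i = lag_pos[k]
        if i < L - 1:
            X[r, 2 + i] = 1.0
        else:
            X[r, 2:] = -1.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"missing calendar lag levels: {missing or 'none'} -- "
            "total lag may be confounded with the seasonal indicators"
        )

    res = sm.OLS(tab["dist"].to_numpy(dtype=float), X).fit()
    beta0, beta1 = res.params[0], res.params[1]
    gam = res.params[2:]
    beta2 = np.zeros(N_SEASONAL_LEVELS)
    se_beta2 = np.zeros(N_SEASONAL_LEVELS)
    cov = res.cov_params()
    for i, k in enumerate(levels[:-1]):
        beta2[k] = gam[i]
        se_beta2[k] = res.bse[2 + i]
    beta2[levels[-1]] = -gam.sum()
    # variance of -sum(gamma) from the coefficient covariance block
    block = cov[2:, 2:]
    se_beta2[levels[-1]] = float(np.sqrt(np.ones(L - 1) @ block @ np.ones(L - 1)))
    return SeasonalTrendFit(
        beta0=float(beta0), beta1=float(beta1), beta2=beta2,
        se_beta0=float(res.bse[0]), se_beta1=float(res.bse[1]), se_beta2=se_beta2,
        r_squared=float(res.rsquared), resid_std=float(np.sqrt(res.scale)),
        n_obs=len(tab), observed_levels=levels,
    )


def slope_ratio(fit_a: SeasonalTrendFit, fit_b: SeasonalTrendFit) -> float:
    """Ratio of long-term trend slopes beta1_a / beta1_b between two sources."""
    if fit_b.beta1 == 0:
        raise ZeroDivisionError("slope ratio undefined: denominator slope is zero")
    ratio = fit_a.beta1 / fit_b.beta1
    if ratio < 0:
        warnings.warn(
            f"slope ratio is negative ({ratio:.4g}): the two trends have "
            "opposite signs"
        )
    return ratio


def reference_distance_series(
    fields: Sequence[ProbabilityField],
    dates: Sequence[tuple[int, int]],
    reference: tuple[int, int],
    metric: str = "wasserstein",
    normalize: bool = False,
) -> pd.DataFrame:
    """Distance from one reference map to every map in a dated collection.

    Returns a DataFrame (year, month, dist) sorted by date; with
    ``normalize=True`` the distances are min-max scaled to [0, 1].  The peak
    month per year is available via :func:`peak_months`.
    """
    dates = list(dates)
    if reference not in dates:
        raise ValueError(f"reference date {reference} not in collection")
    ref = fields[dates.index(reference)]
    from .comparison import _base_matrix

    rows = []
    for f, (y, m) in zip(fields, dates):
        if metric == "rmse":
            val = _rmse(ref, f)
        else:
            val = solve_transport(ref, f, _base_matrix(ref, f)).w2
        rows.append((y, m, val))
    out = pd.DataFrame(rows, columns=["year", "month", "dist"])
    out = out.sort_values(["year", "month"], ignore_index=True)
    if normalize:
        lo, hi = out["dist"].min(), out["dist"].max()
        if hi > lo:
            out["dist"] = (out["dist"] - lo) / (hi - lo)
        else:
            out["dist"] = 0.0
    return out


def peak_months(series: pd.DataFrame) -> pd.DataFrame:
    """Month of maximum distance within each year of a reference series."""
    idx = series.groupby("year")["dist"].idxmax()
    return series.loc[idx, ["year", "month", "dist"]].reset_index(drop=True)
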