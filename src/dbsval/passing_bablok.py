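"""Passing-Bablok regression.

A robust, rank-based errors-in-both-variables regression for method
comparison.  The slope is a *shifted median* of all pairwise slopes
S_ij = (y_j - y_i) / (x_j - x_i): slopes of exactly -1 are discarded,
and the median index is offset by K, the number of retained slopes
below -1, which makes the estimator invariant to swapping the roles of
the two methods.  Confidence intervals come from the rank-based
order-statistic construction, with

    C = z_{1-alpha/2} * sqrt(n (n - 1) (2 n + 5) / 18),

slope bounds at the order statistics (N -+ C)/2 offset by K, and the
intercept bounds re-derived from the slope bounds as median residuals.

`PassingBablok` is a scikit-learn compatible regressor; the module-level
functions are thin wrappers for vector inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "PassingBablok",
    "PBFit",
    "BiasCall",
    "DegenerateDataError",
    "pairwise_slopes",
    "analytic_ci_indices",
    "fit_passing_bablok",
    "classify_bias",
    "pearson_correlation",
]

#: smallest n for which the analytic order-statistic CI is computed
MIN_N_ANALYTIC_CI = 10


class DegenerateDataError(ValueError):
    """All pairwise slopes are undefined or discarded; no fit possible."""


@dataclass(frozen=True)
class PBFit:
    """A fitted Passing-Bablok regression y = intercept + slope * x."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float] | None
    intercept_ci: tuple[float, float] | None
    n: int
    n_slopes: int
    offset_k: int
    level: float


@dataclass(frozen=True)
class BiasCall:
    """Bias classification: constant bias iff the intercept CI excludes 0,
    proportional bias iff the slope CI excludes 1."""

    constant_bias: bool
    proportional_bias: bool


def pairwise_slopes(x, y) -> tuple[np.ndarray, int]:
    """All pairwise slopes over i < j, sorted ascending, plus the offset K.

    Pairs with equal x are undefined and dropped; slopes exactly -1 are
    discarded by the method's construction.  K counts retained slopes
    strictly below -1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    defined = dx != 0
    s = dy[defined] / dx[defined]
    s = s[s != -1.0]
    if s.size == 0:
        raise DegenerateDataError("all pairwise slopes degenerate or discarded")
    k = int(np.sum(s < -1.0))
    return np.sort(s, kind="stable"), k


def _shifted_median(sorted_slopes: np.ndarray, k: int) -> float:
    # 1-based median index offset by K; even counts average the two
    # central order statistics.
    n = len(sorted_slopes)
    if n % 2 == 1:
        idx = (n + 1) // 2 + k
        _check_index(idx, n)
        return float(sorted_slopes[idx - 1])
    lo, hi = n // 2 + k, n // 2 + 1 + k
    _check_index(lo, n)
    _check_index(hi, n)
    return float(0.5 * (sorted_slopes[lo - 1] + sorted_slopes[hi - 1]))


def _check_index(idx_1based: int, n: int) -> None:
    if not 1 <= idx_1based <= n:
        raise DegenerateDataError(
            f"shifted order-statistic index {idx_1based} outside 1..{n}; "
            "data too degenerate for Passing-Bablok"
        )


def analytic_ci_indices(
    n: int, n_slopes: int, k: int, level: float = 0.95
) -> tuple[int, int]:
    """1-based order-statistic indices of the slope confidence bounds.

    C = z * sqrt(n (n-1) (2n+5) / 18); M1 = round((N - C)/2);
    M2 = N - M1 + 1; bounds at indices M1 + K and M2 + K.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_slopes - c) / 2.0))
    m2 = n_slopes - m1 + 1
    lo_idx, hi_idx = m1 + k, m2 + k
    _check_index(lo_idx, n_slopes)
    _check_index(hi_idx, n_slopes)
    return lo_idx, hi_idx


class PassingBablok(RegressorMixin, BaseEstimator):
    """Passing-Bablok method-comparison regression.

    Parameters
    ----------
    level : float, default 0.95
        Confidence level for the slope and intercept intervals.
    ci : {"analytic", "bootstrap", None}, default "analytic"
        Interval method.  "analytic" uses the rank-based order-statistic
        construction and needs n >= 10 (below that the fit is returned
        without intervals, with a warning); "bootstrap" uses a seeded
        percentile bootstrap; None skips intervals (fast, e.g. inside
        leave-one-out loops).
    n_bootstrap : int, default 2000
        Bootstrap resamples when ``ci="bootstrap"``.
    random_state : int, default 0
        Bootstrap seed.

    Attributes
    ----------
    slope_, intercept_ : float
        Point estimates of y = intercept + slope * x.
    slope_ci_, intercept_ci_ : tuple or None
        Confidence bounds at ``level``.
    n_, n_slopes_, offset_k_ : int
        Points used, pairwise slopes retained, and the offset K.

    Notes
    -----
    The method assumes a positively correlated comparison (both methods
    measure the same quantity); negatively correlated inputs trigger a
    warning rather than a silent fit.
    """

    def __init__(
        self,
        level: float = 0.95,
        ci: str | None = "analytic",
        n_bootstrap: int = 2000,
        random_state: int = 0,
    ):
        self.level = level
        self.ci = ci
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    # -- estimation ----------------------------------------------------

    @staticmethod
    def _point_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray, int]:
        slopes, k = pairwise_slopes(x, y)
        b = _shifted_median(slopes, k)
        a = float(np.median(y - b * x))
        return b, a, slopes, k

    def _analytic_ci(
        self, x, y, slopes: np.ndarray, k: int
    ) -> tuple[tuple[float, float], tuple[float, float]]:
        big_n = len(slopes)
        lo_idx, hi_idx = analytic_ci_indices(len(x), big_n, k, self.level)
        b_lo = float(slopes[lo_idx - 1])
        b_hi = float(slopes[hi_idx - 1])
        # intercept bounds re-derived from the slope bounds
        a_lo = float(np.median(y - b_hi * x))
        a_hi = float(np.median(y - b_lo * x))
        return (b_lo, b_hi), (a_lo, a_hi)

    def _bootstrap_ci(
        self, x, y
    ) -> tuple[tuple[float, float], tuple[float, float]]:
        rng = np.random.default_rng(self.random_state)
        n = len(x)
        bs, as_ = [], []
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                b, a, _, _ = self._point_fit(x[idx], y[idx])
            except DegenerateDataError:
                continue
            bs.append(b)
            as_.append(a)
        q = (100 * (1 - self.level) / 2.0, 100 * (0.5 + self.level / 2.0))
        b_lo, b_hi = np.percentile(bs, q)
        a_lo, a_hi = np.percentile(as_, q)
        return (float(b_lo), float(b_hi)), (float(a_lo), float(a_hi))

    def fit(self, X, y):
        """Fit on comparator concentrations X (n, 1) and reference y (n,)."""
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if X.shape[1] != 1:
            raise ValueError("PassingBablok is a single-feature comparison fit")
        x = X[:, 0]
        if np.std(x) > 0 and np.std(y) > 0 and np.corrcoef(x, y)[0, 1] < 0:
            warnings.warn(
                "negatively correlated inputs: Passing-Bablok assumes both "
                "methods measure the same quantity",
                stacklevel=2,
            )
        b, a, slopes, k = self._point_fit(x, y)
        self.slope_, self.intercept_ = b, a
        self.n_ = len(x)
        self.n_slopes_ = len(slopes)
        self.offset_k_ = k
        self.slope_ci_ = self.intercept_ci_ = None
        if self.ci == "analytic":
            if self.n_ >= MIN_N_ANALYTIC_CI:
                self.slope_ci_, self.intercept_ci_ = self._analytic_ci(x, y, slopes, k)
            else:
                warnings.warn(
                    f"n={self.n_} < {MIN_N_ANALYTIC_CI}: analytic order-statistic "
                    "CI unreliable, returning fit without CI "
                    "(use ci='bootstrap' for small n)",
                    stacklevel=2,
                )
        elif self.ci == "bootstrap":
            self.slope_ci_, self.intercept_ci_ = self._bootstrap_ci(x, y)
        elif self.ci is not None:
            raise ValueError(f"unknown ci method {self.ci!r}")
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = check_array(X)
        return self.intercept_ + self.slope_ * X[:, 0]

    def result_(self) -> PBFit:
        """The fit as an immutable summary record."""
        check_is_fitted(self, "slope_")
        return PBFit(
            slope=self.slope_,
            intercept=self.intercept_,
            slope_ci=self.slope_ci_,
            intercept_ci=self.intercept_ci_,
            n=self.n_,
            n_slopes=self.n_slopes_,
            offset_k=self.offset_k_,
            level=self.level,
        )


def fit_passing_bablok(x, y, level: float = 0.95, ci: str | None = "analytic") -> PBFit:
    """Fit a Passing-Bablok regression of y on x (1-D vectors)."""
    x = np.asarray(x, dtype=float)
    est = PassingBablok(level=level, ci=ci).fit(x.reshape(-1, 1), y)
    return est.result_()


def classify_bias(fit: PBFit) -> BiasCall:
    """Classify constant/proportional bias from the fitted intervals."""
    if fit.slope_ci is None or fit.intercept_ci is None:
        raise ValueError("bias classification requires confidence intervals")
    a_lo, a_hi = fit.intercept_ci
    b_lo, b_hi = fit.slope_ci
    return BiasCall(
        constant_bias=not (a_lo <= 0.0 <= a_hi),
        proportional_bias=not (b_lo <= 1.0 <= b_hi),
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation r and r² between two methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
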