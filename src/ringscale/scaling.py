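"""Scaling-law statistics: power-law fits, bootstrap CIs, model comparison,
regressions, correlations, binned means.

The central model is the allometric power law d = c * V**alpha, fitted as an
ordinary least-squares line in double-logarithmic space; the slope is the
scaling exponent alpha and the intercept is log10(c). Confidence intervals
come from case resampling (cells, not frames) with a percentile interval,
50,000 resamples by default. Competing linear (d = a + b*V) and logarithmic
(d = a + b*log10 V) models are compared on their sum of squared residuals in
diameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearityError, InsufficientDataError


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(d) on log10(V)."""

    slope: float  # scaling exponent alpha
    intercept: float  # log10 of the prefactor c
    n: int
    ci: tuple[float, float] | None = None  # 95% bootstrap CI for the slope
    ssr_linear: float = float("nan")  # residual sum in diameter space
    ssr_log: float = float("nan")  # residual sum in log10-diameter space

    @property
    def prefactor(self) -> float:
        return float(10.0**self.intercept)

    def predict(self, volume) -> np.ndarray:
        """Expected diameter at the given volume(s)."""
        return self.prefactor * np.asarray(volume, dtype=float) ** self.slope


@dataclass(frozen=True)
class ModelComparison:
    """Power vs linear vs logarithmic fits of d(V)."""

    power: PowerLawFit
    linear: tuple[float, float]  # (a, b) of d = a + b*V
    logarithmic: tuple[float, float]  # (a, b) of d = a + b*log10(V)
    ssr: dict[str, float] = field(default_factory=dict)  # diameter-space SSR
    winner: str = ""


@dataclass(frozen=True)
class RegressionResult:
    """OLS with intercept; Wald t p-values per coefficient."""

    coefficients: np.ndarray  # (intercept, x1, x2, ...)
    p_values: np.ndarray
    n: int


def _validate_pairs(d, V) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float)
    V = np.asarray(V, dtype=float)
    if d.shape != V.shape or d.ndim != 1:
        raise ValueError("d and V must be 1D arrays of equal length")
    if d.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.any(d <= 0) or np.any(V <= 0):
        raise ValueError("d and V must be strictly positive for log fitting")
    return d, V


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple linear regression (slope, intercept)."""
    mx, my = x.mean(), y.mean()
    sxx = np.mean((x - mx) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    slope = sxy / sxx
    return float(slope), float(my - slope * mx)


def fit_power_law(
    d, V, n_boot: int = 0, level: float = 0.95, seed: int | None = None
) -> PowerLawFit:
    """Fit d = c * V**alpha by OLS on the double-logarithmic data.

    With ``n_boot > 0`` a percentile bootstrap CI for the exponent is
    attached (case resampling, seed-deterministic).
    """
    d, V = _validate_pairs(d, V)
    lx, ly = np.log10(V), np.log10(d)
    slope, intercept = _ols_line(lx, ly)
    pred_log = intercept + slope * lx
    fit = PowerLawFit(
        slope=slope,
        intercept=intercept,
        n=d.size,
        ssr_linear=float(np.sum((d - 10.0**pred_log) ** 2)),
        ssr_log=float(np.sum((ly - pred_log) ** 2)),
    )
    if n_boot > 0:
        fit = replace(fit, ci=bootstrap_ci(d, V, n_boot=n_boot, level=level, seed=seed))
    return fit


def _bootstrap_slopes(
    lx: np.ndarray, ly: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = lx.size
    slopes = np.empty(n_boot)
    chunk = max(1, int(2e6) // n)
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        x = lx[idx]
        y = ly[idx]
        mx = x.mean(axis=1, keepdims=True)
        my = y.mean(axis=1, keepdims=True)
        sxx = np.mean((x - mx) ** 2, axis=1)
        sxy = np.mean((x - mx) * (y - my), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes[start:stop] = sxy / sxx
    # a resample with zero x-variance (all cells identical) has no slope
    return slopes[np.isfinite(slopes)]


def bootstrap_ci(
    d,
    V,
    n_boot: int = 50_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the power-law exponent.

    Cells (d, V pairs) are resampled with replacement; the slope of the
    log-log OLS line is recorded for each resample.
    """
    d, V = _validate_pairs(d, V)
    rng = np.random.default_rng(seed)
    slopes = _bootstrap_slopes(np.log10(V), np.log10(d), n_boot, rng)
    if slopes.size == 0:
        raise InsufficientDataError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(slopes, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_models(d, V) -> ModelComparison:
    """Fit power, linear and logarithmic models; rank by diameter-space SSR.

    The power law is fitted in log space (as published) but its residuals
    are evaluated in diameter space so the three SSRs share units; the
    log-space SSR is also carried on the PowerLawFit.
    """
    d, V = _validate_pairs(d, V)
    power = fit_power_law(d, V)
    b_lin, a_lin = _ols_line(V, d)
    b_log, a_log = _ols_line(np.log10(V), d)
    ssr = {
        "power": power.ssr_linear,
        "linear": float(np.sum((d - (a_lin + b_lin * V)) ** 2)),
        "logarithmic": float(np.sum((d - (a_log + b_log * np.log10(V))) ** 2)),
    }
    winner = min(sorted(ssr), key=lambda k: ssr[k])
    return ModelComparison(
        power=power,
        linear=(a_lin, b_lin),
        logarithmic=(a_log, b_log),
        ssr=ssr,
        winner=winner,
    )


def log_offset_percent(d, V, reference: PowerLawFit) -> float:
    """Vertical offset of a population above a reference scaling fit, in %.

    The mean offset in log10 diameter between the population and the
    reference prediction at each cell's volume, converted to a percentage
    (e.g. +7.0 means diameters sit 7% above the reference fit across the
    volume range). This is the ploidy-comparison statistic: two
    populations with the same exponent but different prefactors differ by
    a constant log offset.
    """
    d, V = _validate_pairs(d, V)
    mean_offset = float(np.mean(np.log10(d) - np.log10(reference.predict(V))))
    return (10.0**mean_offset - 1.0) * 100.0


def two_var_regression(y, x1, x2) -> RegressionResult:
    """Two-predictor linear regression with constant offset.

    Coefficient p-values are two-sided Wald t-tests under homoscedastic
    normal errors (the classical GLM/normal-model convention). Coefficients
    are ordered (intercept, x1, x2).
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    if y.size <= 3:
        raise InsufficientDataError("need more than 3 observations")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    return RegressionResult(
        coefficients=np.asarray(res.params, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        n=int(y.size),
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson R with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class BinnedMeans:
    """Per-bin summaries; empty bins are omitted (their edges recorded)."""

    mean_x: np.ndarray
    mean_y: np.ndarray
    se_y: np.ndarray  # SEM; 0 by convention for singleton bins
    n: np.ndarray
    empty_bins: list[int] = field(default_factory=list)


def binned_means(x, y, bin_edges) -> BinnedMeans:
    """Arithmetic mean of x and y, SEM of y, and count, per x-bin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(x, edges) - 1
    mean_x, mean_y, se_y, ns, empty = [], [], [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        k = int(sel.sum())
        if k == 0:
            empty.append(b)
            continue
        mean_x.append(float(x[sel].mean()))
        mean_y.append(float(y[sel].mean()))
        se_y.append(float(np.std(y[sel], ddof=1) / np.sqrt(k)) if k > 1 else 0.0)
        ns.append(k)
    if not ns:
        raise InsufficientDataError("no data falls into any bin")
    return BinnedMeans(
        mean_x=np.array(mean_x),
        mean_y=np.array(mean_y),
        se_y=np.array(se_y),
        n=np.array(ns),
        empty_bins=empty,
    )
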