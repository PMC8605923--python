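"""Ordinary least-squares fitting with the inferential quantities the rest of
the package consumes: standard errors, Student-t confidence intervals,
Pearson correlation, and relative standard deviation.

All downstream regressions (calibration curves, log-recovery vs. time,
log-rate vs. inverse temperature) go through :func:`ols_fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["XYData", "LinearFit", "ols_fit", "rsd_percent"]


@dataclass(frozen=True)
class XYData:
    """Paired observations for a simple linear regression.

    Parameters
    ----------
    x, y : array-like
        Equal-length numeric vectors. ``x`` must contain at least two
        distinct values and both vectors must be finite.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if x.size != y.size:
            raise ValueError(f"length mismatch: len(x)={x.size}, len(y)={y.size}")
        if x.size < 2:
            raise ValueError("at least two points are required")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("x and y must be finite (no NaN/inf)")
        if np.ptp(x) == 0.0:
            raise ValueError("x has zero variance; slope is unidentifiable")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class LinearFit:
    """Result of a simple OLS fit ``y = beta0 + beta1 * x``.

    ``se_beta0`` is the standard error of the intercept; ``residual_sd`` is
    the residual standard deviation ``sqrt(SSE / (n - 2))``. Either may be
    used as the intercept-dispersion estimate for detection/quantification
    limits (see :func:`stabval.validation.lod_loq`).

    Confidence intervals use the Student-t distribution with ``n - 2``
    degrees of freedom; with ``n == 2`` they are undefined and reported as
    NaN.
    """

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    r: float
    r2: float
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float]
    n: int
    residuals: np.ndarray = field(repr=False)
    residual_sd: float = float("nan")
    confidence_level: float = 0.95

    def predict(self, x) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)

    def inverse_predict(self, y) -> np.ndarray:
        """Concentration (abscissa) implied by a response ``y``."""
        if self.beta1 == 0.0:
            raise ZeroDivisionError("slope is zero; inverse prediction undefined")
        return (np.asarray(y, dtype=float) - self.beta0) / self.beta1


def ols_fit(data: XYData, confidence_level: float = 0.95) -> LinearFit:
    """Fit ``y = beta0 + beta1 * x`` by ordinary least squares.

    Parameters
    ----------
    data : XYData
        Validated paired observations (``n >= 2``; inference needs
        ``n >= 3``).
    confidence_level : float
        Two-sided level for the parameter confidence intervals
        (default 0.95).
    """
    if not 0.0 < confidence_level < 1.0:
        raise ValueError("confidence_level must be in (0, 1)")
    x, y, n = data.x, data.y, data.n

    if n == 2:
        # exact line through two points; no residual degrees of freedom
        beta1 = (y[1] - y[0]) / (x[1] - x[0])
        beta0 = y[0] - beta1 * x[0]
        residuals = np.zeros(2)
        nan = float("nan")
        r = float(np.sign(beta1)) if beta1 != 0.0 else nan
        return LinearFit(
            beta0=float(beta0), beta1=float(beta1),
            se_beta0=nan, se_beta1=nan,
            r=r, r2=r * r if np.isfinite(r) else nan,
            ci_beta0=(nan, nan), ci_beta1=(nan, nan),
            n=2, residuals=residuals, residual_sd=nan,
            confidence_level=confidence_level,
        )

    if np.ptp(y) == 0.0:
        # constant response: slope 0, correlation undefined -> reported as 0
        res = stats.linregress(x, np.zeros_like(y))
        beta1, beta0 = 0.0, float(np.mean(y))
        r = 0.0
        se_beta1 = 0.0
        se_beta0 = 0.0
        residuals = y - beta0
        residual_sd = 0.0
    else:
        res = stats.linregress(x, y)
        beta0, beta1 = float(res.intercept), float(res.slope)
        r = float(res.rvalue)
        se_beta1 = float(res.stderr)
        se_beta0 = float(res.intercept_stderr)
        residuals = y - (beta0 + beta1 * x)
        residual_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))

    tcrit = float(stats.t.ppf(0.5 + confidence_level / 2.0, df=n - 2))
    ci_beta0 = (beta0 - tcrit * se_beta0, beta0 + tcrit * se_beta0)
    ci_beta1 = (beta1 - tcrit * se_beta1, beta1 + tcrit * se_beta1)

    return LinearFit(
        beta0=beta0, beta1=beta1,
        se_beta0=se_beta0, se_beta1=se_beta1,
        r=r, r2=r * r,
        ci_beta0=ci_beta0, ci_beta1=ci_beta1,
        n=n, residuals=residuals, residual_sd=residual_sd,
        confidence_level=confidence_level,
    )


def rsd_percent(values) -> float:
    """Relative standard deviation, ``100 * sd / mean`` (sample sd, ddof=1).

    Raises
    ------
    ValueError
        If fewer than two values are given or the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD requires at least two values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValueError("RSD is undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean
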