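"""Test-retest precision and method-agreement statistics.

Duplicate-measurement precision follows densitometry (ISCD) conventions:
for a pair (a_i, b_i), SD_i = |a_i - b_i| / sqrt(2) and
CV_i = 100 * SD_i / mean_i; RMSSD and RMSCV are the root mean squares over
subjects.  The least significant change LSC = 1.96 * sqrt(2) * RMSSD is the
smallest longitudinal change distinguishable from measurement error at 95%
confidence.  Absolute agreement between occasions is summarised by the
two-way random-effects single-measure intraclass correlation ICC(2,1);
method agreement by Bland-Altman limits and univariable regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

LSC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class PrecisionReport:
    RMSCV_pct: float
    RMSSD: float
    LSC: float
    ICC_2_1: float
    ICC_ci95: tuple[float, float]
    n_pairs: int


@dataclass
class AgreementReport:
    mean_difference: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int


def rmscv_rmssd(pairs: np.ndarray) -> tuple[float, float]:
    """Root-mean-square CV (%) and SD over duplicate pairs.

    ``pairs`` is (n, 2).  Pairs with mean 0 are excluded from the CV (their
    CV is undefined) with a warning; they still contribute to RMSSD.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) array of duplicate measurements")
    sd = np.abs(pairs[:, 0] - pairs[:, 1]) / math.sqrt(2.0)
    means = pairs.mean(axis=1)
    ok = means != 0
    if not ok.all():
        log.warning("excluding %d pair(s) with zero mean from RMSCV", int((~ok).sum()))
    if not ok.any():
        raise ValueError("all pairs have zero mean; CV undefined")
    cv = 100.0 * sd[ok] / means[ok]
    rmscv = float(np.sqrt(np.mean(cv**2)))
    rmssd = float(np.sqrt(np.mean(sd**2)))
    return rmscv, rmssd


def lsc(rmssd: float) -> float:
    """Least significant change: 1.96 * sqrt(2) * RMSSD."""
    if rmssd < 0:
        raise ValueError("RMSSD must be non-negative")
    return LSC_FACTOR * rmssd


def icc_2_1(data: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is (subjects, raters/occasions).  Computed from the two-way
    ANOVA mean squares (rows = subjects, columns = occasions):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the F-based 95% CI of McGraw & Wong.  Zero between-subject
    variance makes the ICC undefined; 0 is returned with a warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, occasions >= 2) matrix")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if np.allclose(ss_rows, 0.0):
        log.warning("zero between-subject variance; ICC undefined, returning 0")
        return 0.0, (float("nan"), float("nan"))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    if mse <= 0:
        # perfect within-subject agreement; CI collapses
        return float(icc), (float(icc), float(icc))

    # F-based interval (McGraw & Wong 1996, case A-1)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lower), float(upper))


def bland_altman(pairs: np.ndarray) -> AgreementReport:
    """Bland-Altman agreement between two methods plus OLS calibration line.

    Differences are method1 - method2 (here: fully-automated minus
    semi-automated).  Limits of agreement are mean +/- 1.96 SD of the
    differences.  The regression line is method2 ~ method1 by ordinary
    least squares.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) array of paired measurements")
    d = pairs[:, 0] - pairs[:, 1]
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    slope, intercept, r2 = fit_line(pairs[:, 0], pairs[:, 1])
    return AgreementReport(
        mean_difference=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_pairs=pairs.shape[0],
    )


def fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Univariable OLS: returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    if np.allclose(y, y[0]):
        return float(res.slope), float(res.intercept), 1.0 if np.allclose(res.slope, 0) else 0.0
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def precision_report(pairs: np.ndarray) -> PrecisionReport:
    """Full duplicate-precision summary for one metric."""
    pairs = np.asarray(pairs, dtype=float)
    rmscv, rmssd = rmscv_rmssd(pairs)
    icc, ci = icc_2_1(pairs)
    return PrecisionReport(
        RMSCV_pct=rmscv,
        RMSSD=rmssd,
        LSC=lsc(rmssd),
        ICC_2_1=icc,
        ICC_ci95=ci,
        n_pairs=pairs.shape[0],
    )
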