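"""Reliability, criterion validity, feasibility and normalized scoring.

Conventions follow common questionnaire-validation practice: Cronbach's
alpha with an acceptability cut of 0.60; test--retest reliability as the
two-way, absolute-agreement, single-measures intraclass correlation with
bands poor/fair (<=0.40), moderate (0.41-0.60), good (0.61-0.80) and
excellent (>0.80); Pearson criterion correlations banded at |r| of
0.1 / 0.3 / 0.5; floor and ceiling effects flagged feasible when both are
below 15%; distribution screens flag |skewness| > 3 or (raw) kurtosis
> 10; and item scores normalized to 0-100 via
``(raw - minimum) / range * 100`` with subscale and total scores as
means over their constituent item scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import InstrumentSpec, ResponseMatrix

ALPHA_ACCEPTABLE = 0.60
FLOOR_CEILING_LIMIT = 15.0
SKEWNESS_LIMIT = 3.0
KURTOSIS_LIMIT = 10.0


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def normalized_score(raw, minimum: float, possible_range: float):
    """0-100 normalized score: ``(raw - minimum) / possible_range * 100``."""
    if possible_range <= 0:
        raise ValueError("possible_range must be positive")
    raw = np.asarray(raw, float)
    with np.errstate(invalid="ignore"):
        out_of_range = (raw < minimum) | (raw > minimum + possible_range)
    if np.any(out_of_range & ~np.isnan(raw)):
        raise ValueError("raw score outside the admissible range")
    score = (raw - minimum) / possible_range * 100.0
    return float(score) if score.ndim == 0 else score


def scale_scores(data: ResponseMatrix, instrument: InstrumentSpec) -> pd.DataFrame:
    """Normalized subscale and total scores (means over item scores)."""
    vals = data.values
    cats = data.n_categories.astype(float)
    item_scores = (vals - 1.0) / (cats[None, :] - 1.0) * 100.0
    out = {}
    ids = list(data.item_ids)
    for s in instrument.subscales:
        cols = [ids.index(i) for i in instrument.items_of(s) if i in ids]
        if cols:
            out[s] = np.nanmean(item_scores[:, cols], axis=1)
    out["total"] = np.nanmean(item_scores, axis=1)
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# reliability
# ----------------------------------------------------------------------

def cronbach_alpha(scores: np.ndarray) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item var) / var(total))``."""
    X = np.asarray(scores, float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    label: str


def icc_band(value: float) -> str:
    if value <= 0.40:
        return "poor_to_fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "excellent"


def icc_test_retest(time1: np.ndarray, time2: np.ndarray, ci: float = 0.95) -> ICCResult:
    """Two-way mixed, absolute-agreement, single-measures ICC.

    Computed from the two-way ANOVA mean squares with the McGraw & Wong
    F-based confidence interval.
    """
    x = np.column_stack([np.asarray(time1, float), np.asarray(time2, float)])
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        raise ValueError("zero between-subject variance; ICC undefined")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong (1996) interval for ICC(A,1)
    alpha = 1.0 - ci
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_up = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_lo = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_up * mse) / (
            f_up * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_lo * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lo * msr
        )
    else:
        lower = upper = 1.0
    icc = float(icc)
    return ICCResult(icc, float(lower), float(upper), icc_band(icc))


# ----------------------------------------------------------------------
# criterion validity
# ----------------------------------------------------------------------

def correlation_band(r: float, p_value: float | None = None, alpha: float = 0.05) -> str:
    """Band |r| at 0.1 / 0.3 / 0.5 (non-significant / poor / medium / strong)."""
    a = abs(r)
    if a < 0.1 or (p_value is not None and p_value >= alpha):
        return "non_significant"
    if a < 0.3:
        return "poor"
    if a < 0.5:
        return "medium"
    return "strong"


def criterion_correlations(
    scores: pd.DataFrame, criteria: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of each scale score with each criterion.

    Returns one row per (scale, criterion) pair with r, the two-sided
    p-value and the magnitude band.  Constant vectors yield NaN and the
    band ``undefined``.
    """
    rows = []
    for scale in scores.columns:
        for crit in criteria.columns:
            x = scores[scale].to_numpy(float)
            y = criteria[crit].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if x.size < 3:
                raise ValueError("need at least 3 paired observations")
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"scale": scale, "criterion": crit, "r": float("nan"),
                             "p": float("nan"), "band": "undefined"})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"scale": scale, "criterion": crit, "r": float(r),
                         "p": float(p), "band": correlation_band(r, p)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# feasibility and distribution screens
# ----------------------------------------------------------------------

def floor_ceiling(
    scores: np.ndarray, minimum: float = 0.0, maximum: float = 100.0
) -> tuple[float, float, bool]:
    """Percent of scores at the bounds; feasible when both are below 15%."""
    x = np.asarray(scores, float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("scores must be nonempty")
    if ((x < minimum) | (x > maximum)).any():
        raise ValueError("scores outside the scale bounds")
    floor_pct = float(np.mean(np.isclose(x, minimum)) * 100.0)
    ceiling_pct = float(np.mean(np.isclose(x, maximum)) * 100.0)
    feasible = floor_pct < FLOOR_CEILING_LIMIT and ceiling_pct < FLOOR_CEILING_LIMIT
    return floor_pct, ceiling_pct, feasible


def distribution_screen(scores: np.ndarray) -> tuple[float, float, bool]:
    """Sample skewness, raw kurtosis and the 3/10 normality flag."""
    x = np.asarray(scores, float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("zero variance; shape statistics undefined")
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x, fisher=False))
    ok = abs(skew) <= SKEWNESS_LIMIT and kurt <= KURTOSIS_LIMIT
    return skew, kurt, ok
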