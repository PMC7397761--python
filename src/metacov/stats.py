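"""Descriptive and frequentist statistics for the behavioral analyses.

Covers the non-Bayesian layer of the analysis sequence: per-subject-task
summaries (d', mean confidence, AUROC2, optional MLE Mratio), paired t-tests
with Cohen's dz, Bonferroni-corrected thresholds, Pearson correlations with
Fisher-z confidence intervals, regression-based outlier screening, and the
low-performance (d' < 0.10) exclusion rule applied before nonhierarchical
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .exceptions import DegenerateDataError, InvalidParameterError


def compute_confidence_level(trials: pd.DataFrame) -> float:
    """Mean confidence (% scale) across trials — the metacognitive-bias measure.

    Deliberately *not* performance-corrected: the average confidence level is
    used as-is, without subtracting percent correct.
    """
    if len(trials) == 0:
        raise DegenerateDataError("cannot average confidence over zero trials")
    return float(trials["confidence_pct"].mean())


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    dz: float
    mean_diff: float
    significant_after_correction: bool | None = None


def paired_ttest(x, y, alpha_corrected: float | None = None) -> TTestResult:
    """Classical paired t-test with Cohen's dz = mean(diff)/sd(diff) (= t/sqrt(n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("x and y must be equal-length 1-d arrays with n >= 3")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences: paired t-test undefined")
    res = sps.ttest_rel(x, y)
    dz = float(diff.mean() / sd)
    return TTestResult(
        t=float(res.statistic),
        df=x.size - 1,
        p=float(res.pvalue),
        dz=dz,
        mean_diff=float(diff.mean()),
        significant_after_correction=(
            None if alpha_corrected is None else bool(res.pvalue < alpha_corrected)
        ),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise InvalidParameterError("number of comparisons must be >= 1")
    if not 0 < alpha <= 1:
        raise InvalidParameterError(f"alpha must be in (0, 1], got {alpha}")
    return alpha / m


@dataclass(frozen=True)
class CorrResult:
    r: float
    ci95: tuple
    p: float
    n: int
    significant_after_correction: bool | None = None


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if not -1 < r < 1:
        raise InvalidParameterError("r must be strictly inside (-1, 1) for a Fisher-z CI")
    if n < 4:
        raise InvalidParameterError("Fisher-z CI requires n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = ndtri(0.5 + conf / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def pearson_with_ci(x, y, alpha_corrected: float | None = None) -> CorrResult:
    """Pearson r with a 95% Fisher-z confidence interval and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise InvalidParameterError("x and y must be equal-length 1-d arrays with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidParameterError("x and y must be finite")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    if abs(r) == 1.0:
        ci = (float(r), float(r))
    else:
        ci = fisher_ci(float(r), x.size)
    return CorrResult(
        r=float(r),
        ci95=ci,
        p=float(p),
        n=x.size,
        significant_after_correction=(
            None if alpha_corrected is None else bool(p < alpha_corrected)
        ),
    )


def influence_outliers(x, y) -> dict:
    """Regression-influence screening of a paired sample.

    Fits the simple linear regression of y on x and flags points by three
    criteria: leverage > 2(k+1)/n, |externally studentized residual| > 3,
    Cook's distance > 4/n.  Returns per-test index arrays and their union.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.shape != x.shape or x.ndim != 1 or n < 5:
        raise InvalidParameterError("x and y must be equal-length 1-d arrays with n >= 5")
    if x.std() == 0:
        raise DegenerateDataError("degenerate regression: x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    infl = OLSInfluence(model)
    lev = np.flatnonzero(infl.hat_matrix_diag > 2.0 * 2 / n)
    resid = np.flatnonzero(np.abs(infl.resid_studentized_external) > 3.0)
    cooks = np.flatnonzero(infl.cooks_distance[0] > 4.0 / n)
    union = np.unique(np.concatenate([lev, resid, cooks]))
    return {"leverage": lev, "studentized_residual": resid, "cooks": cooks, "flagged": union}


def exclude_low_performance(
    summaries: pd.DataFrame, threshold: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every subject whose d' falls below ``threshold`` in ANY task.

    ``summaries`` needs columns ``subject``, ``task``, ``dprime``.  Returns
    (filtered summaries, exclusion log with one row per offending
    subject-task).
    """
    if not {"subject", "task", "dprime"}.issubset(summaries.columns):
        raise InvalidParameterError("summaries must have subject, task and dprime columns")
    low = summaries[summaries["dprime"] < threshold]
    excluded = sorted(low["subject"].unique())
    log = low[["subject", "task", "dprime"]].reset_index(drop=True)
    kept = summaries[~summaries["subject"].isin(excluded)].reset_index(drop=True)
    return kept, log
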