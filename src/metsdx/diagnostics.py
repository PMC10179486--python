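"""Diagnostic-accuracy engine: ROC/AUC, DeLong inference, Youden cutoffs,
cutoff-level metrics, and the descriptive statistics used alongside them.

Conventions
-----------
* Higher score = more disease-like. A subject is called positive at a cutoff
  ``c`` iff ``score > c`` (strict), so a reported cutoff reads "greater than
  c is positive".
* The empirical ROC curve is traced over the distinct observed score values
  used as strict cutoffs, plus a ``-inf`` sentinel at which every subject is
  called positive; it therefore runs from (0, 0) to (1, 1) and the
  trapezoidal area equals the Mann-Whitney statistic (ties at half credit).
* AUC standard errors and paired AUC comparisons use DeLong's structural
  components (the jackknife-like placement values of each subject), the
  standard nonparametric treatment for correlated empirical AUCs.

Undefined ratios are reported as ``math.inf`` (division of a positive number
by zero, e.g. PLR at specificity 1) or ``None`` (0/0), never as a silently
wrong finite number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve. thresholds[i] is the strict cutoff producing
    operating point (fpr[i], tpr[i]); thresholds decrease, rates increase."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_se: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    level: Optional[float] = None


@dataclass(frozen=True)
class DiagnosticSummary:
    cutoff: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    plr: Optional[float]
    nlr: Optional[float]
    youden: float
    prevalence: float
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity_ci: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    se_difference: float
    z: float
    p: float


# ---------------------------------------------------------------------------
# input handling


def _as_score_label_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        missing = "negative" if y.all() else "positive"
        raise ValueError(f"labels contain no {missing} subjects; both classes are required")
    return s, y


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC curve with trapezoidal AUC."""
    s, y = _as_score_label_arrays(scores, labels)
    npos = int(y.sum())
    nneg = int(y.size - npos)

    # strict-> cutoffs at each distinct score, descending, then -inf (all positive)
    thresholds = np.append(np.unique(s)[::-1], -np.inf)
    # positive call iff score > t
    calls = s[None, :] > thresholds[:, None]
    tpr = (calls & y).sum(axis=1) / npos
    fpr = (calls & ~y).sum(axis=1) / nneg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability: mean over all (positive, negative)
    pairs of 1[pos > neg] + 0.5 * 1[pos == neg]."""
    s, y = _as_score_label_arrays(scores, labels)
    pos = s[y][:, None]
    neg = s[~y][None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


def _delong_placements(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos, neg = s[y], s[~y]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """AUC with DeLong standard error and normal-approximation CI.

    The CI is truncated to [0, 1]; a degenerate (zero-variance) case such as
    perfect separation yields se = 0 and a point interval.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    s, y = _as_score_label_arrays(scores, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("DeLong variance needs at least 2 positives and 2 negatives")
    auc, v10, v01 = _delong_placements(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    se = float(math.sqrt(max(var, 0.0)))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    ci = (max(0.0, auc - zcrit * se), min(1.0, auc + zcrit * se))
    return auc, se, ci


def roc_with_ci(scores, labels, level: float = 0.95) -> RocCurve:
    """ROC curve annotated with DeLong AUC standard error and CI."""
    curve = roc_curve(scores, labels)
    auc, se, ci = auc_delong_ci(scores, labels, level=level)
    return RocCurve(
        thresholds=curve.thresholds,
        fpr=curve.fpr,
        tpr=curve.tpr,
        auc=curve.auc,
        auc_se=se,
        auc_ci=ci,
        level=level,
    )


def compare_auc_delong(scores_a, scores_b, labels) -> AucComparison:
    """Paired DeLong test for the difference between two correlated AUCs
    measured on the same subjects. Two-sided normal p-value."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("scores_a and scores_b must cover the same subjects")
    sa, y = _as_score_label_arrays(sa, labels)
    sb, _ = _as_score_label_arrays(sb, labels)

    auc_a, v10_a, v01_a = _delong_placements(sa, y)
    auc_b, v10_b, v01_b = _delong_placements(sb, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    diff = auc_a - auc_b
    var_diff = max(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1], 0.0)
    se = float(math.sqrt(var_diff))
    if se == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, difference=diff, se_difference=se, z=z, p=float(p))


# ---------------------------------------------------------------------------
# cutoffs and cutoff-level metrics


def youden_optimal_cutoff(roc: RocCurve) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest maximizing threshold; positivity is
    strict ``score > cutoff``.
    """
    finite = np.isfinite(roc.thresholds)
    j = roc.tpr[finite] - roc.fpr[finite]
    best = float(j.max())
    # J values are rationals with denominator npos*nneg; rates stored as
    # floats can differ by ~1e-16 on true ties, so tie within tolerance
    ties = np.flatnonzero(j >= best - 1e-9 * (1.0 + abs(best)))
    # thresholds descend, so the last tied maximizer is the smallest
    idx = int(ties[-1])
    return float(roc.thresholds[finite][idx]), best


def confusion_at_cutoff(scores, labels, cutoff: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts with positivity ``score > cutoff`` (strict)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    calls = s > cutoff
    tp = int((calls & y).sum())
    fp = int((calls & ~y).sum())
    tn = int((~calls & ~y).sum())
    fn = int((~calls & y).sum())
    return tp, fp, tn, fn


def _ratio(num: float, den: float) -> Optional[float]:
    if den > 0:
        return num / den
    return None if num == 0 else math.inf


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def diagnostic_summary(
    counts: tuple[int, int, int, int],
    prevalence_override: Optional[float] = None,
    cutoff: Optional[float] = None,
    level: float = 0.95,
) -> DiagnosticSummary:
    """Sensitivity/specificity/predictive values/likelihood ratios/Youden from
    (TP, FP, TN, FN) counts.

    PPV and NPV default to the empirical prevalence of the counts; when
    ``prevalence_override`` is given they are recomputed by Bayes' rule at
    that prevalence, which lets test performance measured in one sample be
    transported to a population with a different base rate.
    """
    tp, fp, tn, fn = (int(c) for c in counts)
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    npos, nneg = tp + fn, tn + fp
    if npos == 0 or nneg == 0:
        raise ValueError("need at least one positive and one negative subject")

    se = tp / npos
    sp = tn / nneg
    plr = _ratio(se, 1.0 - sp)
    nlr = _ratio(1.0 - se, sp)

    prev = prevalence_override if prevalence_override is not None else npos / (npos + nneg)
    if not 0.0 < prev < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prev}")
    ppv = _ratio(se * prev, se * prev + (1.0 - sp) * (1.0 - prev))
    npv = _ratio(sp * (1.0 - prev), sp * (1.0 - prev) + (1.0 - se) * prev)

    return DiagnosticSummary(
        cutoff=cutoff,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        youden=se + sp - 1.0,
        prevalence=prev,
        sensitivity_ci=_clopper_pearson(tp, npos, level),
        specificity_ci=_clopper_pearson(tn, nneg, level),
    )


def positivity_rate(scores, cutoff: float) -> float:
    """Fraction of subjects called positive (score > cutoff, strict)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be nonempty")
    return float((s > cutoff).mean())


# ---------------------------------------------------------------------------
# descriptive statistics


def pearson_r2(x, y) -> tuple[float, float, float]:
    """Pearson product-moment correlation with r^2 and two-sided p (t transform,
    n - 2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    res = stats.pearsonr(xa, ya)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def two_sample_t(x, y, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; Welch (unequal variances) by default,
    ``variant='pooled'`` for the equal-variance version. Returns (t, df, p)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.std(xa, ddof=1) == 0 and np.std(ya, ddof=1) == 0 and xa.mean() == ya.mean():
        # identical degenerate groups: no evidence of a difference
        return 0.0, float(xa.size + ya.size - 2), 1.0
    if variant == "welch":
        res = stats.ttest_ind(xa, ya, equal_var=False)
    elif variant == "pooled":
        res = stats.ttest_ind(xa, ya, equal_var=True)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return float(res.statistic), float(res.df), float(res.pvalue)


def sds_outlier_screen(values, cutoff_sds: float = 4.5) -> np.ndarray:
    """Flag values whose standard-deviation score exceeds ``cutoff_sds``.

    The SDS of a value is |value - mean| / SD with mean and SD (ddof=1) taken
    over the full sample, the conventional screen applied before analysis.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("outlier screen is undefined for zero-variance input")
    return np.abs(v - v.mean()) / sd > cutoff_sds


def group_descriptives(
    frame: pd.DataFrame,
    group_labels: Sequence[bool],
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Two-group mean +/- SD table with a Welch t-test p-value per variable.

    ``group_labels`` is a boolean vector (True = case group); the result has
    one row per variable with columns mean/sd per group and ``p``.
    """
    labels = np.asarray(group_labels, dtype=bool)
    if labels.size != len(frame):
        raise ValueError("group_labels must match the number of rows")
    if labels.all() or not labels.any():
        raise ValueError("both groups must be nonempty")
    if variables is None:
        variables = [c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])]
    rows = []
    for var in variables:
        if var not in frame.columns:
            raise ValueError(f"unknown variable {var!r}")
        col = frame[var].to_numpy(dtype=float)
        g0, g1 = col[~labels], col[labels]
        _, _, p = two_sample_t(g0, g1)
        rows.append(
            {
                "variable": var,
                "mean_neg": g0.mean(), "sd_neg": g0.std(ddof=1),
                "mean_pos": g1.mean(), "sd_pos": g1.std(ddof=1),
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
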