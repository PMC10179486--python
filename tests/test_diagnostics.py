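"""ROC/AUC, DeLong inference, cutoffs, cutoff-level metrics and descriptives."""

import math

import numpy as np
import pytest
from scipy import stats

from metsdx import (
    roc_curve,
    auc_mann_whitney,
    auc_delong_ci,
    compare_auc_delong,
    youden_optimal_cutoff,
    confusion_at_cutoff,
    diagnostic_summary,
    positivity_rate,
    pearson_r2,
    two_sample_t,
    sds_outlier_screen,
    group_descriptives,
)


def random_instance(rng, max_n=50):
    """Small random scored sample with ties, both classes present."""
    n = int(rng.integers(4, max_n))
    scores = rng.integers(0, 10, size=n).astype(float)  # integer scores force ties
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels


# ---------------------------------------------------------------------------
# ROC / AUC


def test_roc_perfect_separation_and_ties():
    assert roc_curve([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)
    assert roc_curve([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)
    assert roc_curve([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)


def test_roc_curve_shape_invariants(rng):
    for _ in range(50):
        scores, labels = random_instance(rng)
        c = roc_curve(scores, labels)
        assert c.fpr[0] == 0.0 and c.tpr[0] == 0.0
        assert c.fpr[-1] == 1.0 and c.tpr[-1] == 1.0
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)
        assert 0.0 <= c.auc <= 1.0


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="negative"):
        roc_curve([1, 2], [1, 1])
    with pytest.raises(ValueError, match="positive"):
        auc_mann_whitney([1, 2], [0, 0])


def test_auc_label_inversion_and_negation_symmetry(rng):
    scores, labels = random_instance(rng)
    a = auc_mann_whitney(scores, labels)
    assert auc_mann_whitney(scores, ~labels) == pytest.approx(1.0 - a)
    assert roc_curve(-scores, labels).auc == pytest.approx(1.0 - roc_curve(scores, labels).auc)


def test_auc_invariant_under_increasing_transform(rng):
    scores, labels = random_instance(rng)
    assert roc_curve(np.exp(scores / 3) + 5, labels).auc == pytest.approx(
        roc_curve(scores, labels).auc, abs=1e-12
    )


def test_trapezoid_auc_equals_pairwise_oracle(rng):
    for _ in range(100):
        scores, labels = random_instance(rng)
        assert abs(roc_curve(scores, labels).auc - auc_mann_whitney(scores, labels)) <= 1e-12


def test_auc_agrees_with_sklearn():
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(7)
    for _ in range(20):
        scores, labels = random_instance(rng)
        assert roc_curve(scores, labels).auc == pytest.approx(
            sklearn.roc_auc_score(labels, scores), abs=1e-12
        )


# ---------------------------------------------------------------------------
# DeLong


def test_delong_perfect_separation_zero_variance():
    scores = np.r_[np.zeros(20), np.ones(20)]
    labels = np.r_[np.zeros(20, bool), np.ones(20, bool)]
    auc, se, ci = auc_delong_ci(scores, labels)
    assert auc == 1.0 and se == 0.0 and ci == (1.0, 1.0)


def test_delong_ci_width_shrinks_with_sample_size(rng):
    widths = []
    for n in (250, 1000):
        s = np.r_[rng.normal(0, 1, n), rng.normal(1.19, 1, n)]
        y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        _, _, (lo, hi) = auc_delong_ci(s, y)
        widths.append(hi - lo)
    # quadrupling n should roughly halve the width
    assert widths[1] < 0.7 * widths[0]


def test_delong_comparison_identical_and_transformed_scores(rng):
    scores, labels = random_instance(rng, max_n=40)
    same = compare_auc_delong(scores, scores, labels)
    assert same.difference == 0.0 and same.p == 1.0
    trans = compare_auc_delong(scores, 2.0 * scores + 7.0, labels)
    assert trans.difference == pytest.approx(0.0, abs=1e-12)


def test_delong_comparison_detects_informative_score():
    rng = np.random.default_rng(99)
    n = 200
    labels = np.r_[np.zeros(n, bool), np.ones(n, bool)]
    informative = np.r_[rng.normal(0, 1, n), rng.normal(1.19, 1, n)]
    noise = rng.normal(0, 1, 2 * n)
    cmp = compare_auc_delong(informative, noise, labels)
    assert cmp.p < 0.05
    assert math.copysign(1, cmp.z) == math.copysign(1, cmp.difference)


def test_delong_comparison_length_mismatch_rejected():
    with pytest.raises(ValueError, match="same subjects"):
        compare_auc_delong([1, 2, 3], [1, 2], [0, 1, 1])


# ---------------------------------------------------------------------------
# cutoffs


def youden_scan_oracle(scores, labels):
    """Exhaustive scan over all distinct cutoffs (strict >), smallest-tie."""
    best = (-np.inf, None)
    for c in sorted(np.unique(scores)):
        tp, fp, tn, fn = confusion_at_cutoff(scores, labels, c)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best[0] + 1e-15:
            best = (j, c)
    return best[1], best[0]


def test_youden_trivial_cases():
    roc = roc_curve([1, 3, 5, 7], [0, 0, 1, 1])
    cutoff, j = youden_optimal_cutoff(roc)
    assert j == pytest.approx(1.0) and 3 <= cutoff < 5
    cutoff, j = youden_optimal_cutoff(roc_curve([2, 2, 2, 2], [0, 1, 0, 1]))
    assert j == pytest.approx(0.0)


def test_youden_matches_exhaustive_scan(rng):
    for _ in range(200):
        scores, labels = random_instance(rng)
        roc = roc_curve(scores, labels)
        cutoff, j = youden_optimal_cutoff(roc)
        oc, oj = youden_scan_oracle(scores, labels)
        assert j == pytest.approx(oj, abs=1e-12)
        assert cutoff == oc


def test_confusion_counts():
    assert confusion_at_cutoff([2, 3], [1, 1], 1.0) == (2, 0, 0, 0)
    assert confusion_at_cutoff([1, 2], [1, 0], 5.0) == (0, 0, 1, 1)
    # strict >: the 0.9 score is a negative call at cutoff 0.9
    assert confusion_at_cutoff([0.5, 0.9, 1.0, 2.0], [0, 0, 1, 1], 0.9) == (2, 0, 2, 0)


def test_positivity_rate():
    assert positivity_rate([1, 2, 3], 0.0) == 1.0
    assert positivity_rate([1, 2, 3], 3.0) == 0.0
    assert positivity_rate([1, 2, 3, 4, 5], 2.5) == 0.6
    with pytest.raises(ValueError):
        positivity_rate([], 0.0)


# ---------------------------------------------------------------------------
# summary metrics


def counts_for(se, sp, npos=1000, nneg=1000):
    tp = round(se * npos)
    tn = round(sp * nneg)
    return tp, nneg - tn, tn, npos - tp


def test_summary_identities_from_counts():
    s = diagnostic_summary((738, 186, 814, 262))
    assert s.sensitivity == pytest.approx(0.738)
    assert s.specificity == pytest.approx(0.814)
    assert s.youden == pytest.approx(s.sensitivity + s.specificity - 1.0, abs=1e-15)
    assert s.plr == pytest.approx(s.sensitivity / (1 - s.specificity), abs=1e-12)
    assert s.nlr == pytest.approx((1 - s.sensitivity) / s.specificity, abs=1e-12)
    # Bayes at the empirical prevalence reproduces the count-based PPV/NPV
    bayes = diagnostic_summary((738, 186, 814, 262), prevalence_override=0.5)
    assert bayes.ppv == pytest.approx(s.ppv, abs=1e-12)  # balanced counts here
    assert s.ppv == pytest.approx(738 / (738 + 186), abs=1e-12)
    assert s.npv == pytest.approx(814 / (814 + 262), abs=1e-12)


def test_summary_prevalence_transport():
    """PPV/NPV at an external prevalence follow Bayes' rule."""
    s = diagnostic_summary(counts_for(0.738, 0.814), prevalence_override=542 / 876)
    assert round(s.ppv, 3) == 0.866
    assert round(s.youden, 2) == 0.55


def test_perfect_test_has_unit_predictive_values():
    s = diagnostic_summary((10, 0, 10, 0), prevalence_override=0.3)
    assert s.ppv == 1.0 and s.npv == 1.0 and s.plr == math.inf and s.nlr == 0.0


def test_undefined_ratios_are_explicit_markers():
    s = diagnostic_summary((0, 0, 10, 10))  # Se=0, Sp=1
    assert s.plr is None  # 0/0
    assert s.nlr == pytest.approx(1.0)
    t = diagnostic_summary((5, 0, 10, 5))  # Sp=1, Se>0
    assert t.plr == math.inf
    with pytest.raises(ValueError):
        diagnostic_summary((0, 0, 0, 5))


# ---------------------------------------------------------------------------
# descriptive statistics


def test_pearson_exact_line_and_hand_example():
    r, r2, p = pearson_r2([1, 2, 3, 4], [3, 5, 7, 9])
    assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)
    r, r2, p = pearson_r2([1, 2, 3], [1, 2, 4])
    assert round(r2, 4) == 0.9643
    with pytest.raises(ValueError, match="zero-variance"):
        pearson_r2([1, 1, 1], [1, 2, 3])


def test_pearson_null_is_small(rng):
    x, y = rng.normal(size=10_000), rng.normal(size=10_000)
    r, _, _ = pearson_r2(x, y)
    assert abs(r) < 0.03


def test_t_test_identical_and_separated_groups(rng):
    x = [1.0, 2.0, 3.0, 4.0]
    t, df, p = two_sample_t(x, x)
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    a, b = rng.normal(0, 1, 200), rng.normal(1, 1, 200)
    assert two_sample_t(a, b)[2] < 0.001
    with pytest.raises(ValueError):
        two_sample_t([1.0], [1.0, 2.0])


def test_t_test_type_one_error_calibrated():
    rng = np.random.default_rng(2718)
    x = rng.normal(size=(2000, 30))
    y = rng.normal(size=(2000, 30))
    res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    # sanity: vectorized scipy matches our wrapper on the first replicate
    t0, _, p0 = two_sample_t(x[0], y[0])
    assert t0 == pytest.approx(res.statistic[0]) and p0 == pytest.approx(res.pvalue[0])
    rate = float((res.pvalue < 0.05).mean())
    assert 0.035 <= rate <= 0.065


def test_pooled_variant_matches_classic_t():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    t, df, p = two_sample_t(x, y, variant="pooled")
    assert df == pytest.approx(4.0)
    assert t == pytest.approx(-3.674, abs=1e-3)


def test_sds_outlier_screen():
    values = np.r_[np.zeros(100), 10.0]
    flags = sds_outlier_screen(values)
    assert flags.sum() == 1 and flags[-1]
    assert not sds_outlier_screen(np.linspace(-2, 2, 50)).any()
    with pytest.raises(ValueError, match="zero-variance"):
        sds_outlier_screen([3.0, 3.0, 3.0])


def test_group_descriptives_toy_table():
    import pandas as pd

    frame = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    labels = [False, False, False, True, True, True]
    table = group_descriptives(frame, labels)
    row = table.loc["v"]
    assert row.mean_neg == 2.0 and row.mean_pos == 5.0
    assert row.sd_neg == pytest.approx(1.0) and row.sd_pos == pytest.approx(1.0)

    same = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    assert group_descriptives(same, labels).loc["v", "p"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unknown variable"):
        group_descriptives(frame, labels, ["nope"])
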