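"""Tests of ROC construction, DeLong AUC, Youden cut-offs and the
two-threshold referral rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cephscreen.errors import DegenerateLabelsError
from cephscreen.roc import (
    TriageRule,
    auc_ci,
    balanced_accuracy,
    evaluate_triage,
    roc_points,
    triage_cutoffs,
    youden_cutoff,
)
from cephscreen.reference import ROC_REFERENCE

score_sets = st.lists(st.floats(-50, 50, allow_nan=False), min_size=6,
                      max_size=50)


def _random_labels(n, seed):
    rng = np.random.default_rng(seed)
    lab = rng.random(n) < 0.4
    if lab.all():
        lab[0] = False
    if not lab.any():
        lab[0] = True
    return lab


def _oracle_points(scores, labels):
    """Exhaustive threshold enumeration, lower-is-positive."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pts = [(-np.inf, 0.0, 1.0)]
    for v in np.unique(scores):
        called = scores <= v
        sens = np.mean(called[labels])
        spec = np.mean(~called[~labels])
        pts.append((float(v), float(sens), float(spec)))
    return pts


def test_roc_points_match_enumeration_toy():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([True, True, False, False])
    curve = roc_points(scores, labels, "lower")
    oracle = _oracle_points(scores, labels)
    assert len(curve.values) == len(oracle)
    for i, (v, sens, spec) in enumerate(oracle):
        assert curve.values[i] == v
        assert curve.sensitivity[i] == pytest.approx(sens)
        assert curve.specificity[i] == pytest.approx(spec)


@given(score_sets, st.integers(0, 500))
def test_roc_points_match_enumeration_random(scores, seed):
    labels = _random_labels(len(scores), seed)
    curve = roc_points(scores, labels, "lower")
    for v, sens, spec in _oracle_points(scores, labels):
        i = int(np.searchsorted(curve.values, v))
        assert curve.values[i] == v
        assert curve.sensitivity[i] == pytest.approx(sens)
        assert curve.specificity[i] == pytest.approx(spec)
    # extremes present; sensitivity non-decreasing
    assert curve.sensitivity[0] == 0.0 and curve.specificity[0] == 1.0
    assert curve.sensitivity[-1] == 1.0 and curve.specificity[-1] == 0.0
    assert np.all(np.diff(curve.sensitivity) >= 0)


def test_roc_direction_higher_mirrors_lower():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=40)
    labels = _random_labels(40, 1)
    lo = roc_points(scores, labels, "lower")
    hi = roc_points(-scores, labels, "higher")
    assert np.allclose(lo.sensitivity, hi.sensitivity)
    assert np.allclose(lo.specificity, hi.specificity)
    assert np.allclose(lo.values[1:], -hi.values[1:])


def test_one_class_absent_errors():
    with pytest.raises(DegenerateLabelsError):
        roc_points([1.0, 2.0], [True, True], "lower")


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------

def _auc_pair_counting(scores, labels, direction="lower"):
    s = -np.asarray(scores, float) if direction == "lower" else np.asarray(scores, float)
    pos, neg = s[np.asarray(labels, bool)], s[~np.asarray(labels, bool)]
    total = 0.0
    for x in pos:
        for y in neg:
            total += (x > y) + 0.5 * (x == y)
    return total / (len(pos) * len(neg))


@given(score_sets, st.integers(0, 500))
def test_auc_equals_pair_counting(scores, seed):
    labels = _random_labels(len(scores), seed)
    res = auc_ci(scores, labels, "lower")
    assert res.auc == pytest.approx(_auc_pair_counting(scores, labels), abs=1e-12)
    curve = roc_points(scores, labels, "lower")
    assert curve.auc_trapezoid() == pytest.approx(res.auc, abs=1e-12)


def test_auc_edge_cases():
    labels = np.array([True] * 5 + [False] * 5)
    perfect = np.concatenate([np.arange(5), np.arange(10, 15)])
    res = auc_ci(perfect, labels, "lower")
    assert res.auc == 1.0
    assert res.ci_high <= 1.0
    ties = np.ones(10)
    assert auc_ci(ties, labels, "lower").auc == pytest.approx(0.5)
    rng = np.random.default_rng(1)
    noise = auc_ci(rng.normal(size=2000), _random_labels(2000, 2), "lower")
    assert abs(noise.auc - 0.5) < 0.05
    assert noise.p_vs_half > 0.001


def test_delong_interval_behaviour():
    rng = np.random.default_rng(3)
    pos = rng.normal(10, 3, 30)
    neg = rng.normal(15, 3, 70)
    scores = np.concatenate([pos, neg])
    labels = np.array([True] * 30 + [False] * 70)
    res = auc_ci(scores, labels, "lower")
    assert 0.0 < res.se < 0.1
    assert res.ci_low < res.auc < res.ci_high
    assert res.p_vs_half < 0.001


# --------------------------------------------------------------------------
# Youden and balanced accuracy
# --------------------------------------------------------------------------

def test_youden_perfect_separation():
    labels = np.array([True] * 4 + [False] * 4)
    scores = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
    cut = youden_cutoff(roc_points(scores, labels, "lower"))
    assert cut.sensitivity == 1.0 and cut.specificity == 1.0
    assert cut.threshold == 4.0
    assert not cut.degenerate


def test_youden_symmetric_normals_near_midpoint():
    rng = np.random.default_rng(4)
    pos = rng.normal(10, 3, 20000)
    neg = rng.normal(16, 3, 20000)
    scores = np.concatenate([pos, neg])
    labels = np.array([True] * 20000 + [False] * 20000)
    cut = youden_cutoff(roc_points(scores, labels, "lower"))
    assert cut.threshold == pytest.approx(13.0, abs=0.35)


def test_youden_degenerate_flag_on_all_ties():
    labels = np.array([True, False, True, False])
    cut = youden_cutoff(roc_points(np.ones(4), labels, "lower"))
    assert cut.degenerate


@pytest.mark.parametrize("row", ROC_REFERENCE,
                         ids=[f"{r['outcome']}-{r['predictor']}" for r in ROC_REFERENCE])
def test_balanced_accuracy_reproduces_reference_rows(row):
    """100*(sens+spec)/2 reproduces the published balanced accuracy of every
    screening predictor within the rounding of the printed sens/spec."""
    ba = balanced_accuracy(row["sens"], row["spec"])
    assert ba == pytest.approx(row["balanced_accuracy"], abs=0.1)


def test_balanced_accuracy_properties():
    assert balanced_accuracy(1.0, 1.0) == 100.0
    assert balanced_accuracy(0.3, 0.7) == balanced_accuracy(0.7, 0.3)
    # linear in each argument
    assert (balanced_accuracy(0.2, 0.5) + balanced_accuracy(0.8, 0.5)
            ) == pytest.approx(2 * balanced_accuracy(0.5, 0.5))
    with pytest.raises(ValueError):
        balanced_accuracy(1.2, 0.5)


# --------------------------------------------------------------------------
# triage
# --------------------------------------------------------------------------

def test_triage_construction_guarantee_random_datasets():
    """Rules built from the 90/90 targets achieve scheme sensitivity and
    specificity >= 90% on their construction sample, for any class overlap."""
    for seed in range(200):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(10, 60))
        n_neg = int(rng.integers(10, 90))
        shift = float(rng.uniform(0.0, 6.0))
        scores = np.concatenate([rng.normal(10, 3, n_pos),
                                 rng.normal(10 + shift, 3, n_neg)])
        labels = np.array([True] * n_pos + [False] * n_neg)
        rule = triage_cutoffs(roc_points(scores, labels, "lower"), predictor="x")
        ev = evaluate_triage(scores, labels, rule)
        assert ev.sensitivity >= 0.90
        assert ev.specificity >= 0.90
        assert ev.balanced_accuracy >= 90.0


def test_triage_zone_brackets_youden_for_overlapping_classes():
    rng = np.random.default_rng(11)
    scores = np.concatenate([rng.normal(10, 3, 50000),
                             rng.normal(15, 3, 50000)])
    labels = np.array([True] * 50000 + [False] * 50000)
    curve = roc_points(scores, labels, "lower")
    rule = triage_cutoffs(curve, predictor="x")
    cut = youden_cutoff(curve)
    assert rule.lower < cut.threshold < rule.upper
    ev = evaluate_triage(scores, labels, rule)
    assert ev.sensitivity >= 0.90 and ev.specificity >= 0.90


def test_triage_collapse_on_separable_data():
    """Separable classes: the two targets may collapse to one threshold
    (empty referral zone), or cross (specificity target beyond the
    sensitivity one); both are valid rules with perfect performance."""
    labels = np.array([True] * 20 + [False] * 20)
    scores = np.concatenate([np.repeat([1.0, 2.0], 10), np.repeat([3.0, 4.0], 10)])
    rule = triage_cutoffs(roc_points(scores, labels, "lower"), predictor="x")
    assert rule.lower == rule.upper == 2.0
    ev = evaluate_triage(scores, labels, rule)
    assert ev.deferral_fraction == 0.0
    assert ev.sensitivity == 1.0 and ev.specificity == 1.0
    # widely separated continuous scores: thresholds cross, no exception
    scores2 = np.concatenate([np.linspace(1, 5, 20), np.linspace(100, 120, 20)])
    rule2 = triage_cutoffs(roc_points(scores2, labels, "lower"), predictor="x")
    assert rule2.crossed
    ev2 = evaluate_triage(scores2, labels, rule2)
    assert ev2.sensitivity == 1.0 and ev2.specificity == 1.0


def test_triage_upper_equals_single_cutoff_when_sens_target_at_youden():
    """A predictor whose Youden point already reaches 90% sensitivity keeps
    that value as the upper referral threshold (the GoGn pattern)."""
    pos = np.concatenate([np.linspace(70, 88, 18), [89.0, 90.2]])
    neg = np.concatenate([np.linspace(80, 95, 14), np.linspace(91, 110, 6)])
    scores = np.concatenate([pos, neg])
    labels = np.array([True] * 20 + [False] * 20)
    curve = roc_points(scores, labels, "lower")
    cut = youden_cutoff(curve)
    rule = triage_cutoffs(curve, predictor="GoGn-like")
    if cut.sensitivity >= 0.90:
        assert rule.upper == cut.threshold


def test_widening_referral_zone_never_hurts():
    rng = np.random.default_rng(12)
    scores = np.concatenate([rng.normal(10, 3, 40), rng.normal(14, 3, 60)])
    labels = np.array([True] * 40 + [False] * 60)
    base = triage_cutoffs(roc_points(scores, labels, "lower"), predictor="x")
    ev0 = evaluate_triage(scores, labels, base)
    for dlow, dhigh in ((1.0, 0.0), (0.0, 1.0), (2.0, 2.0)):
        wider = TriageRule(predictor="x", lower=base.lower - dlow,
                           upper=base.upper + dhigh)
        ev = evaluate_triage(scores, labels, wider)
        assert ev.sensitivity >= ev0.sensitivity - 1e-12
        assert ev.specificity >= ev0.specificity - 1e-12


def test_evaluate_triage_degenerate_zones():
    scores = np.array([1.0, 2, 3, 10, 11, 12])
    labels = np.array([True, True, True, False, False, False])
    binary = TriageRule(predictor="x", lower=5.0, upper=5.0)
    ev = evaluate_triage(scores, labels, binary)
    assert ev.sensitivity == 1.0 and ev.specificity == 1.0
    assert ev.deferral_fraction == 0.0
    everything = TriageRule(predictor="x", lower=-100.0, upper=100.0)
    ev2 = evaluate_triage(scores, labels, everything)
    assert ev2.sensitivity == 1.0 and ev2.specificity == 1.0
    assert ev2.deferral_fraction == 1.0


def test_triage_rule_validation():
    with pytest.raises(ValueError):
        TriageRule(predictor="x", lower=5.0, upper=4.0)
    labels = np.array([True, False] * 5)
    with pytest.raises(ValueError):
        triage_cutoffs(roc_points(np.arange(10.0), labels, "lower"),
                       sens_target=1.5)
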