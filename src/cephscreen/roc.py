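"""ROC analysis and the two-threshold referral (triage) rule.

The screening logic: a continuous predictor (e.g. the IPAS sagittal airway
diameter) is evaluated against a binary three-dimensional outcome (SASN or
RSAV). For airway predictors *lower* values indicate the positive class, so
the direction is carried as an explicit flag and all reported thresholds stay
on the original measurement scale.

Beyond the usual single Youden cut-off, a gray zone is defined by two
empirical thresholds: the value where specificity reaches 90% (bounding the
classify-positive zone) and the value where sensitivity reaches 90%
(bounding the classify-negative zone). Cases between them are referred to
three-dimensional imaging, which is assumed definitive, so the scheme's
sensitivity and specificity are both >= 90% on the construction sample by
design — a prevalence-independent balanced accuracy above 90%.

Because the empirical ROC is a step function, "the value where sensitivity
is 90%" is implemented as the least extreme observed value achieving >= 90%
(conservative). AUC uncertainty uses the DeLong variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateLabelsError, UnattainableTargetError


def _check_labels(labels) -> np.ndarray:
    lab = np.asarray(labels).astype(bool)
    if lab.all() or not lab.any():
        raise DegenerateLabelsError("both outcome classes must be present")
    return lab


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    """Map scores so that *larger* oriented score means more positive."""
    if direction == "lower":
        return -scores
    if direction == "higher":
        return scores
    raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")


@dataclass
class RocCurve:
    """Empirical ROC curve for one predictor.

    ``values`` are the classification boundaries on the original scale, one
    per curve point, ordered by increasing sensitivity; for
    ``direction='lower'`` a case is called positive when score <= value.
    The first point (value -inf/+inf) calls nothing positive: (sens 0,
    spec 1); the last calls everything positive: (sens 1, spec 0).
    ``thresholds`` are the equivalent midpoint cut-offs between consecutive
    distinct scores.
    """

    values: np.ndarray
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str
    n_pos: int
    n_neg: int

    def auc_trapezoid(self) -> float:
        fpr = 1.0 - self.specificity
        return float(np.trapezoid(self.sensitivity, fpr))


def roc_points(scores, labels, direction: str = "lower") -> RocCurve:
    """Exact empirical ROC over every distinct observed threshold."""
    scores = np.asarray(scores, dtype=float)
    lab = _check_labels(labels)
    if scores.shape != lab.shape:
        raise ValueError("scores and labels must have equal length")
    s = _oriented(scores, direction)
    order = np.argsort(-s, kind="stable")  # most-positive oriented first
    s_sorted, lab_sorted = s[order], lab[order]
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())

    distinct = np.concatenate(([True], np.diff(s_sorted) != 0))
    tps = np.cumsum(lab_sorted)
    fps = np.cumsum(~lab_sorted)
    # curve points at the *last* index of each tied block
    block_ends = np.flatnonzero(np.concatenate((distinct[1:], [True])))
    sens = np.concatenate(([0.0], tps[block_ends] / n_pos))
    spec = np.concatenate(([1.0], 1.0 - fps[block_ends] / n_neg))
    oriented_vals = np.concatenate(([np.inf], s_sorted[block_ends]))

    if direction == "lower":
        values = -oriented_vals
    else:
        values = oriented_vals
    # midpoint thresholds between consecutive distinct original values
    dv = values.copy()
    mids = np.empty_like(dv)
    mids[0] = -np.inf if direction == "lower" else np.inf
    if dv.size > 2:
        mids[1:-1] = (dv[1:-1] + dv[2:]) / 2.0
    if dv.size > 1:
        mids[-1] = np.inf if direction == "lower" else -np.inf
    return RocCurve(
        values=values, thresholds=mids, sensitivity=sens, specificity=spec,
        direction=direction, n_pos=n_pos, n_neg=n_neg,
    )


# --------------------------------------------------------------------------
# AUC with DeLong uncertainty
# --------------------------------------------------------------------------

@dataclass
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_vs_half: float


def auc_ci(scores, labels, direction: str = "lower",
           alpha: float = 0.05) -> AucResult:
    """AUC (Mann-Whitney with tie correction), DeLong SE, Wald CI, p vs 0.5."""
    scores = np.asarray(scores, dtype=float)
    lab = _check_labels(labels)
    s = _oriented(scores, direction)
    x, y = s[lab], s[~lab]  # positives, negatives
    m, n = x.size, y.size
    # placement values
    psi = (x[:, None] > y[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == y[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)   # per-positive placements
    v01 = psi.mean(axis=0)   # per-negative placements
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = sps.norm.ppf(1 - alpha / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return AucResult(auc=auc, se=se, ci_low=lo, ci_high=hi, p_vs_half=p)


# --------------------------------------------------------------------------
# cut-offs
# --------------------------------------------------------------------------

@dataclass
class YoudenCutoff:
    threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def youden_cutoff(curve: RocCurve) -> YoudenCutoff:
    """Threshold maximising J = sens + spec - 1.

    Ties break toward higher specificity, then the less extreme threshold.
    When no threshold beats chance (all scores tied), the result carries a
    ``degenerate`` flag.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    jmax = j.max()
    idx = np.flatnonzero(np.isclose(j, jmax))
    best = idx[np.argsort(-curve.specificity[idx], kind="stable")[0]]
    # prefer highest specificity; among those, the earliest (least extreme)
    cand = idx[np.isclose(curve.specificity[idx], curve.specificity[best])]
    best = int(cand.min())
    return YoudenCutoff(
        threshold=float(curve.values[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        degenerate=bool(jmax <= 0),
    )


def balanced_accuracy(sens: float, spec: float) -> float:
    """Prevalence-independent accuracy, percent: 100 * (sens + spec) / 2."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return 100.0 * (sens + spec) / 2.0


# --------------------------------------------------------------------------
# two-threshold triage rule
# --------------------------------------------------------------------------

@dataclass
class TriageRule:
    """Two thresholds partitioning a predictor into three decision zones.

    For ``direction='lower'`` (low value = positive): score <= lower is
    classified positive; score > upper is classified negative; scores in
    (lower, upper] are referred to three-dimensional imaging. ``crossed``
    records that the specificity-target point exceeded the
    sensitivity-target point before sorting (very separable data); the
    scheme guarantees still hold.
    """

    predictor: str
    lower: float
    upper: float
    direction: str = "lower"
    sens_target: float = 0.90
    spec_target: float = 0.90
    crossed: bool = False

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower threshold must be <= upper threshold")

    def zones(self, scores) -> np.ndarray:
        """Per-case decision: 'positive', 'refer' or 'negative'."""
        s = np.asarray(scores, dtype=float)
        out = np.full(s.shape, "refer", dtype=object)
        if self.direction == "lower":
            out[s <= self.lower] = "positive"
            out[s > self.upper] = "negative"
        else:
            out[s >= self.upper] = "positive"
            out[s < self.lower] = "negative"
        return out

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor, "lower": self.lower,
            "upper": self.upper, "direction": self.direction,
            "sens_target": self.sens_target, "spec_target": self.spec_target,
            "crossed": self.crossed,
        }


def triage_cutoffs(curve: RocCurve, sens_target: float = 0.90,
                   spec_target: float = 0.90, predictor: str = "") -> TriageRule:
    """Derive the referral zone from sensitivity/specificity targets.

    One threshold is the least extreme observed value with sensitivity >=
    ``sens_target`` (bounding the classify-negative zone); the other the
    most extreme value keeping specificity >= ``spec_target`` (bounding the
    classify-positive zone). They are stored sorted as (lower, upper).
    """
    if not (0 < sens_target < 1 and 0 < spec_target < 1):
        raise ValueError("targets must lie in (0, 1)")
    sens_ok = np.flatnonzero(curve.sensitivity >= sens_target)
    spec_ok = np.flatnonzero(curve.specificity >= spec_target)
    if sens_ok.size == 0 or spec_ok.size == 0:
        raise UnattainableTargetError(
            f"targets (sens {sens_target}, spec {spec_target}) unreachable "
            "on the empirical curve")
    # sensitivity is non-decreasing along the curve: first index reaching it
    t_sens = float(curve.values[int(sens_ok.min())])
    # specificity is non-increasing: last index keeping it
    t_spec = float(curve.values[int(spec_ok.max())])
    if curve.direction == "lower":
        lower, upper = min(t_spec, t_sens), max(t_spec, t_sens)
        crossed = t_spec > t_sens
    else:
        lower, upper = min(t_spec, t_sens), max(t_spec, t_sens)
        crossed = t_spec < t_sens
    return TriageRule(
        predictor=predictor, lower=lower, upper=upper,
        direction=curve.direction, sens_target=sens_target,
        spec_target=spec_target, crossed=crossed,
    )


@dataclass
class TriageEvaluation:
    """Performance of a triage rule with referral assumed definitive."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    deferral_fraction: float
    n_pos: int
    n_neg: int


def evaluate_triage(scores, labels, rule: TriageRule) -> TriageEvaluation:
    """Score a rule: referred cases count as correctly resolved.

    Scheme sensitivity = (positives classified positive + positives
    referred) / n_pos, and analogously for specificity.
    """
    scores = np.asarray(scores, dtype=float)
    lab = _check_labels(labels)
    zones = rule.zones(scores)
    pos, neg = lab, ~lab
    sens = float(np.mean(zones[pos] != "negative"))
    spec = float(np.mean(zones[neg] != "positive"))
    return TriageEvaluation(
        sensitivity=sens, specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        deferral_fraction=float(np.mean(zones == "refer")),
        n_pos=int(pos.sum()), n_neg=int(neg.sum()),
    )


# --------------------------------------------------------------------------
# plotting
# --------------------------------------------------------------------------

def plot_roc(curves: dict[str, RocCurve], ax=None):
    """Plot one or more ROC curves (sensitivity vs 1 - specificity)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        auc = curve.auc_trapezoid()
        ax.plot(1.0 - curve.specificity, curve.sensitivity,
                drawstyle="steps-post", label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax
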