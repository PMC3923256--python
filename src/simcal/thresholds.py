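"""Operating-point statistics, ROC curves and optimal-threshold selection.

A pair is predicted "similar" when its computed similarity is greater than
or equal to the threshold t (inclusive).  Sweeping t over the midpoints
between consecutive distinct similarity values traces the full ROC curve;
the area under it (trapezoidal) equals the Mann–Whitney concordance
probability with ties counted 1/2.

The operating threshold t_ROC is the candidate maximizing the Youden index
(sensitivity + specificity − 1) among thresholds meeting configurable
sensitivity/specificity floors, with ties broken by Matthews correlation,
then accuracy, then the smaller threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["OperatingPoint", "confusion_at", "roc_curve", "auc", "select_t_roc"]


@dataclass
class OperatingPoint:
    """Confusion counts and the seven derived statistics at one threshold.

    Ratio statistics with a zero denominator are reported as ``nan`` (never
    silently as 0).  The two sentinel curve endpoints carry thresholds of
    −inf (everything predicted similar) and +inf (nothing predicted similar);
    every selectable threshold lies in [0, 1].
    """

    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_index: float
    youden: float
    mcc: float
    predicted_probability: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def point_from_counts(tp: int, tn: int, fp: int, fn: int, threshold: float = float("nan")) -> OperatingPoint:
    """Build an :class:`OperatingPoint` from integer confusion counts.

    All statistics are evaluated from the unrounded integer counts; the MCC
    numerator and the product under its square root are computed in exact
    integer arithmetic before the single floating-point division.
    """
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    mcc_den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)  # exact int product
    mcc = (tp * tn - fp * fn) / math.isqrt(mcc_den2) if _is_square_exact(mcc_den2) else (
        (tp * tn - fp * fn) / math.sqrt(mcc_den2) if mcc_den2 else float("nan")
    )
    return OperatingPoint(
        threshold=threshold,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        precision=_ratio(tp, tp + fp),
        accuracy=(tp + tn) / n,
        f_index=_ratio(2 * tp, 2 * tp + fp + fn),
        youden=sens + spec - 1.0,
        mcc=mcc,
    )


def _is_square_exact(v: int) -> bool:
    if v <= 0:
        return False
    r = math.isqrt(v)
    return r * r == v


def confusion_at(similarities, labels, t: float) -> OperatingPoint:
    """Confusion matrix at threshold ``t`` (similar iff similarity >= t)."""
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size == 0:
        raise ValueError("empty input")
    if not math.isfinite(t) and not math.isinf(t):
        raise ValueError("threshold must not be NaN")
    pred = s >= t
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    return point_from_counts(tp, tn, fp, fn, threshold=t)


def _candidate_thresholds(s: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct similarities."""
    u = np.unique(s)
    return (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)


def roc_curve(similarities, labels) -> list[OperatingPoint]:
    """Operating points swept over all distinguishable thresholds.

    Includes the two sentinel endpoints, so the curve always contains
    (1−specificity, sensitivity) = (0, 0) and (1, 1); points are ordered by
    (1−specificity, sensitivity) ascending.
    """
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size == 0:
        raise ValueError("empty input")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to build a ROC curve")
    thresholds = np.concatenate(([-np.inf], _candidate_thresholds(s), [np.inf]))
    points = [confusion_at(s, y, t) for t in thresholds]
    points.sort(key=lambda p: (1.0 - p.specificity, p.sensitivity))
    return points


def auc(roc: list[OperatingPoint]) -> float:
    """Trapezoidal area under the ROC curve over (1−specificity, sensitivity)."""
    fpr = np.array([1.0 - p.specificity for p in roc])
    tpr = np.array([p.sensitivity for p in roc])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def select_t_roc(
    similarities,
    labels,
    min_sens: float = 0.9,
    min_spec: float = 0.85,
) -> OperatingPoint:
    """Choose the operating threshold t_ROC.

    Among midpoint thresholds whose sensitivity and specificity both meet
    the floors, return the one maximizing the Youden index (ties: higher
    MCC, then higher accuracy, then smaller threshold).  If no threshold
    meets the floors they are relaxed with a warning and the unconstrained
    Youden maximum is returned.
    """
    s = np.asarray(similarities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size == 0:
        raise ValueError("empty input")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to select a threshold")
    cands = _candidate_thresholds(s)
    if cands.size == 0:  # all similarities identical: only degenerate thresholds exist
        cands = np.array([float(s[0])])
    points = [confusion_at(s, y, t) for t in cands]

    def rank(p: OperatingPoint):
        mcc = p.mcc if math.isfinite(p.mcc) else -2.0
        return (p.youden, mcc, p.accuracy, -p.threshold)

    admissible = [p for p in points if p.sensitivity >= min_sens and p.specificity >= min_spec]
    if not admissible:
        warnings.warn(
            f"no threshold meets sensitivity >= {min_sens} and specificity >= {min_spec}; "
            "floors relaxed, returning the unconstrained Youden maximum",
            stacklevel=2,
        )
        admissible = points
    return replace(max(admissible, key=rank))
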