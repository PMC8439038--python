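"""Specificity-anchored cutoffs, ROC curves and positive/negative calls.

Diagnostic thresholds here are anchored on specificity: given a
reference population (healthy controls, or other diseases excluding
SLE), the cutoff is the smallest threshold at which no more than
``floor((1 − target_specificity) · n)`` reference subjects are called
positive. Candidate thresholds are midpoints between consecutive sorted
distinct reference values plus the maximum value itself, so the cutoff
never lands on an observed value where the strict/non-strict boundary
choice would matter. Positivity is strictly greater than the threshold,
which makes "threshold = reference maximum" yield exactly 100%
specificity. Because allowed exceedances are floored, the achieved
specificity is always ≥ the target (the conservative side).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MIN_REFERENCE_N = 10

REFERENCE_LABELS = ("healthy_controls", "other_diseases_excl_SLE", "custom")


class ReferenceTooSmallError(ValueError):
    """Reference population too small for cutoff estimation."""


@dataclass
class ReferenceSet:
    label: str
    values: np.ndarray

    def __init__(self, label: str, values: Sequence[float]):
        if label not in REFERENCE_LABELS:
            raise ValueError(
                f"unknown reference label {label!r}; expected one of {REFERENCE_LABELS}"
            )
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("reference values must be finite")
        self.label = label
        self.values = arr

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class Cutoff:
    marker_id: str
    reference_label: str
    target_specificity: float
    threshold: float
    achieved_specificity: float
    reference_n: int = 0


@dataclass
class ROCCurve:
    """Points ordered by increasing threshold; AUC by the trapezoid rule."""

    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float


@dataclass
class PerformanceSummary:
    marker_id: str
    cohort_label: str
    n: int
    n_positive: int
    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float] = None
    flags: set[str] = field(default_factory=set)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted distinct values, plus the max."""
    distinct = np.unique(values)
    if distinct.size == 1:
        return distinct
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.append(mids, distinct[-1])


def threshold_at_specificity(values: Sequence[float], target_specificity: float) -> float:
    """Smallest midpoint threshold with ≤ floor((1−target)·n) exceedances.

    The bare search, without the reference-size contract of
    :func:`cutoff_at_specificity`; used directly where the reference
    group is legitimately small (e.g. non-responder strata). Accepts
    ``target_specificity`` up to and including 1 (zero exceedances).
    """
    if not (0.0 < target_specificity <= 1.0):
        raise ValueError(f"target_specificity must be in (0, 1], got {target_specificity}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("reference values must be non-empty")
    allowed = math.floor((1.0 - target_specificity) * arr.size)
    for t in _candidate_thresholds(arr):
        if int(np.sum(arr > t)) <= allowed:
            return float(t)
    raise AssertionError("unreachable: the maximum value admits zero exceedances")


def cutoff_at_specificity(
    reference: ReferenceSet,
    target_specificity: float,
    marker_id: str = "marker",
) -> Cutoff:
    """Smallest midpoint threshold achieving the target specificity.

    Allowed exceedances on the reference set are
    ``floor((1 − target) · n)``; the returned threshold is the smallest
    candidate with no more than that many reference values strictly above
    it, and the achieved specificity is reported from the reference set.
    """
    if not (0.0 < target_specificity < 1.0):
        raise ValueError(
            f"target_specificity must be in (0, 1), got {target_specificity}"
        )
    if reference.n < MIN_REFERENCE_N:
        raise ReferenceTooSmallError(
            f"reference too small: n={reference.n} < {MIN_REFERENCE_N}"
        )
    values = reference.values
    n = reference.n
    allowed = math.floor((1.0 - target_specificity) * n)

    distinct = np.unique(values)
    if distinct.size == 1:
        warnings.warn(
            f"all {n} reference values identical ({distinct[0]}); "
            "cutoff placed on that value",
            stacklevel=2,
        )
        return Cutoff(
            marker_id=marker_id,
            reference_label=reference.label,
            target_specificity=target_specificity,
            threshold=float(distinct[0]),
            achieved_specificity=1.0,
            reference_n=n,
        )

    t = threshold_at_specificity(values, target_specificity)
    exceed = int(np.sum(values > t))
    assert exceed <= allowed
    return Cutoff(
        marker_id=marker_id,
        reference_label=reference.label,
        target_specificity=target_specificity,
        threshold=t,
        achieved_specificity=1.0 - exceed / n,
        reference_n=n,
    )


def classify(value: float, cutoff: Cutoff) -> bool:
    """Positive iff the net OD is strictly greater than the threshold."""
    if not math.isfinite(cutoff.threshold):
        raise ValueError("cutoff threshold must be finite")
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    return value > cutoff.threshold


def roc_points(
    positives: Sequence[float], negatives: Sequence[float]
) -> ROCCurve:
    """Empirical ROC curve with midpoint thresholds and trapezoid AUC.

    One point per midpoint of the pooled distinct values, with ±inf
    sentinels as curve endpoints. Ties are pooled: a value tied with a
    threshold is counted on whichever side its strict-greater
    classification puts it (this is what midpoint candidates guarantee
    for interior points).
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positive and negative groups must be non-empty")

    pooled = np.unique(np.concatenate([pos, neg]))
    if pooled.size > 1:
        interior = (pooled[:-1] + pooled[1:]) / 2.0
    else:
        interior = np.array([], dtype=float)
    thresholds = np.concatenate([[-np.inf], interior, [np.inf]])

    points: list[tuple[float, float, float]] = []
    for t in thresholds:
        sens = float(np.mean(pos > t))
        spec = float(np.mean(neg <= t))
        points.append((float(t), sens, spec))

    # integrate TPR over FPR; thresholds ascend so FPR descends
    fpr = np.array([1.0 - p[2] for p in points])
    tpr = np.array([p[1] for p in points])
    order = np.lexsort((tpr, fpr))  # ascending fpr, ties resolved by tpr
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return ROCCurve(points=points, auc=auc)


def performance_at_cutoff(
    values: Sequence[float],
    labels: Sequence[bool],
    cutoff: Cutoff,
    cohort_label: str = "",
) -> PerformanceSummary:
    """Sensitivity (and specificity, when negatives exist) at a cutoff.

    Sensitivity is the fraction of label-positive subjects strictly above
    the threshold; with no label-positive subjects it is reported as
    missing with a flag rather than raising.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=bool)
    if vals.shape != labs.shape:
        raise ValueError("values and labels must be aligned")
    calls = vals > cutoff.threshold
    flags: set[str] = set()

    n_diseased = int(labs.sum())
    n_pos = int((calls & labs).sum())
    if n_diseased == 0:
        sensitivity = None
        flags.add("NO_LABEL_POSITIVE")
    else:
        sensitivity = round(100.0 * n_pos / n_diseased, 1)

    n_healthy = int((~labs).sum())
    if n_healthy == 0:
        specificity = None
    else:
        specificity = round(100.0 * int((~calls & ~labs).sum()) / n_healthy, 1)

    return PerformanceSummary(
        marker_id=cutoff.marker_id,
        cohort_label=cohort_label,
        n=n_diseased,
        n_positive=n_pos,
        sensitivity_pct=sensitivity,
        specificity_pct=specificity,
        flags=flags,
    )


def bootstrap_threshold_ci(
    reference: ReferenceSet,
    target_specificity: float,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the specificity-anchored threshold.

    Optional extension, off the main path: resamples the reference set
    with replacement and recomputes the cutoff each time.
    """
    rng = np.random.default_rng(seed)
    n = reference.n
    thresholds = np.empty(n_boot)
    for i in range(n_boot):
        resampled = ReferenceSet(
            reference.label, rng.choice(reference.values, size=n, replace=True)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thresholds[i] = cutoff_at_specificity(
                resampled, target_specificity
            ).threshold
    lo, hi = np.quantile(thresholds, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
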