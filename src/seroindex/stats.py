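"""Group comparisons, correlations and treatment-response analyses.

Nonparametric throughout, matching common serology practice: Mann-Whitney
U for two-group OD contrasts, Spearman rank correlation for paired
continuous measures, and specificity-anchored ROC for response
prediction. Small samples get exact inference: the Mann-Whitney p-value
is computed by full enumeration of the C(n, n_a) group assignments of
the combined multiset (valid with ties) whenever the combined n is at
most 12, and the Spearman p-value by full permutation for n ≤ 8. Larger
samples use the normal approximation with tie and continuity corrections
(Mann-Whitney) and the t approximation (Spearman). All tests are
two-sided; p-values are nominal, with Benjamini-Hochberg adjustment
available as an opt-in column.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cutoffs import threshold_at_specificity
from .records import SubjectRecord

logger = logging.getLogger(__name__)

#: Combined sample size at or below which exact enumeration is used.
EXACT_ENUMERATION_LIMIT = 12

#: Sample size at or below which the exact permutation Spearman p is used.
SPEARMAN_EXACT_LIMIT = 8


@dataclass
class GroupComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    marker: str = ""
    method: str = ""  # "exact" | "asymptotic"
    p_adjusted: Optional[float] = None


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    n: int
    rho: Optional[float]
    p_value: Optional[float]
    method: str = ""
    flags: set[str] = field(default_factory=set)


@dataclass
class ResponseAnalysis:
    treatment: str
    stratum: str
    n: int
    n_responders: int
    cutoff_used: float
    sensitivity_pct: float
    specificity_pct: float
    responder_rate_pct: float
    threshold_source: str = ""  # "roc" | "fixed"


@dataclass
class StratumRate:
    stratum: str
    n: int
    n_responders: int
    rate_pct: Optional[float]
    ci_low_pct: Optional[float]
    ci_high_pct: Optional[float]


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a > b) pairs plus half the tied pairs."""
    a = a[:, None]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    marker: str = "",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two OD groups.

    Exact p by enumeration of all group assignments of the combined
    multiset when n_a + n_b ≤ 12 (correct with ties); otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")

    u_obs = _u_statistic(x, y)
    n_total = x.size + y.size
    if n_total <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([x, y])
        center = x.size * y.size / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        idx = np.arange(n_total)
        for combo in itertools.combinations(idx, x.size):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "asymptotic"

    return GroupComparison(
        group_a_label=label_a,
        group_b_label=label_b,
        n_a=int(x.size),
        n_b=int(y.size),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        u_statistic=u_obs,
        p_value=min(p, 1.0),
        marker=marker,
        method=method,
    )


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> CorrelationResult:
    """Spearman rank correlation with exact permutation p for n ≤ 8.

    rho is the Pearson correlation of mid-ranks. Constant input leaves
    rho undefined (flagged) rather than raising.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must be paired")
    n = xv.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return CorrelationResult(
            variable_x=label_x, variable_y=label_y, n=n,
            rho=None, p_value=None, flags={"CONSTANT_INPUT"},
        )

    rx, ry = _rank(xv), _rank(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= SPEARMAN_EXACT_LIMIT:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        res = sps.spearmanr(xv, yv)
        p = float(res.pvalue)
        method = "t-approximation"

    return CorrelationResult(
        variable_x=label_x, variable_y=label_y, n=n,
        rho=rho, p_value=p, method=method,
    )


def response_roc(
    marker_values: Sequence[float],
    responder_labels: Sequence[bool],
    target_specificity: Optional[float] = None,
    fixed_threshold: Optional[float] = None,
    treatment: str = "",
    stratum: str = "all",
    higher_in_responders: bool = True,
) -> ResponseAnalysis:
    """Response detection at a specificity-anchored or fixed threshold.

    Non-responders are the reference population: with a target
    specificity the threshold comes from the same specificity-anchored
    search used for diagnostic cutoffs, and sensitivity is reported among
    responders. Alternatively an externally supplied fixed threshold
    (e.g. a published RA-specific cutoff) is evaluated directly. The
    direction — responders expected to sit higher — is explicit; with
    ``higher_in_responders=False`` the analysis runs on negated values
    and the threshold is reported back on the original scale.
    """
    vals = np.asarray(marker_values, dtype=float)
    labs = np.asarray(responder_labels, dtype=bool)
    if vals.shape != labs.shape:
        raise ValueError("values and labels must be aligned")
    if labs.all() or (~labs).all():
        raise ValueError("both responders and non-responders must be present")
    if (target_specificity is None) == (fixed_threshold is None):
        raise ValueError("supply exactly one of target_specificity or fixed_threshold")

    sign = 1.0 if higher_in_responders else -1.0
    v = sign * vals

    if fixed_threshold is not None:
        threshold = sign * fixed_threshold
        source = "fixed"
    else:
        # non-responders are the reference; strata may be small, so the
        # bare threshold search is used (no reference-size floor)
        threshold = threshold_at_specificity(v[~labs], target_specificity)
        source = "roc"

    calls = v > threshold
    sens = 100.0 * float(calls[labs].mean())
    spec = 100.0 * float((~calls[~labs]).mean())
    logger.info(
        "response ROC (%s, %s): direction=%s threshold=%.4f sens=%.1f%% spec=%.1f%%",
        treatment or "?", stratum,
        "higher-in-responders" if higher_in_responders else "lower-in-responders",
        sign * threshold, sens, spec,
    )
    return ResponseAnalysis(
        treatment=treatment,
        stratum=stratum,
        n=int(vals.size),
        n_responders=int(labs.sum()),
        cutoff_used=float(sign * threshold),
        sensitivity_pct=sens,
        specificity_pct=spec,
        responder_rate_pct=100.0 * float(labs.mean()),
        threshold_source=source,
    )


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, as fractions."""
    ci = sps.binomtest(k, n).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return float(ci.low), float(ci.high)


def responder_rate_by_cn_sign(
    records: Sequence[SubjectRecord], treatment: Optional[str] = None
) -> list[StratumRate]:
    """Responder percentage within negative- and non-negative-delta strata.

    Records are restricted to one treatment (pass it, or pre-filter);
    subjects without a response label are excluded and counted in the
    log. Rates come with exact 95% Clopper-Pearson intervals; an empty
    stratum reports a missing rate with n = 0.
    """
    if treatment is not None:
        records = [r for r in records if r.treatment == treatment]
    labelled = [r for r in records if r.eular_responder_6m is not None]
    n_dropped = len(records) - len(labelled)
    if n_dropped:
        logger.info("responder_rate_by_cn_sign: %d records without response label excluded", n_dropped)

    out: list[StratumRate] = []
    for stratum, keep in (
        ("negative_delta", lambda r: r.delta < 0),
        ("non_negative_delta", lambda r: r.delta >= 0),
    ):
        members = [r for r in labelled if keep(r)]
        n = len(members)
        k = sum(bool(r.eular_responder_6m) for r in members)
        if n == 0:
            out.append(StratumRate(stratum, 0, 0, None, None, None))
            continue
        lo, hi = clopper_pearson(k, n)
        out.append(
            StratumRate(stratum, n, k, 100.0 * k / n, 100.0 * lo, 100.0 * hi)
        )
    return out


GROUPINGS = {
    "progression": lambda r: r.arthritis_progression,
    "lung_pc": lambda r: r.lung_parenchymal_change,
    "se_copies": lambda r: r.se_copies,
}

_MARKER_GETTERS = {
    "cit": lambda r: r.cit_net,
    "native": lambda r: r.native_net,
    "delta": lambda r: r.delta,
}


def group_contrast_suite(
    records: Sequence[SubjectRecord],
    grouping: str,
    adjust: bool = False,
) -> list[GroupComparison]:
    """Pairwise Mann-Whitney contrasts for each marker across group levels.

    For the shared-epitope dosage all three pairwise contrasts (0 vs 1,
    0 vs 2, 1 vs 2) are run per marker. Records with a missing grouping
    value are excluded per-analysis (logged, never imputed); a level with
    fewer than 2 records is skipped with a warning. Nominal p-values;
    ``adjust=True`` adds a Benjamini-Hochberg column across the suite.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; allowed: {sorted(GROUPINGS)}")
    getter = GROUPINGS[grouping]
    kept = [r for r in records if getter(r) is not None]
    n_missing = len(records) - len(kept)
    if n_missing:
        logger.info("grouping %s: excluded %d records with missing value", grouping, n_missing)

    levels = sorted({getter(r) for r in kept})
    comparisons: list[GroupComparison] = []
    for marker, get_val in _MARKER_GETTERS.items():
        for la, lb in itertools.combinations(levels, 2):
            ga = [get_val(r) for r in kept if getter(r) == la]
            gb = [get_val(r) for r in kept if getter(r) == lb]
            if len(ga) < 2 or len(gb) < 2:
                logger.warning(
                    "grouping %s marker %s: contrast %s vs %s skipped (level with <2 records)",
                    grouping, marker, la, lb,
                )
                continue
            comparisons.append(
                mann_whitney(
                    ga, gb,
                    label_a=f"{grouping}={la}", label_b=f"{grouping}={lb}",
                    marker=marker,
                )
            )
    if adjust and comparisons:
        adjusted = sps.false_discovery_control(
            [c.p_value for c in comparisons], method="bh"
        )
        for c, q in zip(comparisons, adjusted):
            c.p_adjusted = float(q)
    return comparisons
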