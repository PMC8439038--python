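"""Citrullinated/native delta index (CN-index), panel positivity and tables.

The CN-index for one subject is the difference between the
citrullinated-antigen and native-antigen net ODs (delta = cit − native).
Its sign stratifies subjects: a negative index means the native signal
dominates; a strongly negative index (delta < −0.1) is a pattern seen
almost exclusively in lupus sera. The combined panel ("total") calls a
subject positive when any of the three markers — citrullinated, native,
or delta — exceeds its own cutoff.

The delta marker gets its own specificity-anchored cutoffs estimated
from the delta values of the reference populations, by the same
procedure as the single markers; it is never classified through the
cit/native cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cutoffs import Cutoff, classify
from .records import SubjectRecord

#: Delta below this bound is annotated "strong negative" (native signal
#: dominating by more than 0.1 OD).
STRONG_NEGATIVE_BOUND = -0.1

MARKERS = ("cit", "native", "delta", "total")


@dataclass(frozen=True)
class CNIndex:
    subject_id: str
    delta: float
    sign_class: str  # "negative" | "non_negative"
    strong_negative: bool


@dataclass
class PanelResult:
    subject_id: str
    status_cit: Optional[bool]
    status_native: Optional[bool]
    status_delta: Optional[bool]
    total_positive: Optional[bool]
    flags: set[str] = field(default_factory=set)


@dataclass
class RatioSummary:
    group_id: str
    n_tested: int
    pct_positive: float
    ratio_mean_od_positive: Optional[float]

    def render_ratio(self) -> str:
        if self.ratio_mean_od_positive is None:
            return "-"
        return f"{self.ratio_mean_od_positive:.2f}"


def cn_index(
    cit_net: float,
    native_net: float,
    subject_id: str = "",
    cit_subject_id: Optional[str] = None,
    native_subject_id: Optional[str] = None,
) -> CNIndex:
    """Delta between the citrullinated and native net ODs of one subject.

    Sign class splits at zero; delta < −0.1 is additionally annotated as
    strong negative. When the two subject ids are supplied they must
    match (the index is only meaningful within one subject and run).
    """
    if cit_subject_id is not None and native_subject_id is not None:
        if cit_subject_id != native_subject_id:
            raise ValueError(
                f"CN-index inputs from different subjects: "
                f"{cit_subject_id!r} vs {native_subject_id!r}"
            )
        subject_id = cit_subject_id
    if not (math.isfinite(cit_net) and math.isfinite(native_net)):
        raise ValueError("net ODs must be finite")
    delta = cit_net - native_net
    return CNIndex(
        subject_id=subject_id,
        delta=delta,
        sign_class="negative" if delta < 0 else "non_negative",
        strong_negative=delta < STRONG_NEGATIVE_BOUND,
    )


def panel_positivity(
    status_cit: Optional[bool],
    status_native: Optional[bool],
    status_delta: Optional[bool],
    subject_id: str = "",
) -> PanelResult:
    """Combined-panel call: positive when any marker is positive.

    All three statuses must be determined against the same reference
    family; a missing status makes the total missing (flagged) unless a
    present status already decides it positive.
    """
    statuses = (status_cit, status_native, status_delta)
    flags: set[str] = set()
    if any(s is None for s in statuses):
        flags.add("STATUS_MISSING")
        total = True if any(s is True for s in statuses) else None
    else:
        total = bool(status_cit or status_native or status_delta)
    return PanelResult(
        subject_id=subject_id,
        status_cit=status_cit,
        status_native=status_native,
        status_delta=status_delta,
        total_positive=total,
        flags=flags,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _marker_value(record: SubjectRecord, marker: str) -> float:
    if marker == "cit":
        return record.cit_net
    if marker == "native":
        return record.native_net
    if marker == "delta":
        return record.delta
    raise ValueError(f"unknown marker {marker!r}")


def classify_record(
    record: SubjectRecord, cutoffs: Mapping[tuple[str, str], Cutoff], reference: str
) -> PanelResult:
    """All three marker statuses plus the total for one subject, one reference."""
    statuses = {
        m: classify(_marker_value(record, m), cutoffs[(m, reference)])
        for m in ("cit", "native", "delta")
    }
    return panel_positivity(
        statuses["cit"], statuses["native"], statuses["delta"],
        subject_id=record.subject_id,
    )


STRATA = ("all", "seropositive", "seronegative")


def _stratum_members(records: Sequence[SubjectRecord], stratum: str):
    if stratum == "all":
        return list(records)
    if stratum == "seropositive":
        return [r for r in records if r.seropositive is True]
    if stratum == "seronegative":
        return [r for r in records if r.seropositive is False]
    raise ValueError(f"unknown stratum {stratum!r}")


def build_sensitivity_table(
    records: Sequence[SubjectRecord],
    cutoffs: Mapping[tuple[str, str], Cutoff],
    references: tuple[str, str] = ("healthy_controls", "other_diseases_excl_SLE"),
) -> pd.DataFrame:
    """Dual-cutoff percent-positive table per cohort, stratum and marker.

    One row per (cohort, serostatus stratum, marker); the ``cell`` column
    renders "x/y" with the healthy-control cutoff left of the slash and
    the other-disease cutoff right, percentages rounded half-up; the
    full-precision percentages are kept in separate columns. Strata are
    all / seropositive (RF-IgM or CCP-2 positive) / seronegative (both
    negative); subjects with unknown serostatus appear only under "all".
    Empty strata yield rows with n=0 and missing percentages.
    """
    for marker in ("cit", "native", "delta"):
        for ref in references:
            if (marker, ref) not in cutoffs:
                raise KeyError(f"missing cutoff for marker {marker!r}, reference {ref!r}")

    by_cohort: dict[str, list[SubjectRecord]] = {}
    for r in records:
        by_cohort.setdefault(r.cohort, []).append(r)

    rows = []
    for cohort, members in by_cohort.items():
        for stratum in STRATA:
            subset = _stratum_members(members, stratum)
            n = len(subset)
            for marker in MARKERS:
                pcts: list[Optional[float]] = []
                for ref in references:
                    if n == 0:
                        pcts.append(None)
                        continue
                    if marker == "total":
                        calls = [
                            classify_record(r, cutoffs, ref).total_positive
                            for r in subset
                        ]
                    else:
                        calls = [
                            classify(_marker_value(r, marker), cutoffs[(marker, ref)])
                            for r in subset
                        ]
                    pcts.append(100.0 * sum(bool(c) for c in calls) / n)
                cell = "/".join(
                    "-" if p is None else str(_round_half_up(p)) for p in pcts
                )
                rows.append(
                    {
                        "cohort": cohort,
                        "stratum": stratum,
                        "marker": marker,
                        "n": n,
                        "pct_positive_hc": pcts[0],
                        "pct_positive_od": pcts[1],
                        "cell": cell,
                    }
                )
    return pd.DataFrame(rows)


def ratio_mean_od_positive(
    values: Sequence[float], cutoff: Cutoff, group_id: str = ""
) -> RatioSummary:
    """Mean OD of the positive signals divided by the diagnostic cutoff.

    Summarises how far above the cutoff the positive signals sit;
    undefined (rendered "-") when no value exceeds the threshold, which
    is how an all-negative group is reported.
    """
    if cutoff.threshold <= 0:
        raise ValueError("ratio is meaningless for a non-positive threshold")
    vals = np.asarray(values, dtype=float)
    positives = vals[vals > cutoff.threshold]
    ratio = (
        None if positives.size == 0 else float(positives.mean() / cutoff.threshold)
    )
    pct = 100.0 * positives.size / vals.size if vals.size else 0.0
    return RatioSummary(
        group_id=group_id,
        n_tested=int(vals.size),
        pct_positive=pct,
        ratio_mean_od_positive=ratio,
    )
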