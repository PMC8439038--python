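"""Plate-level ELISA processing: raw absorbances to QC-validated net OD values.

The assay reads each well at 450 nm with 620 nm as the reference
wavelength; the per-well optical density is the dual-wavelength
difference A450 − A620. Samples are run in triplicate against the coated
antigen and against a sample background (coating buffer only); every
plate carries a secondary-antibody control (serum dilution buffer) and a
positive control serum. The net value for one subject and one antigen is

    net = (mean(antigen) − mean(secondary)) − (mean(background) − mean(secondary))
        ≡ mean(antigen) − mean(background)

The secondary-control terms cancel algebraically; both corrected
intermediates are retained for logging fidelity. Net values may be
negative and are never clamped — downstream cutoffs operate on the raw
scale.

Plate QC requires the positive control and the secondary-antibody
control to sit within a relative tolerance (default ±10%) of their
lot-assigned expected ODs. In strict mode samples from an invalid plate
are dropped entirely; lenient mode emits them carrying a plate-level
flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Reader noise floor: absorbances slightly below zero are physical
#: (electronic noise), anything lower indicates a corrupt reading.
ABSORBANCE_FLOOR = -0.1


class WellRole(str, Enum):
    ANTIGEN = "antigen"
    BACKGROUND = "background"
    SECONDARY_CONTROL = "secondary_control"
    POSITIVE_CONTROL = "positive_control"


class InvalidReadingError(ValueError):
    """A well produced a non-finite or sub-floor absorbance."""


class PlateSchemaError(ValueError):
    """Plate data violates the structural contract (missing groups etc.)."""


@dataclass(frozen=True)
class RawWell:
    plate_id: str
    well_id: str
    role: WellRole
    sample_id: str  # empty for plate controls
    antigen_id: str  # empty for background/control wells
    a450: float
    a620: float

    def __post_init__(self) -> None:
        for name, v in (("a450", self.a450), ("a620", self.a620)):
            if not math.isfinite(v):
                raise InvalidReadingError(
                    f"non-finite {name} in well {self.plate_id}/{self.well_id}"
                )
            if v < ABSORBANCE_FLOOR:
                raise InvalidReadingError(
                    f"{name}={v} below reader floor in well "
                    f"{self.plate_id}/{self.well_id}"
                )

    @property
    def od(self) -> float:
        return compute_od(self.a450, self.a620, well=f"{self.plate_id}/{self.well_id}")


@dataclass
class ReplicateGroup:
    sample_id: str
    antigen_id: str
    role: WellRole
    ods: list[float]

    def __post_init__(self) -> None:
        if len(self.ods) == 0:
            raise PlateSchemaError(
                f"empty replicate group (sample={self.sample_id!r}, "
                f"antigen={self.antigen_id!r}, role={self.role})"
            )
        if not all(math.isfinite(v) for v in self.ods):
            raise InvalidReadingError(
                f"non-finite OD in replicate group (sample={self.sample_id!r})"
            )

    @property
    def n_replicates(self) -> int:
        return len(self.ods)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ods))


@dataclass
class PlateRun:
    """One physical plate: sample replicate groups plus plate controls."""

    plate_id: str
    groups: list[ReplicateGroup]
    secondary_control: ReplicateGroup
    positive_control: Optional[ReplicateGroup] = None
    expected_positive_control_od: Optional[float] = None
    qc_tolerance: Optional[float] = None  # None -> take from config

    def antigen_groups(self) -> list[ReplicateGroup]:
        return [g for g in self.groups if g.role is WellRole.ANTIGEN]

    def background_for(self, sample_id: str) -> Optional[ReplicateGroup]:
        for g in self.groups:
            if g.role is WellRole.BACKGROUND and g.sample_id == sample_id:
                return g
        return None


@dataclass
class NetValue:
    sample_id: str
    antigen_id: str
    value: float
    replicate_cv_antigen: float
    replicate_cv_background: float
    qc_flags: set[str] = field(default_factory=set)
    plate_id: str = ""


@dataclass
class QCResult:
    plate_id: str
    valid: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class QCConfig:
    """Plate-QC settings; expected control ODs are lot-assigned."""

    expected_positive_control_od: float = 1.0
    expected_secondary_od: float = 0.08
    qc_tolerance: float = 0.10
    cv_warn_threshold: float = 0.20
    strict_qc: bool = True
    allow_missing_positive_control: bool = False


def compute_od(a450: float, a620: float, well: str = "?") -> float:
    """Dual-wavelength optical density: A450 minus the A620 reference."""
    if not (math.isfinite(a450) and math.isfinite(a620)):
        raise InvalidReadingError(f"non-finite absorbance in well {well}")
    return a450 - a620


def summarize_replicates(
    group: ReplicateGroup, cv_warn_threshold: float = 0.20
) -> tuple[float, float, set[str]]:
    """Mean and coefficient of variation of a replicate group.

    CV uses the sample standard deviation (n−1 denominator) divided by
    |mean|. No well is ever excluded; dispersion and replicate-count
    anomalies are surfaced as flags only: ``HIGH_CV`` above the warning
    threshold, ``NOT_TRIPLICATE`` when n differs from 3, and
    ``CV_UNDEFINED`` when the mean is zero.
    """
    flags: set[str] = set()
    ods = np.asarray(group.ods, dtype=float)
    mean = float(ods.mean())
    if ods.size == 1:
        sd = 0.0
    else:
        sd = float(ods.std(ddof=1))
    if mean == 0.0:
        cv = math.nan
        flags.add("CV_UNDEFINED")
    else:
        cv = sd / abs(mean)
        if cv > cv_warn_threshold:
            flags.add("HIGH_CV")
    if ods.size != 3:
        flags.add("NOT_TRIPLICATE")
    return mean, cv, flags


def compute_net_value(
    antigen: ReplicateGroup,
    background: ReplicateGroup,
    secondary: ReplicateGroup,
    cv_warn_threshold: float = 0.20,
) -> NetValue:
    """Control-corrected net OD for one subject and one antigen.

    Both the antigen and the background means are corrected by the
    secondary-antibody control mean before differencing; the correction
    cancels, so the result equals mean(antigen) − mean(background), but
    the corrected intermediates are logged for audit.
    """
    if antigen.sample_id != background.sample_id:
        raise PlateSchemaError(
            f"antigen group (sample {antigen.sample_id!r}) paired with "
            f"background of different sample {background.sample_id!r}"
        )
    mean_ag, cv_ag, flags_ag = summarize_replicates(antigen, cv_warn_threshold)
    mean_bg, cv_bg, flags_bg = summarize_replicates(background, cv_warn_threshold)
    mean_sec, _, _ = summarize_replicates(secondary, cv_warn_threshold)

    corrected_antigen = mean_ag - mean_sec
    corrected_background = mean_bg - mean_sec
    value = corrected_antigen - corrected_background
    logger.debug(
        "net value sample=%s antigen=%s: corrected antigen %.4f, "
        "corrected background %.4f, net %.4f",
        antigen.sample_id, antigen.antigen_id,
        corrected_antigen, corrected_background, value,
    )

    flags = {f"{f}_ANTIGEN" for f in flags_ag} | {f"{f}_BACKGROUND" for f in flags_bg}
    if value < 0:
        flags.add("NEGATIVE_NET")
    return NetValue(
        sample_id=antigen.sample_id,
        antigen_id=antigen.antigen_id,
        value=value,
        replicate_cv_antigen=cv_ag,
        replicate_cv_background=cv_bg,
        qc_flags=flags,
    )


def validate_plate(plate: PlateRun, config: QCConfig) -> QCResult:
    """Check the plate controls against their expected ODs.

    Valid iff the positive-control mean and the secondary-control mean
    each lie within ``qc_tolerance`` (relative) of their expected values.
    A plate without a positive control is invalid with reason
    ``NO_POSITIVE_CONTROL`` unless the config allows control-free plates.
    """
    tolerance = plate.qc_tolerance if plate.qc_tolerance is not None else config.qc_tolerance
    if not (0.0 < tolerance < 1.0):
        raise ValueError(f"qc_tolerance must be in (0, 1), got {tolerance}")
    reasons: list[str] = []

    expected_pos = (
        plate.expected_positive_control_od
        if plate.expected_positive_control_od is not None
        else config.expected_positive_control_od
    )
    if plate.positive_control is None:
        if not config.allow_missing_positive_control:
            reasons.append("NO_POSITIVE_CONTROL")
    else:
        observed = plate.positive_control.mean
        if abs(observed - expected_pos) > tolerance * expected_pos:
            reasons.append(
                f"POSITIVE_CONTROL_OUT_OF_RANGE observed={observed:.4f} "
                f"expected={expected_pos:.4f} tol={tolerance:.2f}"
            )

    observed_sec = plate.secondary_control.mean
    expected_sec = config.expected_secondary_od
    if abs(observed_sec - expected_sec) > tolerance * expected_sec:
        reasons.append(
            f"SECONDARY_CONTROL_OUT_OF_RANGE observed={observed_sec:.4f} "
            f"expected={expected_sec:.4f} tol={tolerance:.2f}"
        )

    for reason in reasons:
        logger.warning("plate %s QC: %s", plate.plate_id, reason)
    return QCResult(plate_id=plate.plate_id, valid=not reasons, reasons=reasons)


def process_plate(
    plate: PlateRun, config: Optional[QCConfig] = None
) -> tuple[QCResult, list[NetValue]]:
    """QC a plate and emit one NetValue per (sample, antigen) pair.

    Every antigen group must have a background group for the same
    sample on the same plate. In strict mode a QC-invalid plate emits
    no net values; lenient mode emits them flagged ``PLATE_QC_INVALID``.
    """
    config = config or QCConfig()
    qc = validate_plate(plate, config)
    if not qc.valid and config.strict_qc:
        logger.warning(
            "plate %s failed QC in strict mode; dropping %d antigen groups",
            plate.plate_id, len(plate.antigen_groups()),
        )
        return qc, []

    nets: list[NetValue] = []
    for group in plate.antigen_groups():
        background = plate.background_for(group.sample_id)
        if background is None:
            raise PlateSchemaError(
                f"plate {plate.plate_id}: no background group for sample "
                f"{group.sample_id!r}"
            )
        net = compute_net_value(
            group, background, plate.secondary_control, config.cv_warn_threshold
        )
        net.plate_id = plate.plate_id
        if not qc.valid:
            net.qc_flags.add("PLATE_QC_INVALID")
        nets.append(net)
    return qc, nets


def process_plates(
    plates: Iterable[PlateRun], config: Optional[QCConfig] = None
) -> tuple[list[QCResult], list[NetValue]]:
    """Run QC + net-value extraction over a collection of plates."""
    config = config or QCConfig()
    all_qc: list[QCResult] = []
    all_nets: list[NetValue] = []
    for plate in plates:
        qc, nets = process_plate(plate, config)
        all_qc.append(qc)
        all_nets.extend(nets)
    return all_qc, all_nets
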