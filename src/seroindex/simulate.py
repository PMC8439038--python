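"""Synthetic serology studies with known ground truth.

No patient sera from the original cohorts are deposited, so every
pipeline stage is exercised on generated data that carries the
statistical structure the analysis assumes:

* per subject, a pair of latent antibody states (citrullinated-reactive,
  native-reactive) drawn with a configurable odds-multiplier dependence
  between them (a Plackett 2×2 coupling with fixed margins);
* net ODs drawn from two-component lognormal mixtures — ODs are
  positive and right-skewed with overlapping bulks and heavy positive
  tails, which the lognormal is the simplest shape to honour;
* shared-epitope allele dosage (0/1/2 copies) acting multiplicatively on
  the citrullinated signal;
* for treated cohorts, a 6-month EULAR response label from a logistic
  model with an explicit negative-delta indicator, so a target like
  "87% responders among negative-index patients" is a settable
  parameter rather than an emergent accident, and a pain VAS linear in
  the native signal;
* plate-level realisation: triplicate antigen and background wells with
  lognormal replicate noise, per-plate secondary-antibody and positive
  controls with lot drift, and dual-wavelength (A450/A620) raw readings
  that round-trip through the net-value arithmetic.

Negative measured net ODs arise naturally when background noise exceeds
antigen noise, exercising the no-clamp rule downstream.

Seeding: one root seed; per-cohort and per-plate substreams are derived
as ``SeedSequence([root, crc32(cohort_name)])`` and
``SeedSequence([root, PLATE_STREAM, plate_index])``, so adding a cohort
does not perturb the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import COHORTS, SubjectRecord

PLATE_STREAM = 0xB1A7E  # namespace tag for plate-noise substreams


@dataclass
class LogNormalComponent:
    """One OD mixture component: log-mean (mu) and log-sd (sigma)."""

    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be > 0")

    def draw(self, rng: np.random.Generator, size=None):
        return np.exp(self.log_mean + self.log_sd * rng.standard_normal(size))

    def tail_probability(self, cutoff: float, scale: float = 1.0) -> float:
        """P(scale · X > cutoff) in closed form."""
        if cutoff <= 0:
            return 1.0
        z = (math.log(cutoff) - math.log(scale) - self.log_mean) / self.log_sd
        return float(norm.sf(z))


@dataclass
class ResponseModel:
    """Logistic model for 6-month EULAR response in a treated cohort."""

    intercept: float
    coef_native: float
    coef_negative_delta: float

    def probability(self, native_net: float, delta: float) -> float:
        eta = (
            self.intercept
            + self.coef_native * native_net
            + self.coef_negative_delta * (1.0 if delta < 0 else 0.0)
        )
        return 1.0 / (1.0 + math.exp(-eta))


@dataclass
class PainModel:
    """Pain VAS (0-100) linear in the native net OD, Gaussian noise."""

    intercept: float
    slope: float
    noise_sd: float


@dataclass
class CohortSpec:
    name: str
    n: int
    prevalence_cit: float
    prevalence_native: float
    joint_dependence: float = 1.0  # odds multiplier linking latent states
    neg_component: LogNormalComponent = field(
        default_factory=lambda: LogNormalComponent(math.log(0.04), 0.6)
    )
    pos_component: LogNormalComponent = field(
        default_factory=lambda: LogNormalComponent(math.log(0.85), 0.55)
    )
    se_distribution: tuple[float, float, float] = (1.0, 0.0, 0.0)
    se_effect_on_cit: float = 1.0  # multiplicative OD shift per copy
    p_rf_given_cit: tuple[float, float] = (0.05, 0.6)  # (latent-neg, latent-pos)
    p_ccp_given_cit: tuple[float, float] = (0.02, 0.7)
    p_lung_change: Optional[tuple[float, float]] = None
    p_progression: Optional[tuple[float, float]] = None
    treatment: Optional[str] = None
    response_model: Optional[ResponseModel] = None
    pain_model: Optional[PainModel] = None

    def __post_init__(self) -> None:
        if self.name not in COHORTS:
            raise ValueError(f"cohort name must be one of {COHORTS}, got {self.name!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for p in (self.prevalence_cit, self.prevalence_native):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        if self.joint_dependence <= 0:
            raise ValueError("joint_dependence must be > 0")
        if abs(sum(self.se_distribution) - 1.0) > 1e-9 or any(
            p < 0 for p in self.se_distribution
        ):
            raise ValueError("se_distribution must be a probability vector over {0,1,2}")


@dataclass
class PlateNoise:
    replicate_cv: float = 0.08
    background_mean_od: float = 0.12
    secondary_mean_od: float = 0.08
    positive_control_od: float = 1.0
    control_drift_sd: float = 0.02  # relative lot drift per plate
    a620_mean: float = 0.04

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be >= 0")


@dataclass
class StudySpec:
    cohorts: list[CohortSpec]
    plate_noise: PlateNoise = field(default_factory=PlateNoise)
    samples_per_plate: int = 30
    seed: int = 0
    include_failing_plate: bool = False

    def __post_init__(self) -> None:
        names = [c.name for c in self.cohorts]
        if len(names) != len(set(names)):
            raise ValueError("duplicate cohort names")
        if self.samples_per_plate < 1:
            raise ValueError("samples_per_plate must be >= 1")


@dataclass
class SyntheticStudy:
    wells: pd.DataFrame  # one row per well: plate_id, well_id, role, sample_id, antigen_id, a450, a620
    subject_records: list[SubjectRecord]
    ground_truth: pd.DataFrame
    spec: StudySpec


def joint_latent_table(
    p_cit: float, p_native: float, odds_multiplier: float
) -> np.ndarray:
    """2×2 joint distribution of the latent states with fixed margins.

    The odds multiplier theta is the cross-product ratio
    P11·P00 / (P10·P01); theta = 1 gives independence. The joint cell
    P11 solves a quadratic (Plackett coupling) and is clipped to the
    Fréchet bounds for numerical safety.
    """
    p1, p2, theta = p_cit, p_native, odds_multiplier
    if abs(theta - 1.0) < 1e-12:
        p11 = p1 * p2
    else:
        a = theta - 1.0
        b = -(1.0 + a * (p1 + p2))
        c = theta * p1 * p2
        disc = b * b - 4.0 * a * c
        p11 = (-b - math.sqrt(max(disc, 0.0))) / (2.0 * a)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    p11 = min(max(p11, lo), hi)
    table = np.array(
        [
            [1.0 - p1 - p2 + p11, p2 - p11],  # cit−: native−, native+
            [p1 - p11, p11],  # cit+: native−, native+
        ]
    )
    return table


def cohort_rng(root_seed: int, cohort_name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([root_seed, zlib.crc32(cohort_name.encode())])
    )


def generate_subject(
    spec: CohortSpec, rng: np.random.Generator, subject_id: str = "S0"
) -> dict:
    """One subject: latent states, true net ODs, covariates and labels."""
    table = joint_latent_table(
        spec.prevalence_cit, spec.prevalence_native, spec.joint_dependence
    )
    cell = rng.choice(4, p=table.ravel())
    cit_pos, native_pos = bool(cell // 2), bool(cell % 2)

    cit = float((spec.pos_component if cit_pos else spec.neg_component).draw(rng))
    native = float((spec.pos_component if native_pos else spec.neg_component).draw(rng))

    se = int(rng.choice(3, p=spec.se_distribution))
    cit *= spec.se_effect_on_cit**se

    def bernoulli(p: float) -> bool:
        return bool(rng.random() < p)

    rf = bernoulli(spec.p_rf_given_cit[int(cit_pos)])
    ccp = bernoulli(spec.p_ccp_given_cit[int(cit_pos)])
    lung = (
        bernoulli(spec.p_lung_change[int(cit_pos)])
        if spec.p_lung_change is not None
        else None
    )
    progression = (
        bernoulli(spec.p_progression[int(cit_pos)])
        if spec.p_progression is not None
        else None
    )

    responder = None
    pain = None
    delta = cit - native
    if spec.treatment is not None and spec.response_model is not None:
        responder = bernoulli(spec.response_model.probability(native, delta))
    if spec.pain_model is not None:
        pm = spec.pain_model
        pain = float(
            np.clip(pm.intercept + pm.slope * native + pm.noise_sd * rng.standard_normal(), 0.0, 100.0)
        )

    return {
        "subject_id": subject_id,
        "cohort": spec.name,
        "cit_net_true": cit,
        "native_net_true": native,
        "latent_cit_positive": cit_pos,
        "latent_native_positive": native_pos,
        "se_copies": se,
        "rf_igm": rf,
        "ccp2": ccp,
        "lung_parenchymal_change": lung,
        "arthritis_progression": progression,
        "treatment": spec.treatment,
        "eular_responder_6m": responder,
        "pain_vas_6m": pain,
    }


def generate_cohort(spec: CohortSpec, root_seed: int) -> list[dict]:
    rng = cohort_rng(root_seed, spec.name)
    return [
        generate_subject(spec, rng, subject_id=f"{spec.name}_{i:04d}")
        for i in range(spec.n)
    ]


def _lognormal_wells(
    mean: float, cv: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n replicate ODs with the given mean and CV (exact mean when CV=0)."""
    if cv == 0.0:
        return np.full(n, mean)
    mean = max(mean, 1e-6)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return np.exp(mu + math.sqrt(sigma2) * rng.standard_normal(n))


def generate_plate_readings(
    true_net: float, noise: PlateNoise, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw (a450, a620) triplicates for one subject and one antigen.

    Background wells are lognormal around the background mean; antigen
    wells lognormal around (true net + background mean) at the same
    replicate CV, so the net-value arithmetic recovers the true net in
    expectation (exactly, when CV = 0). A620 is a small reference-channel
    constant plus proportional noise so the dual-wavelength OD
    round-trips.
    """
    if noise.replicate_cv < 0:
        raise ValueError("replicate CV must be >= 0")
    cv = noise.replicate_cv
    bg_ods = _lognormal_wells(noise.background_mean_od, cv, 3, rng)
    ag_ods = _lognormal_wells(true_net + noise.background_mean_od, cv, 3, rng)

    def raw(ods: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if cv == 0.0:
            a620 = np.full(ods.size, noise.a620_mean)
        else:
            a620 = noise.a620_mean + cv * noise.a620_mean * rng.standard_normal(ods.size)
        return ods + a620, a620

    ag_a450, ag_a620 = raw(ag_ods)
    bg_a450, bg_a620 = raw(bg_ods)
    return ag_a450, ag_a620, bg_a450, bg_a620


def _control_wells(
    mean: float, drift_factor: float, cv: float, a620_mean: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    ods = _lognormal_wells(mean * drift_factor, cv, 3, rng)
    if cv == 0.0:
        a620 = np.full(3, a620_mean)
    else:
        a620 = a620_mean + cv * a620_mean * rng.standard_normal(3)
    return ods + a620, a620


def generate_study(spec: StudySpec) -> SyntheticStudy:
    """Full synthetic study: subjects, plates, measured nets, ground truth.

    Subjects are chunked onto plates (both antigens for a subject on the
    same plate, per-subject shared background wells, plus per-plate
    secondary and positive controls). Measured net ODs in the subject
    records are recomputed from the generated wells through the plate
    arithmetic, so they carry the replicate noise. With
    ``include_failing_plate`` an extra plate whose positive control is
    25% off its expected OD is appended, carrying two extra QC-test
    samples that appear on no cohort table.
    """
    from .elisa import process_plate, QCConfig
    from .io import plates_from_frame

    truth_rows: list[dict] = []
    for cohort in spec.cohorts:
        truth_rows.extend(generate_cohort(cohort, spec.seed))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "subject_id", "cohort", "cit_net_true", "native_net_true",
            "latent_cit_positive", "latent_native_positive", "se_copies",
            "rf_igm", "ccp2", "lung_parenchymal_change",
            "arthritis_progression", "treatment", "eular_responder_6m",
            "pain_vas_6m",
        ],
    )

    noise = spec.plate_noise
    well_rows: list[dict] = []

    def add_well(plate_id, idx, role, sample_id, antigen_id, a450, a620):
        well_rows.append(
            {
                "plate_id": plate_id,
                "well_id": f"W{idx:03d}",
                "role": role,
                "sample_id": sample_id,
                "antigen_id": antigen_id,
                "a450": round(float(a450), 6),
                "a620": round(float(a620), 6),
            }
        )

    def build_plate(plate_id: str, chunk: list[dict], rng, pos_control_factor=1.0):
        idx = 0
        drift = 1.0 + noise.control_drift_sd * float(rng.standard_normal())
        sec_a450, sec_a620 = _control_wells(
            noise.secondary_mean_od, drift, noise.replicate_cv, noise.a620_mean, rng
        )
        pos_a450, pos_a620 = _control_wells(
            noise.positive_control_od, drift * pos_control_factor,
            noise.replicate_cv, noise.a620_mean, rng,
        )
        for a450, a620 in zip(sec_a450, sec_a620):
            idx += 1
            add_well(plate_id, idx, "secondary_control", "", "", a450, a620)
        for a450, a620 in zip(pos_a450, pos_a620):
            idx += 1
            add_well(plate_id, idx, "positive_control", "", "", a450, a620)
        for subj in chunk:
            for antigen_id, key in (("cit-DL", "cit_net_true"), ("DL", "native_net_true")):
                ag_a450, ag_a620, _, _ = generate_plate_readings(subj[key], noise, rng)
                for a450, a620 in zip(ag_a450, ag_a620):
                    idx += 1
                    add_well(plate_id, idx, "antigen", subj["subject_id"], antigen_id, a450, a620)
            bg_ods = _lognormal_wells(noise.background_mean_od, noise.replicate_cv, 3, rng)
            if noise.replicate_cv == 0.0:
                bg_a620 = np.full(3, noise.a620_mean)
            else:
                bg_a620 = noise.a620_mean + noise.replicate_cv * noise.a620_mean * rng.standard_normal(3)
            for od, a620 in zip(bg_ods, bg_a620):
                idx += 1
                add_well(plate_id, idx, "background", subj["subject_id"], "", od + a620, a620)

    chunks = [
        truth_rows[i : i + spec.samples_per_plate]
        for i in range(0, len(truth_rows), spec.samples_per_plate)
    ]
    for plate_index, chunk in enumerate(chunks):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, PLATE_STREAM, plate_index])
        )
        build_plate(f"P{plate_index + 1:03d}", chunk, rng)

    if spec.include_failing_plate:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, PLATE_STREAM, len(chunks)])
        )
        qc_subjects = [
            {"subject_id": f"QCFAIL_{i}", "cit_net_true": 0.5, "native_net_true": 0.2}
            for i in range(2)
        ]
        build_plate(f"P{len(chunks) + 1:03d}", qc_subjects, rng, pos_control_factor=1.25)

    wells = pd.DataFrame(
        well_rows,
        columns=["plate_id", "well_id", "role", "sample_id", "antigen_id", "a450", "a620"],
    )

    # Measured nets: run the generated wells through the plate arithmetic.
    qc_config = QCConfig(
        expected_positive_control_od=noise.positive_control_od,
        expected_secondary_od=noise.secondary_mean_od,
        strict_qc=False,
    )
    nets: dict[tuple[str, str], float] = {}
    for plate in plates_from_frame(wells):
        _, plate_nets = process_plate(plate, qc_config)
        for nv in plate_nets:
            nets[(nv.sample_id, nv.antigen_id)] = nv.value

    records: list[SubjectRecord] = []
    for subj in truth_rows:
        sid = subj["subject_id"]
        records.append(
            SubjectRecord(
                subject_id=sid,
                cohort=subj["cohort"],
                cit_net=nets[(sid, "cit-DL")],
                native_net=nets[(sid, "DL")],
                rf_igm=subj["rf_igm"],
                ccp2=subj["ccp2"],
                se_copies=subj["se_copies"],
                lung_parenchymal_change=subj["lung_parenchymal_change"],
                arthritis_progression=subj["arthritis_progression"],
                treatment=subj["treatment"],
                eular_responder_6m=subj["eular_responder_6m"],
                pain_vas_6m=subj["pain_vas_6m"],
            )
        )

    return SyntheticStudy(
        wells=wells, subject_records=records, ground_truth=truth, spec=spec
    )


def _spec_echo(spec: StudySpec) -> dict:
    echo = asdict(spec)
    return echo


def write_study(study: SyntheticStudy, out_dir) -> dict[str, object]:
    """Write plates/*.csv, cohort.tsv, covariates.tsv, truth.tsv and a spec echo.

    ``cohort.tsv`` carries the measured nets; ``covariates.tsv`` is the
    same table without the net columns, for pipelines that recompute nets
    from the plates. Fixed spec + seed ⇒ byte-identical files.
    """
    import yaml
    from pathlib import Path

    from .io import records_to_frame, write_cohort_tsv

    out = Path(out_dir)
    (out / "plates").mkdir(parents=True, exist_ok=True)
    plate_paths = []
    for plate_id, pdf in study.wells.groupby("plate_id", sort=True):
        path = out / "plates" / f"{plate_id}.csv"
        pdf.to_csv(path, index=False)
        plate_paths.append(path)

    cohort_path = out / "cohort.tsv"
    write_cohort_tsv(study.subject_records, cohort_path)

    cov = records_to_frame(study.subject_records).drop(columns=["cit_net", "native_net"])
    cov_path = out / "covariates.tsv"
    cov.to_csv(cov_path, sep="\t", index=False)

    truth_path = out / "truth.tsv"
    study.ground_truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")

    spec_path = out / "study_spec.yaml"
    spec_path.write_text(yaml.safe_dump(_spec_echo(study.spec), sort_keys=True))

    return {
        "plates": plate_paths,
        "cohort": cohort_path,
        "covariates": cov_path,
        "truth": truth_path,
        "spec": spec_path,
    }


def demo_spec(seed: int = 0, scale: float = 1.0, include_failing_plate: bool = False) -> StudySpec:
    """Seven cohorts shaped like the study's panels.

    Cohort sizes default to the published ones (Risk-RA 71, LURA 106,
    EIRA 404, established RA "predict" 127, SLE 89, other diseases 127,
    healthy controls 86); ``scale`` shrinks them proportionally (minimum
    12 per cohort) for quick runs. Mixture components and prevalences are
    illustrative — chosen to reproduce the qualitative layout: strong
    citrullinated reactivity in RA cohorts, native-dominated (negative
    delta) reactivity in SLE, near-silence in controls, a shared-epitope
    dose effect on the citrullinated signal in EIRA, and an MTX response
    model in EIRA whose responder probability given a negative delta is
    0.87.
    """

    def n_of(n: int) -> int:
        return max(12, int(round(n * scale)))

    neg = LogNormalComponent(math.log(0.04), 0.6)
    pos = LogNormalComponent(math.log(0.85), 0.55)
    sle_native_pos = LogNormalComponent(math.log(1.1), 0.5)

    eira_response = ResponseModel(intercept=0.2, coef_native=1.0, coef_negative_delta=1.7)
    # intercept 0.2 + indicator 1.7 => P(responder | negative delta, native≈0) ≈ 0.87

    cohorts = [
        CohortSpec(
            name="risk_ra", n=n_of(71), prevalence_cit=0.70, prevalence_native=0.13,
            joint_dependence=3.0, neg_component=neg, pos_component=pos,
            se_distribution=(0.35, 0.45, 0.20), se_effect_on_cit=1.25,
            p_ccp_given_cit=(0.5, 0.95),  # risk cohort is CCP-enriched by design
            p_progression=(0.25, 0.6),
        ),
        CohortSpec(
            name="lura", n=n_of(106), prevalence_cit=0.62, prevalence_native=0.10,
            joint_dependence=3.0, neg_component=neg, pos_component=pos,
            se_distribution=(0.35, 0.45, 0.20), se_effect_on_cit=1.25,
            p_lung_change=(0.15, 0.45),
        ),
        CohortSpec(
            name="eira", n=n_of(404), prevalence_cit=0.78, prevalence_native=0.20,
            joint_dependence=3.0, neg_component=neg, pos_component=pos,
            se_distribution=(0.30, 0.50, 0.20), se_effect_on_cit=1.30,
            treatment="mtx", response_model=eira_response,
            pain_model=PainModel(intercept=45.0, slope=-15.0, noise_sd=18.0),
        ),
        CohortSpec(
            name="predict", n=n_of(127), prevalence_cit=0.95, prevalence_native=0.06,
            joint_dependence=2.0, neg_component=neg, pos_component=pos,
            se_distribution=(0.30, 0.50, 0.20), se_effect_on_cit=1.25,
            treatment="etanercept",
            response_model=ResponseModel(intercept=0.5, coef_native=1.2, coef_negative_delta=0.5),
        ),
        CohortSpec(
            name="sle", n=n_of(89), prevalence_cit=0.45, prevalence_native=0.40,
            joint_dependence=6.0, neg_component=neg, pos_component=sle_native_pos,
            p_rf_given_cit=(0.1, 0.15), p_ccp_given_cit=(0.02, 0.02),
        ),
        CohortSpec(
            name="other_disease", n=n_of(127), prevalence_cit=0.04,
            prevalence_native=0.03, neg_component=neg, pos_component=pos,
            p_rf_given_cit=(0.08, 0.2), p_ccp_given_cit=(0.02, 0.05),
        ),
        CohortSpec(
            name="healthy", n=n_of(86), prevalence_cit=0.02, prevalence_native=0.02,
            neg_component=neg, pos_component=pos,
            p_rf_given_cit=(0.03, 0.05), p_ccp_given_cit=(0.01, 0.02),
        ),
    ]
    return StudySpec(
        cohorts=cohorts, seed=seed, include_failing_plate=include_failing_plate
    )
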