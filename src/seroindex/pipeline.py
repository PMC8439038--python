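"""End-to-end pipeline: plates → QC → net values → cutoffs → index → tables.

Each stage writes a plain TSV that the next stage consumes, so every
number in the final report is recomputable from the intermediates. The
pipeline is a pure function of (input files, config, seed): result
tables are byte-identical across reruns; wall-clock information is
confined to the manifest.
"""

from __future__ import annotations

import glob as _glob
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import cutoffs as co
from . import panel as pn
from . import stats as st
from .elisa import process_plates
from .io import (
    PipelineConfig,
    read_cohort_tsv,
    read_plate_csv,
    records_to_frame,
    write_manifest,
)
from .records import SubjectRecord

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _resolve_plates(patterns: Sequence[str]) -> list[str]:
    paths: list[str] = []
    for pattern in patterns:
        matched = sorted(_glob.glob(pattern))
        paths.extend(matched if matched else [pattern])
    return paths


def compute_reference_cutoffs(
    records: Sequence[SubjectRecord], config: PipelineConfig
) -> dict[tuple[str, str], co.Cutoff]:
    """Specificity-anchored cutoffs for all three markers and both references."""
    refs = {
        "healthy_controls": [r for r in records if r.cohort == config.healthy_cohort],
        "other_diseases_excl_SLE": [
            r for r in records if r.cohort == config.other_disease_cohort
        ],
    }
    getters = {"cit": lambda r: r.cit_net, "native": lambda r: r.native_net,
               "delta": lambda r: r.delta}
    out: dict[tuple[str, str], co.Cutoff] = {}
    for ref_label, members in refs.items():
        reference_values = {m: [g(r) for r in members] for m, g in getters.items()}
        for marker, values in reference_values.items():
            ref = co.ReferenceSet(ref_label, values)
            out[(marker, ref_label)] = co.cutoff_at_specificity(
                ref, config.target_specificity, marker_id=marker
            )
    return out


def subject_index_frame(
    records: Sequence[SubjectRecord], cutoff_map: dict[tuple[str, str], co.Cutoff]
) -> pd.DataFrame:
    """Per-subject classification table under both reference cutoff families."""
    rows = []
    for r in records:
        idx = pn.cn_index(r.cit_net, r.native_net, subject_id=r.subject_id)
        row = {
            "subject_id": r.subject_id,
            "cohort": r.cohort,
            "cit_net": r.cit_net,
            "native_net": r.native_net,
            "delta": idx.delta,
            "sign_class": idx.sign_class,
            "strong_negative": idx.strong_negative,
        }
        for ref_label, suffix in (
            ("healthy_controls", "hc"),
            ("other_diseases_excl_SLE", "od"),
        ):
            result = pn.classify_record(r, cutoff_map, ref_label)
            row[f"status_cit_{suffix}"] = result.status_cit
            row[f"status_native_{suffix}"] = result.status_native
            row[f"status_delta_{suffix}"] = result.status_delta
            row[f"total_{suffix}"] = result.total_positive
        rows.append(row)
    return pd.DataFrame(rows)


def cutoffs_frame(cutoff_map: dict[tuple[str, str], co.Cutoff]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": c.marker_id,
                "reference": c.reference_label,
                "reference_n": c.reference_n,
                "target_specificity": c.target_specificity,
                "threshold": c.threshold,
                "achieved_specificity": c.achieved_specificity,
            }
            for c in cutoff_map.values()
        ]
    )


def contrasts_frame(records: Sequence[SubjectRecord], bh_adjust: bool) -> pd.DataFrame:
    rows = []
    for cohort, grouping in (
        ("risk_ra", "progression"),
        ("lura", "lung_pc"),
        ("eira", "se_copies"),
    ):
        members = [r for r in records if r.cohort == cohort]
        if not members:
            continue
        for comp in st.group_contrast_suite(members, grouping, adjust=bh_adjust):
            rows.append(
                {
                    "cohort": cohort,
                    "grouping": grouping,
                    "marker": comp.marker,
                    "group_a": comp.group_a_label,
                    "group_b": comp.group_b_label,
                    "n_a": comp.n_a,
                    "n_b": comp.n_b,
                    "median_a": comp.median_a,
                    "median_b": comp.median_b,
                    "u_statistic": comp.u_statistic,
                    "p_value": comp.p_value,
                    "method": comp.method,
                    "p_adjusted": comp.p_adjusted,
                }
            )
    return pd.DataFrame(rows)


def response_frame(records: Sequence[SubjectRecord], config: PipelineConfig) -> pd.DataFrame:
    """Response ROC per serostatus stratum plus CN-sign responder rates."""
    treated = [
        r
        for r in records
        if r.treatment == config.response_treatment and r.eular_responder_6m is not None
    ]
    rows = []
    strata = {
        "all": treated,
        "seropositive": [r for r in treated if r.seropositive is True],
        "seronegative": [r for r in treated if r.seropositive is False],
    }
    for stratum, members in strata.items():
        labels = [bool(r.eular_responder_6m) for r in members]
        if len(set(labels)) < 2:
            logger.warning("response stratum %s has a single class; skipped", stratum)
            continue
        values = [r.native_net for r in members]
        analyses = [
            st.response_roc(
                values, labels,
                target_specificity=config.response_target_specificity,
                treatment=config.response_treatment, stratum=stratum,
            )
        ]
        if config.response_fixed_threshold is not None:
            analyses.append(
                st.response_roc(
                    values, labels,
                    fixed_threshold=config.response_fixed_threshold,
                    treatment=config.response_treatment, stratum=stratum,
                )
            )
        for a in analyses:
            rows.append(
                {
                    "analysis": "response_roc",
                    "treatment": a.treatment,
                    "stratum": a.stratum,
                    "n": a.n,
                    "n_responders": a.n_responders,
                    "threshold_source": a.threshold_source,
                    "cutoff_used": a.cutoff_used,
                    "sensitivity_pct": a.sensitivity_pct,
                    "specificity_pct": a.specificity_pct,
                    "responder_rate_pct": a.responder_rate_pct,
                }
            )
    for rate in st.responder_rate_by_cn_sign(treated):
        rows.append(
            {
                "analysis": "cn_sign_rate",
                "treatment": config.response_treatment,
                "stratum": rate.stratum,
                "n": rate.n,
                "n_responders": rate.n_responders,
                "threshold_source": "",
                "cutoff_used": None,
                "sensitivity_pct": None,
                "specificity_pct": None,
                "responder_rate_pct": rate.rate_pct,
                "ci_low_pct": rate.ci_low_pct,
                "ci_high_pct": rate.ci_high_pct,
            }
        )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute qc → net → cutoff → index → table → compare/response.

    Returns a mapping from artifact name to written path; aborts with a
    stage-tagged PipelineError on the first failing stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    outputs: dict[str, Path] = {}

    # --- qc + net ---------------------------------------------------------
    try:
        plate_paths = _resolve_plates(config.plates)
        plates = [p for path in plate_paths for p in read_plate_csv(path)]
        qc_results, nets = process_plates(plates, config.qc)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineError("qc/net", str(exc)) from exc
    for qc in qc_results:
        if not qc.valid:
            warnings_log.append(f"plate {qc.plate_id} failed QC: {'; '.join(qc.reasons)}")
    qc_df = pd.DataFrame(
        [{"plate_id": q.plate_id, "valid": q.valid, "reasons": "; ".join(q.reasons)}
         for q in qc_results]
    )
    net_df = pd.DataFrame(
        [
            {
                "plate_id": n.plate_id, "sample_id": n.sample_id,
                "antigen_id": n.antigen_id, "net_od": n.value,
                "cv_antigen": n.replicate_cv_antigen,
                "cv_background": n.replicate_cv_background,
                "flags": ";".join(sorted(n.qc_flags)),
            }
            for n in nets
        ]
    )
    outputs["qc_report"] = out_dir / "qc_report.tsv"
    outputs["net_values"] = out_dir / "net_values.tsv"
    _write(qc_df, outputs["qc_report"])
    _write(net_df, outputs["net_values"])

    # --- join with covariates --------------------------------------------
    try:
        covariates = read_cohort_tsv(config.covariates_tsv, require_nets=False)
        net_map = {(n.sample_id, n.antigen_id): n.value for n in nets}
        records: list[SubjectRecord] = []
        for r in covariates:
            key_cit = (r.subject_id, config.cit_antigen_id)
            key_nat = (r.subject_id, config.native_antigen_id)
            if key_cit not in net_map or key_nat not in net_map:
                warnings_log.append(
                    f"subject {r.subject_id}: net OD missing (QC drop or absent wells)"
                )
                continue
            r.cit_net = net_map[key_cit]
            r.native_net = net_map[key_nat]
            records.append(r)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("join", str(exc)) from exc
    outputs["cohort"] = out_dir / "cohort.tsv"
    records_to_frame(records).to_csv(outputs["cohort"], sep="\t", index=False)

    # --- cutoffs -----------------------------------------------------------
    try:
        cutoff_map = compute_reference_cutoffs(records, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cutoff", str(exc)) from exc
    outputs["cutoffs"] = out_dir / "cutoffs.tsv"
    _write(cutoffs_frame(cutoff_map), outputs["cutoffs"])

    # --- index + tables ----------------------------------------------------
    try:
        index_df = subject_index_frame(records, cutoff_map)
        sens_df = pn.build_sensitivity_table(records, cutoff_map)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("index/table", str(exc)) from exc
    outputs["subject_index"] = out_dir / "subject_index.tsv"
    outputs["sensitivity_table"] = out_dir / "sensitivity_table.tsv"
    _write(index_df, outputs["subject_index"])
    _write(sens_df, outputs["sensitivity_table"])

    # --- comparisons + response -------------------------------------------
    try:
        contrasts = contrasts_frame(records, config.bh_adjust)
        response = response_frame(records, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("compare/response", str(exc)) from exc
    outputs["contrasts"] = out_dir / "contrasts.tsv"
    outputs["response"] = out_dir / "response.tsv"
    _write(contrasts, outputs["contrasts"])
    _write(response, outputs["response"])

    inputs = list(plate_paths) + ([config.covariates_tsv] if config.covariates_tsv else [])
    outputs["manifest"] = write_manifest(out_dir, config, inputs, warnings_log)
    return outputs
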