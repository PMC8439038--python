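"""File formats, configuration and the run manifest.

Plate CSV (one row per well): columns ``plate_id, well_id, role,
sample_id, antigen_id, a450, a620``; header required, UTF-8, decimal
point. Cohort TSV (one row per subject): net ODs per marker plus
clinical covariates, empty cells meaning missing (never zero).
Intermediate pipeline artifacts are plain TSV/JSON so every stage is
independently inspectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .elisa import PlateRun, QCConfig, ReplicateGroup, WellRole
from .records import COHORTS, TREATMENTS, SubjectRecord

PLATE_COLUMNS = ["plate_id", "well_id", "role", "sample_id", "antigen_id", "a450", "a620"]

COHORT_COLUMNS = [
    "subject_id", "cohort", "cit_net", "native_net", "rf_igm", "ccp2",
    "se_copies", "lung_parenchymal_change", "arthritis_progression",
    "treatment", "eular_responder_6m", "pain_vas_6m",
]

_ROLES = {r.value for r in WellRole}


class SchemaError(ValueError):
    """Input file violates its documented schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")


def plates_from_frame(df: pd.DataFrame) -> list[PlateRun]:
    """Group a well table into PlateRuns.

    Wells are grouped into replicate groups by (sample_id, antigen_id,
    role) within each plate; each plate must carry exactly one
    secondary-control group.
    """
    plates: list[PlateRun] = []
    for plate_id, pdf in df.groupby("plate_id", sort=True):
        groups: list[ReplicateGroup] = []
        secondary: Optional[ReplicateGroup] = None
        positive: Optional[ReplicateGroup] = None
        keys = pdf[["sample_id", "antigen_id", "role"]].drop_duplicates()
        for _, key in keys.iterrows():
            sel = pdf[
                (pdf["sample_id"] == key.sample_id)
                & (pdf["antigen_id"] == key.antigen_id)
                & (pdf["role"] == key.role)
            ]
            ods = (sel["a450"] - sel["a620"]).tolist()
            group = ReplicateGroup(
                sample_id=key.sample_id,
                antigen_id=key.antigen_id,
                role=WellRole(key.role),
                ods=ods,
            )
            if group.role is WellRole.SECONDARY_CONTROL:
                if secondary is not None:
                    raise SchemaError(
                        f"plate {plate_id}: more than one secondary-control group"
                    )
                secondary = group
            elif group.role is WellRole.POSITIVE_CONTROL:
                positive = group
            else:
                groups.append(group)
        if secondary is None:
            raise SchemaError(f"plate {plate_id}: no secondary-control group")
        plates.append(
            PlateRun(
                plate_id=str(plate_id),
                groups=groups,
                secondary_control=secondary,
                positive_control=positive,
            )
        )
    return plates


def plates_to_frame(plates: Sequence[PlateRun], a620: float = 0.0) -> pd.DataFrame:
    """Serialize PlateRuns back to a well table (ODs stored as a450, a620 fixed)."""
    rows = []
    for plate in plates:
        idx = 0
        all_groups = list(plate.groups) + [plate.secondary_control]
        if plate.positive_control is not None:
            all_groups.append(plate.positive_control)
        for g in all_groups:
            for od in g.ods:
                idx += 1
                rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "well_id": f"W{idx:03d}",
                        "role": g.role.value,
                        "sample_id": g.sample_id,
                        "antigen_id": g.antigen_id,
                        "a450": od + a620,
                        "a620": a620,
                    }
                )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def read_plate_csv(path: Union[str, Path]) -> list[PlateRun]:
    """Read a per-well plate CSV into PlateRuns, validating the schema."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"plate_id": str, "well_id": str, "role": str,
                                  "sample_id": str, "antigen_id": str},
                     keep_default_na=False)
    _check_columns(df, PLATE_COLUMNS, path)
    for col in ("a450", "a620"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            line = int(bad.index[0]) + 2  # header is line 1
            raise SchemaError(f"{path}:{line}: non-numeric {col}")
        df[col] = pd.to_numeric(df[col])
    bad_roles = df[~df["role"].isin(_ROLES)]
    if len(bad_roles):
        line = int(bad_roles.index[0]) + 2
        raise SchemaError(
            f"{path}:{line}: unknown role {bad_roles.iloc[0]['role']!r}; "
            f"allowed: {sorted(_ROLES)}"
        )
    dupes = df.duplicated(subset=["plate_id", "well_id"])
    if dupes.any():
        line = int(df.index[dupes][0]) + 2
        raise SchemaError(f"{path}:{line}: duplicate (plate_id, well_id)")
    return plates_from_frame(df)


def write_wells_csv(wells: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    wells.to_csv(path, index=False)


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_bool(raw: str, column: str, line: int, path) -> Optional[bool]:
    if raw == "":
        return None
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise SchemaError(f"{path}:{line}: {column}={raw!r} is not a boolean") from None


def read_cohort_tsv(
    path: Union[str, Path], require_nets: bool = True
) -> list[SubjectRecord]:
    """Read the wide cohort table; empty cells are missing, never zero.

    With ``require_nets=False`` the net-OD columns may be absent
    (covariates-only tables for pipelines that recompute nets from
    plates); the records then carry placeholder zeros until joined.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["subject_id", "cohort"]
    if require_nets:
        required += ["cit_net", "native_net"]
    _check_columns(df, required, path)
    if not require_nets:
        for col in ("cit_net", "native_net"):
            if col not in df.columns:
                df[col] = "0.0"
    records: list[SubjectRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        cohort = row["cohort"]
        if cohort not in COHORTS:
            raise SchemaError(
                f"{path}:{line}: unknown cohort {cohort!r}; "
                f"allowed: {', '.join(COHORTS)}"
            )
        se_raw = row.get("se_copies", "")
        if se_raw == "":
            se = None
        else:
            try:
                se = int(se_raw)
            except ValueError:
                raise SchemaError(f"{path}:{line}: se_copies={se_raw!r} not an integer") from None
            if se not in (0, 1, 2):
                raise SchemaError(f"{path}:{line}: se_copies must be 0, 1 or 2; got {se}")
        treatment = row.get("treatment", "") or None
        if treatment is not None and treatment not in TREATMENTS:
            raise SchemaError(
                f"{path}:{line}: unknown treatment {treatment!r}; "
                f"allowed: {', '.join(TREATMENTS)}"
            )
        pain_raw = row.get("pain_vas_6m", "")
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                cohort=cohort,
                cit_net=float(row["cit_net"]),
                native_net=float(row["native_net"]),
                rf_igm=_parse_bool(row.get("rf_igm", ""), "rf_igm", line, path),
                ccp2=_parse_bool(row.get("ccp2", ""), "ccp2", line, path),
                se_copies=se,
                lung_parenchymal_change=_parse_bool(
                    row.get("lung_parenchymal_change", ""), "lung_parenchymal_change", line, path
                ),
                arthritis_progression=_parse_bool(
                    row.get("arthritis_progression", ""), "arthritis_progression", line, path
                ),
                treatment=treatment,
                eular_responder_6m=_parse_bool(
                    row.get("eular_responder_6m", ""), "eular_responder_6m", line, path
                ),
                pain_vas_6m=float(pain_raw) if pain_raw != "" else None,
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {col: _fmt(getattr(r, col)) for col in COHORT_COLUMNS} for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_tsv(records: Sequence[SubjectRecord], path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs; loadable from YAML/JSON."""

    plates: list[str] = field(default_factory=list)  # plate CSV paths or glob
    covariates_tsv: Optional[str] = None
    out_dir: str = "results"
    qc: QCConfig = field(default_factory=QCConfig)
    target_specificity: float = 0.98
    healthy_cohort: str = "healthy"
    other_disease_cohort: str = "other_disease"
    cit_antigen_id: str = "cit-DL"
    native_antigen_id: str = "DL"
    response_treatment: str = "mtx"
    response_target_specificity: float = 0.90
    response_fixed_threshold: Optional[float] = None
    bh_adjust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_specificity < 1.0):
            raise ValueError("target_specificity must be in (0, 1)")


def load_config(path: Union[str, Path]) -> PipelineConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    qc = QCConfig(**raw.pop("qc", {}))
    return PipelineConfig(qc=qc, **raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def file_checksum(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: Union[str, Path],
    config: PipelineConfig,
    inputs: Sequence[Union[str, Path]],
    warnings: Sequence[str],
) -> Path:
    """Run manifest: tool version, config hash, input checksums, warnings.

    Timestamps live only here, so rerunning with identical inputs and
    config leaves every result table byte-identical.
    """
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "config_hash": config_hash(config),
        "inputs": {str(p): file_checksum(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "warnings": list(warnings),
    }
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return out
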