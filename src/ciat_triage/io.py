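"""Plain-text file formats and run configuration.

Every intermediate artifact is CSV or JSON so runs can be inspected at
desk scale: activity tables, curated datasets, evaluation reports, model
sidecars.  Validation errors name the offending rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .bsf import BSF_CUTOFF
from .chem import FINGERPRINT_BITS, FINGERPRINT_RADIUS
from .curation import VALID_FLAGS, VALID_SOURCES
from .evaluation import MIN_CIAT_COUNT, REPORT_COLUMNS

RESULT_COLUMNS = [
    "compound_id",
    "assay_id",
    "technology",
    "assay_kind",
    "activity_flag",
    "flag_source",
]

SCHEMA_TAG = "ciat-triage/v1"


@dataclass
class RunConfig:
    """End-to-end run configuration; defaults are the published protocol.

    1024-bit radius-2 fingerprints, pBSF cutoff 2, assays kept only with
    more than five CIATs, LOAO on.
    """

    campaign_dir: str = "."
    out_dir: str = "out"
    technologies: list[str] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["rfc", "bsf", "pains"])
    seed: int = 0
    bsf_cutoff: float = BSF_CUTOFF
    fingerprint_radius: int = FINGERPRINT_RADIUS
    fingerprint_bits: int = FINGERPRINT_BITS
    min_ciat_count: int = MIN_CIAT_COUNT
    loao: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long activity-results CSV.

    Required columns: compound_id, assay_id, technology, assay_kind,
    activity_flag, flag_source (may be empty for artefact rows).  Unknown
    flags or kinds are rejected with their 1-based data row numbers.
    """
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_flag = ~df["activity_flag"].isin(VALID_FLAGS)
    if bad_flag.any():
        rows = (df.index[bad_flag] + 1).tolist()[:10]
        vals = sorted(set(df.loc[bad_flag, "activity_flag"]))
        raise ValueError(
            f"{path}: invalid activity_flag values {vals} at rows {rows}"
        )
    bad_kind = ~df["assay_kind"].isin(["primary", "artefact"])
    if bad_kind.any():
        rows = (df.index[bad_kind] + 1).tolist()[:10]
        raise ValueError(f"{path}: invalid assay_kind at rows {rows}")
    bad_src = ~df["flag_source"].isin(VALID_SOURCES)
    if bad_src.any():
        rows = (df.index[bad_src] + 1).tolist()[:10]
        raise ValueError(f"{path}: invalid flag_source at rows {rows}")
    return df[RESULT_COLUMNS]


def write_activity_table(df: pd.DataFrame, path: str | Path) -> None:
    df[RESULT_COLUMNS].to_csv(path, index=False)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write an evaluation report CSV with a schema tag comment line."""
    path = Path(path)
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ValueError(f"report is missing columns {missing}")
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_TAG}\n")
        report[REPORT_COLUMNS].to_csv(fh, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read an evaluation report, checking the schema tag and columns."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# schema:"):
            raise ValueError(f"{path}: missing schema tag line")
        tag = first.split(":", 1)[1].strip()
        if tag != SCHEMA_TAG:
            raise ValueError(f"{path}: schema {tag!r} != expected {SCHEMA_TAG!r}")
        df = pd.read_csv(fh, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: report missing columns {missing}")
    for col in ("mcc", "recall", "precision", "auc"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("n", "TP", "FP", "TN", "FN"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return df[REPORT_COLUMNS]
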