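"""Curation of raw activity tables into per-technology CIAT/NCIAT datasets.

The labeling protocol mirrors how counter-screen (artefact) assays are used
for experimental HTS triage:

* per (compound, primary assay), activity flags are reconciled — Z-score
  flags take precedence over percent-effect flags, conflicting
  active/inactive calls at the same conditions resolve to active, and
  records left with only inconclusive flags are discarded;
* compounds active in at least one artefact-linked primary assay of a
  technology are labeled: active in any artefact assay of that technology
  -> CIAT, inactive in all -> NCIAT; compounds without artefact evidence
  are excluded;
* labeled compounds with parseable structures are fingerprinted into a
  :class:`TechnologyDataset` ready for model training.

A PubChem BioAssay ingestion path applies the same idea to public
counter-screen exports (activity outcome column, inconclusive dropped,
cross-assay conflicts dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    FINGERPRINT_BITS,
    FINGERPRINT_RADIUS,
    StructureParseError,
    compute_fingerprint,
)

logger = logging.getLogger(__name__)

FLAG_ACTIVE = "active"
FLAG_INACTIVE = "inactive"
FLAG_INCONCLUSIVE = "inconclusive"
VALID_FLAGS = frozenset({FLAG_ACTIVE, FLAG_INACTIVE, FLAG_INCONCLUSIVE})
VALID_SOURCES = frozenset({"zscore", "percent_effect", ""})

LABEL_CIAT = "CIAT"
LABEL_NCIAT = "NCIAT"


@dataclass(frozen=True)
class AssayResult:
    """One (compound, assay) outcome."""

    compound_id: str
    assay_id: str
    technology: str
    assay_kind: str  # primary | artefact
    activity_flag: str  # active | inactive | inconclusive
    flag_source: str = ""  # zscore | percent_effect (primary only)

    def __post_init__(self) -> None:
        if self.assay_kind not in ("primary", "artefact"):
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")
        if self.activity_flag not in VALID_FLAGS:
            raise ValueError(f"unknown activity flag {self.activity_flag!r}")
        if self.flag_source not in VALID_SOURCES:
            raise ValueError(f"unknown flag source {self.flag_source!r}")


@dataclass
class TechnologyDataset:
    """Curated training table for one technology.

    One row per labeled compound: id, structure, CIAT/NCIAT label and the
    set of artefact-linked primary assays where the compound was active.
    ``fingerprints`` is the matching (n, bits) 0/1 matrix.
    """

    technology: str
    table: pd.DataFrame
    fingerprints: np.ndarray
    radius: int = FINGERPRINT_RADIUS
    n_bits: int = FINGERPRINT_BITS

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        """Boolean CIAT indicator per row."""
        return (self.table["label"] == LABEL_CIAT).to_numpy()

    @property
    def compound_ids(self) -> np.ndarray:
        return self.table["compound_id"].to_numpy()

    def active_assay_sets(self) -> dict[str, frozenset[str]]:
        return {
            row.compound_id: frozenset(row.active_assays)
            for row in self.table.itertuples()
        }

    def assay_ids(self) -> list[str]:
        out: set[str] = set()
        for assays in self.table["active_assays"]:
            out.update(assays)
        return sorted(out)

    def class_counts(self) -> tuple[int, int]:
        n_ciat = int((self.table["label"] == LABEL_CIAT).sum())
        return n_ciat, len(self.table) - n_ciat

    def prevalence(self) -> float:
        n_ciat, n_nciat = self.class_counts()
        total = n_ciat + n_nciat
        return n_ciat / total if total else float("nan")

    def summary(self) -> str:
        n_ciat, n_nciat = self.class_counts()
        return (
            f"{self.technology}: {len(self)} compounds, "
            f"{n_ciat} CIATs ({100 * self.prevalence():.1f} %), "
            f"{n_nciat} NCIATs ({100 * (1 - self.prevalence()):.1f} %)"
        )

    def subset(self, mask: np.ndarray) -> "TechnologyDataset":
        return TechnologyDataset(
            technology=self.technology,
            table=self.table.loc[mask].reset_index(drop=True),
            fingerprints=self.fingerprints[np.asarray(mask)],
            radius=self.radius,
            n_bits=self.n_bits,
        )


def _validate_flags(results: pd.DataFrame) -> None:
    bad = set(results["activity_flag"]) - VALID_FLAGS
    if bad:
        raise ValueError(f"unknown activity flag values: {sorted(bad)}")


def reconcile_primary_flags(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse primary-assay flags to one flag per (compound, assay).

    Z-score flags take precedence: if a (compound, assay) pair has any
    conclusive Z-score flag, percent-effect flags are ignored; pairs
    without a conclusive Z-score flag fall back to conclusive
    percent-effect flags.  Within the considered flags, a compound found
    both active and inactive at the same conditions (same assay) is
    classified active.  Pairs with only inconclusive flags are dropped.

    The result is independent of the input row order.
    """
    if len(results) == 0:
        return pd.DataFrame(
            columns=["compound_id", "assay_id", "technology", "activity_flag"]
        )
    if (results["assay_kind"] != "primary").any():
        raise ValueError("reconcile_primary_flags expects primary-assay rows only")
    _validate_flags(results)

    df = results.copy()
    df["_conclusive"] = df["activity_flag"] != FLAG_INCONCLUSIVE
    df["_z"] = df["flag_source"] == "zscore"
    df["_active"] = df["activity_flag"] == FLAG_ACTIVE

    def _one(group: pd.DataFrame) -> str | None:
        z = group[group["_z"] & group["_conclusive"]]
        considered = z if len(z) else group[group["_conclusive"]]
        if len(considered) == 0:
            return None  # inconclusive-only: discarded
        return FLAG_ACTIVE if considered["_active"].any() else FLAG_INACTIVE

    grouped = (
        df.groupby(["compound_id", "assay_id", "technology"], sort=True)
        .apply(_one, include_groups=False)
        .dropna()
        .rename("activity_flag")
        .reset_index()
    )
    return grouped


def derive_technology_labels(
    primary_flags: pd.DataFrame,
    artefact_results: pd.DataFrame,
    linked_primary_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Label primary actives as CIAT/NCIAT from artefact outcomes.

    Only primary assays with artefact follow-up contribute activity:
    ``linked_primary_ids`` restricts the reconciled primary flags (pass
    ``None`` if the table is already restricted).  Compounds active in at
    least one linked primary get a label: active in any artefact assay of
    the technology -> CIAT; inactive in all -> NCIAT; compounds with no
    conclusive artefact result are excluded.

    Returns ``compound_id, technology, label, active_assays`` (tuple of
    linked primaries where the compound was active).
    """
    flags = primary_flags
    if linked_primary_ids is not None:
        linked = set(linked_primary_ids)
        flags = flags[flags["assay_id"].isin(linked)]
    active = flags[flags["activity_flag"] == FLAG_ACTIVE]
    if len(active) == 0:
        return pd.DataFrame(
            columns=["compound_id", "technology", "label", "active_assays"]
        )

    _validate_flags(artefact_results)
    art = artefact_results[
        artefact_results["activity_flag"] != FLAG_INCONCLUSIVE
    ]
    art_state = (
        art.assign(_active=art["activity_flag"] == FLAG_ACTIVE)
        .groupby(["compound_id", "technology"], sort=True)["_active"]
        .any()
    )

    membership = (
        active.groupby(["compound_id", "technology"], sort=True)["assay_id"]
        .apply(lambda s: tuple(sorted(set(s))))
        .rename("active_assays")
        .reset_index()
    )
    key = pd.MultiIndex.from_frame(membership[["compound_id", "technology"]])
    art_any = art_state.reindex(key)
    labeled = membership[art_any.notna().to_numpy()].copy()
    labeled["label"] = np.where(
        art_any.dropna().to_numpy(), LABEL_CIAT, LABEL_NCIAT
    )
    return labeled[["compound_id", "technology", "label", "active_assays"]].reset_index(
        drop=True
    )


def build_dataset(
    labels: pd.DataFrame,
    compounds: pd.DataFrame,
    technology: str | None = None,
    radius: int = FINGERPRINT_RADIUS,
    n_bits: int = FINGERPRINT_BITS,
) -> TechnologyDataset:
    """Assemble a fingerprinted :class:`TechnologyDataset` from labels.

    ``compounds`` maps compound ids to SMILES.  Records whose structure
    cannot be parsed are discarded (and counted in the log).  Raises
    ``ValueError`` if no labeled, parseable compound remains.
    """
    if technology is not None:
        labels = labels[labels["technology"] == technology]
    else:
        techs = labels["technology"].unique()
        if len(techs) > 1:
            raise ValueError(
                f"labels span several technologies {sorted(techs)}; pass technology="
            )
        technology = str(techs[0]) if len(techs) else ""
    merged = labels.merge(
        compounds[["compound_id", "smiles"]], on="compound_id", how="left"
    )
    rows = []
    fps = []
    n_dropped = 0
    for row in merged.itertuples():
        smiles = row.smiles
        try:
            fp = compute_fingerprint(str(smiles), radius=radius, n_bits=n_bits)
        except StructureParseError:
            n_dropped += 1
            continue
        rows.append(
            (row.compound_id, smiles, row.label, tuple(row.active_assays))
        )
        fps.append(fp)
    if not rows:
        raise ValueError(f"no usable labeled compounds for {technology!r}")
    table = pd.DataFrame(
        rows, columns=["compound_id", "smiles", "label", "active_assays"]
    )
    dataset = TechnologyDataset(
        technology=technology,
        table=table,
        fingerprints=np.vstack(fps).astype(np.uint8),
        radius=radius,
        n_bits=n_bits,
    )
    if n_dropped:
        logger.info("%s: dropped %d unparseable structures", technology, n_dropped)
    logger.info("%s", dataset.summary())
    return dataset


def curate_campaign(
    campaign, radius: int = FINGERPRINT_RADIUS, n_bits: int = FINGERPRINT_BITS
) -> dict[str, TechnologyDataset]:
    """Run the full curation chain on a synthetic campaign, per technology."""
    out: dict[str, TechnologyDataset] = {}
    res = campaign.results
    for tech in campaign.config.technologies:
        tech_res = res[res["technology"] == tech]
        primary = tech_res[tech_res["assay_kind"] == "primary"]
        artefact = tech_res[tech_res["assay_kind"] == "artefact"]
        reconciled = reconcile_primary_flags(primary)
        labels = derive_technology_labels(
            reconciled,
            artefact,
            linked_primary_ids=campaign.linked_primary_assays(tech),
        )
        out[tech] = build_dataset(
            labels, campaign.compounds, technology=tech, radius=radius, n_bits=n_bits
        )
    return out


def ingest_pubchem(
    csv_files: Sequence[str | Path],
    technology: str,
    smiles_column: str = "PUBCHEM_EXT_DATASOURCE_SMILES",
) -> pd.DataFrame:
    """Curate PubChem BioAssay CSV exports of artefact assays into labels.

    Active and inactive outcomes become CIAT and NCIAT; inconclusive (and
    unspecified) outcomes are discarded; compounds that are CIAT in one of
    the technology's assays and NCIAT in another are discarded as
    conflicting.  Returns ``compound_id, technology, label[, smiles]``.
    """
    frames = []
    for path in csv_files:
        df = pd.read_csv(path)
        id_col = next(
            (c for c in ("PUBCHEM_CID", "PUBCHEM_SID") if c in df.columns), None
        )
        if id_col is None:
            raise ValueError(f"{path}: no PUBCHEM_CID or PUBCHEM_SID column")
        if "PUBCHEM_ACTIVITY_OUTCOME" not in df.columns:
            raise ValueError(f"{path}: missing PUBCHEM_ACTIVITY_OUTCOME column")
        sub = df[df[id_col].notna()].copy()
        sub["compound_id"] = sub[id_col].astype("Int64").astype(str)
        sub["outcome"] = sub["PUBCHEM_ACTIVITY_OUTCOME"].astype(str).str.lower()
        if smiles_column in df.columns:
            sub["smiles"] = sub[smiles_column]
        frames.append(sub)
    merged = pd.concat(frames, ignore_index=True)
    conclusive = merged[merged["outcome"].isin(["active", "inactive"])]
    state = conclusive.groupby("compound_id")["outcome"].agg(set)
    consistent = state[state.apply(len) == 1]
    labels = consistent.apply(
        lambda s: LABEL_CIAT if "active" in s else LABEL_NCIAT
    ).rename("label")
    out = labels.reset_index()
    out["technology"] = technology
    if "smiles" in merged.columns:
        smiles = merged.dropna(subset=["smiles"]).drop_duplicates("compound_id")
        out = out.merge(smiles[["compound_id", "smiles"]], on="compound_id", how="left")
    out["active_assays"] = [() for _ in range(len(out))]
    cols = ["compound_id", "technology", "label", "active_assays"]
    if "smiles" in out.columns:
        cols.append("smiles")
    return out[cols]
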