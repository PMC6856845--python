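"""Flag reconciliation and CIAT/NCIAT labeling rules."""

import numpy as np
import pandas as pd
import pytest

from ciat_triage import (
    AssayResult,
    build_dataset,
    derive_technology_labels,
    ingest_pubchem,
    reconcile_primary_flags,
)


def _primary(cid, aid, flag, source="zscore", tech="AlphaScreen"):
    return {
        "compound_id": cid,
        "assay_id": aid,
        "technology": tech,
        "assay_kind": "primary",
        "activity_flag": flag,
        "flag_source": source,
    }


def _artefact(cid, aid, flag, tech="AlphaScreen"):
    return {
        "compound_id": cid,
        "assay_id": aid,
        "technology": tech,
        "assay_kind": "artefact",
        "activity_flag": flag,
        "flag_source": "",
    }


class TestReconcilePrimaryFlags:
    def test_zscore_flag_takes_precedence(self):
        df = pd.DataFrame(
            [
                _primary("c1", "A1", "inactive", "zscore"),
                _primary("c1", "A1", "active", "percent_effect"),
            ]
        )
        out = reconcile_primary_flags(df)
        assert out.loc[0, "activity_flag"] == "inactive"

    def test_percent_effect_used_when_no_zscore(self):
        df = pd.DataFrame([_primary("c1", "A1", "active", "percent_effect")])
        out = reconcile_primary_flags(df)
        assert out.loc[0, "activity_flag"] == "active"

    def test_conflicting_calls_resolve_to_active(self):
        df = pd.DataFrame(
            [
                _primary("c1", "A1", "active", "zscore"),
                _primary("c1", "A1", "inactive", "zscore"),
            ]
        )
        out = reconcile_primary_flags(df)
        assert out.loc[0, "activity_flag"] == "active"

    def test_inconclusive_only_records_dropped(self):
        df = pd.DataFrame(
            [
                _primary("c1", "A1", "inconclusive", "zscore"),
                _primary("c2", "A1", "active", "zscore"),
            ]
        )
        out = reconcile_primary_flags(df)
        assert list(out["compound_id"]) == ["c2"]

    def test_inconclusive_zscore_falls_back_to_percent(self):
        df = pd.DataFrame(
            [
                _primary("c1", "A1", "inconclusive", "zscore"),
                _primary("c1", "A1", "active", "percent_effect"),
            ]
        )
        out = reconcile_primary_flags(df)
        assert out.loc[0, "activity_flag"] == "active"

    def test_unknown_flag_rejected(self):
        df = pd.DataFrame([_primary("c1", "A1", "maybe")])
        with pytest.raises(ValueError, match="maybe"):
            reconcile_primary_flags(df)

    def test_artefact_rows_rejected(self):
        df = pd.DataFrame([_artefact("c1", "X1", "active")])
        with pytest.raises(ValueError, match="primary"):
            reconcile_primary_flags(df)

    def test_order_independent(self):
        rows = [
            _primary("c1", "A1", "inactive", "zscore"),
            _primary("c1", "A1", "active", "percent_effect"),
            _primary("c2", "A1", "active", "zscore"),
            _primary("c2", "A2", "inconclusive", "zscore"),
            _primary("c3", "A2", "inactive", "percent_effect"),
        ]
        base = reconcile_primary_flags(pd.DataFrame(rows))
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            out = reconcile_primary_flags(pd.DataFrame(perm))
            pd.testing.assert_frame_equal(base, out)


class TestDeriveTechnologyLabels:
    def test_any_active_artefact_means_ciat(self):
        flags = reconcile_primary_flags(
            pd.DataFrame([_primary("c1", "A1", "active")])
        )
        art = pd.DataFrame(
            [_artefact("c1", "X1", "active"), _artefact("c1", "X2", "inactive")]
        )
        out = derive_technology_labels(flags, art)
        assert out.loc[0, "label"] == "CIAT"

    def test_all_inactive_artefacts_mean_nciat(self):
        flags = reconcile_primary_flags(
            pd.DataFrame([_primary("c1", "A1", "active")])
        )
        art = pd.DataFrame([_artefact("c1", "X1", "inactive")])
        out = derive_technology_labels(flags, art)
        assert out.loc[0, "label"] == "NCIAT"

    def test_primary_inactive_gets_no_label(self):
        flags = reconcile_primary_flags(
            pd.DataFrame([_primary("c1", "A1", "inactive")])
        )
        art = pd.DataFrame([_artefact("c1", "X1", "active")])
        assert len(derive_technology_labels(flags, art)) == 0

    def test_missing_or_inconclusive_artefact_excluded(self):
        flags = reconcile_primary_flags(
            pd.DataFrame(
                [_primary("c1", "A1", "active"), _primary("c2", "A1", "active")]
            )
        )
        art = pd.DataFrame([_artefact("c2", "X1", "inconclusive")])
        assert len(derive_technology_labels(flags, art)) == 0

    def test_unlinked_assays_do_not_contribute(self):
        flags = reconcile_primary_flags(
            pd.DataFrame(
                [_primary("c1", "A1", "active"), _primary("c2", "A9", "active")]
            )
        )
        art = pd.DataFrame(
            [_artefact("c1", "X1", "inactive"), _artefact("c2", "X1", "inactive")]
        )
        out = derive_technology_labels(flags, art, linked_primary_ids=["A1"])
        assert list(out["compound_id"]) == ["c1"]

    def test_membership_lists_active_assays(self):
        flags = reconcile_primary_flags(
            pd.DataFrame(
                [
                    _primary("c1", "A1", "active"),
                    _primary("c1", "A2", "active"),
                    _primary("c1", "A3", "inactive"),
                ]
            )
        )
        art = pd.DataFrame([_artefact("c1", "X1", "inactive")])
        out = derive_technology_labels(flags, art)
        assert out.loc[0, "active_assays"] == ("A1", "A2")

    def test_idempotent(self):
        flags = reconcile_primary_flags(
            pd.DataFrame(
                [_primary("c1", "A1", "active"), _primary("c2", "A2", "active")]
            )
        )
        art = pd.DataFrame(
            [_artefact("c1", "X1", "active"), _artefact("c2", "X1", "inactive")]
        )
        first = derive_technology_labels(flags, art)
        second = derive_technology_labels(flags, art)
        pd.testing.assert_frame_equal(first, second)


class TestBuildDataset:
    def test_unparseable_structures_dropped(self):
        labels = pd.DataFrame(
            {
                "compound_id": ["c1", "c2"],
                "technology": "AlphaScreen",
                "label": ["CIAT", "NCIAT"],
                "active_assays": [("A1",), ("A1",)],
            }
        )
        compounds = pd.DataFrame(
            {"compound_id": ["c1", "c2"], "smiles": ["CCO", "not_a_smiles"]}
        )
        ds = build_dataset(labels, compounds)
        assert list(ds.table["compound_id"]) == ["c1"]
        assert ds.fingerprints.shape == (1, ds.n_bits)

    def test_empty_dataset_rejected(self):
        labels = pd.DataFrame(
            {
                "compound_id": ["c1"],
                "technology": "AlphaScreen",
                "label": ["CIAT"],
                "active_assays": [("A1",)],
            }
        )
        compounds = pd.DataFrame({"compound_id": ["c1"], "smiles": ["bad"]})
        with pytest.raises(ValueError, match="no usable"):
            build_dataset(labels, compounds)

    def test_summary_reports_counts_and_prevalence(self, small_datasets):
        ds = small_datasets["AlphaScreen"]
        n_ciat, n_nciat = ds.class_counts()
        text = ds.summary()
        assert str(n_ciat) in text and str(n_nciat) in text
        assert f"{100 * ds.prevalence():.1f} %" in text

    def test_labeled_compounds_traceable(self, small_campaign, small_datasets):
        # every labeled compound has >=1 active linked primary and >=1 artefact result
        res = small_campaign.results
        ds = small_datasets["FRET"]
        linked = set(small_campaign.linked_primary_assays("FRET"))
        artefact_ids = set(
            res.loc[
                (res["technology"] == "FRET") & (res["assay_kind"] == "artefact"),
                "compound_id",
            ]
        )
        for row in ds.table.itertuples():
            assert set(row.active_assays) <= linked
            assert len(row.active_assays) >= 1
            assert row.compound_id in artefact_ids


class TestAssayResultValidation:
    def test_valid_record_accepted(self):
        AssayResult("c1", "A1", "FRET", "primary", "active", "zscore")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"assay_kind": "confirmatory"},
            {"activity_flag": "maybe"},
            {"flag_source": "lumi"},
        ],
    )
    def test_bad_enums_rejected(self, kwargs):
        base = dict(
            compound_id="c1",
            assay_id="A1",
            technology="FRET",
            assay_kind="primary",
            activity_flag="active",
            flag_source="zscore",
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            AssayResult(**base)


class TestIngestPubchem:
    @staticmethod
    def _write(tmp_path, name, rows):
        df = pd.DataFrame(rows)
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    def test_curation_rules(self, tmp_path):
        aid1 = self._write(
            tmp_path,
            "aid1641.csv",
            [
                {"PUBCHEM_CID": 11, "PUBCHEM_ACTIVITY_OUTCOME": "Active"},
                {"PUBCHEM_CID": 12, "PUBCHEM_ACTIVITY_OUTCOME": "Inactive"},
                {"PUBCHEM_CID": 13, "PUBCHEM_ACTIVITY_OUTCOME": "Inconclusive"},
                {"PUBCHEM_CID": 14, "PUBCHEM_ACTIVITY_OUTCOME": "Active"},
            ],
        )
        aid2 = self._write(
            tmp_path,
            "aid504689.csv",
            [
                # conflicting with aid1 -> dropped
                {"PUBCHEM_CID": 14, "PUBCHEM_ACTIVITY_OUTCOME": "Inactive"},
                {"PUBCHEM_CID": 15, "PUBCHEM_ACTIVITY_OUTCOME": "Active"},
            ],
        )
        out = ingest_pubchem([aid1, aid2], technology="TR-FRET")
        labels = dict(zip(out["compound_id"], out["label"]))
        assert labels == {"11": "CIAT", "12": "NCIAT", "15": "CIAT"}
        assert set(out["technology"]) == {"TR-FRET"}

    def test_single_assay_active_is_ciat(self, tmp_path):
        aid = self._write(
            tmp_path,
            "aid435026.csv",
            [{"PUBCHEM_CID": 7, "PUBCHEM_ACTIVITY_OUTCOME": "Active"}],
        )
        out = ingest_pubchem([aid], technology="FRET")
        assert list(out["label"]) == ["CIAT"]

    def test_missing_outcome_column_rejected(self, tmp_path):
        path = self._write(tmp_path, "bad.csv", [{"PUBCHEM_CID": 1, "x": 2}])
        with pytest.raises(ValueError, match="PUBCHEM_ACTIVITY_OUTCOME"):
            ingest_pubchem([path], technology="FRET")
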