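"""Metrics, Set A/B protocol, LOAO comparison and scaling experiment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciat_triage import (
    ConfusionCounts,
    GeneratorConfig,
    ciat_count_filter,
    compute_metrics,
    crossover_fraction,
    crossval_10fold,
    curate_campaign,
    label_randomization_cv,
    loao_run,
    nn_analysis,
    simulate_campaign,
    split_sets,
)
from ciat_triage.evaluation import confusion, mcc, precision, recall, roc_auc


def brute_force_auc(y_true, scores):
    """Pairwise positive-vs-negative comparison with midrank ties."""
    y_true = np.asarray(y_true, dtype=bool)
    pos = np.asarray(scores, dtype=float)[y_true]
    neg = np.asarray(scores, dtype=float)[~y_true]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_prediction(self):
        c = ConfusionCounts(TP=5, FP=0, TN=5, FN=0)
        assert mcc(c) == 1.0
        assert recall(c) == 1.0
        assert precision(c) == 1.0

    def test_worked_example(self):
        c = ConfusionCounts(TP=3, FP=1, TN=4, FN=2)
        assert mcc(c) == pytest.approx(10 / np.sqrt(600))  # ~0.408
        assert recall(c) == pytest.approx(0.6)
        assert precision(c) == pytest.approx(0.75)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(TP=0, FP=0, TN=7, FN=3)) == 0.0
        assert recall(ConfusionCounts(TP=0, FP=2, TN=5, FN=0)) == 0.0
        assert precision(ConfusionCounts(TP=0, FP=0, TN=5, FN=2)) == 0.0

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        y = rng.random(4000) < 0.3
        s = rng.random(4000)
        assert abs(roc_auc(y, s) - 0.5) < 0.03

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))

    def test_matches_independent_oracles(self):
        from sklearn.metrics import (
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(4, 40))
            y = rng.random(n) < rng.uniform(0.2, 0.8)
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            m = compute_metrics(y, s, threshold=0.5)
            pred = s >= 0.5
            assert m["mcc"] == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
            assert m["recall"] == pytest.approx(
                recall_score(y, pred, zero_division=0), abs=1e-12
            )
            assert m["precision"] == pytest.approx(
                precision_score(y, pred, zero_division=0), abs=1e-12
            )
            if y.any() and not y.all():
                assert m["auc"] == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    @given(
        y=st.lists(st.booleans(), min_size=4, max_size=30),
        p=st.lists(st.booleans(), min_size=4, max_size=30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mcc_bounded_and_antisymmetric(self, y, p):
        n = min(len(y), len(p))
        y = np.array(y[:n])
        p = np.array(p[:n])
        c = confusion(y, p)
        value = mcc(c)
        assert -1.0 <= value <= 1.0
        assert mcc(confusion(y, ~p)) == pytest.approx(-value, abs=1e-12)


class TestSplitSets:
    MEMBERSHIP = {
        "c_ab": frozenset({"A1", "A2"}),
        "c_b": frozenset({"A2"}),
        "c_other": frozenset({"A1"}),
    }

    def test_definitions(self):
        set_a, set_b = split_sets("A2", self.MEMBERSHIP)
        assert set_a == ["c_ab"]  # also active in a training assay
        assert set_b == ["c_b"]  # novel to the technology

    def test_partition_of_held_out_actives(self):
        set_a, set_b = split_sets("A1", self.MEMBERSHIP)
        held = {c for c, m in self.MEMBERSHIP.items() if "A1" in m}
        assert set(set_a) | set(set_b) == held
        assert set(set_a) & set(set_b) == set()


class TestCiatCountFilter:
    def test_strict_threshold(self):
        assert not ciat_count_filter(["CIAT"] * 5 + ["NCIAT"])
        assert ciat_count_filter(["CIAT"] * 6)
        assert not ciat_count_filter(["NCIAT"] * 10)


@pytest.fixture(scope="module")
def report(small_datasets, small_campaign):
    res = small_campaign.results[
        small_campaign.results["technology"] == "AlphaScreen"
    ]
    return loao_run(small_datasets["AlphaScreen"], results=res, seed=0)


class TestLoao:
    def test_row_bookkeeping(self, report):
        ok = report[report["excluded_reason"] == ""]
        n_passing = ok["holdout_assay"].nunique()
        assert len(ok) == n_passing * 3 * 3  # methods x subsets

    def test_sets_partition_common_subset(self, report):
        ok = report[report["excluded_reason"] == ""]
        for (_, method), grp in ok.groupby(["holdout_assay", "method"]):
            by_subset = grp.set_index("subset")["n"]
            assert by_subset["all"] == by_subset["SetA"] + by_subset["SetB"]

    def test_methods_share_the_common_subset(self, report):
        ok = report[report["excluded_reason"] == ""]
        for (_, subset), grp in ok.groupby(["holdout_assay", "subset"]):
            assert grp["n"].nunique() == 1

    def test_confusion_counts_sum_to_n(self, report):
        ok = report[report["excluded_reason"] == ""]
        sums = ok[["TP", "FP", "TN", "FN"]].sum(axis=1)
        assert (sums == ok["n"]).all()

    def test_pains_near_chance_when_uncorrelated(self, report):
        ok = report[report["excluded_reason"] == ""]
        pains_auc = ok[(ok["method"] == "pains") & (ok["subset"] == "all")]["auc"]
        assert abs(pains_auc.mean() - 0.5) < 0.15

    def test_separable_campaign_set_a_is_perfect(
        self, separable_dataset, separable_campaign
    ):
        res = separable_campaign.results
        rep = loao_run(separable_dataset, results=res, methods=("rfc",), seed=0)
        ok = rep[(rep["excluded_reason"] == "") & (rep["subset"] == "SetA")]
        assert len(ok) > 0
        # every previously seen interferer is recovered; AUC is undefined
        # for slices where Set A happens to contain a single class
        assert (ok["recall"] == 1.0).all()
        assert (ok["FN"] == 0).all()
        assert (ok["auc"].dropna() > 0.99).all()

    def test_bsf_requires_results(self, small_datasets):
        with pytest.raises(ValueError, match="results"):
            loao_run(small_datasets["AlphaScreen"], methods=("bsf",))


class TestCrossval:
    def test_fold_count_and_determinism(self, small_datasets):
        ds = small_datasets["AlphaScreen"]
        a = crossval_10fold(ds, seed=4, n_splits=5)
        b = crossval_10fold(ds, seed=4, n_splits=5)
        assert len(a["fold_aucs"]) == 5
        assert a["fold_aucs"] == b["fold_aucs"]

    def test_small_class_cannot_stratify(self, small_datasets):
        ds = small_datasets["AlphaScreen"]
        keep = np.ones(len(ds), dtype=bool)
        ciat_rows = np.flatnonzero(ds.labels)
        keep[ciat_rows[3:]] = False  # leave only 3 CIATs
        with pytest.raises(ValueError, match="stratify"):
            crossval_10fold(ds.subset(keep), n_splits=10)

    def test_label_randomization_near_chance(self, small_datasets):
        out = label_randomization_cv(small_datasets["FRET"], seed=2, n_splits=5)
        # wide band: the fixture has only ~25 CIATs, so fold AUCs are noisy
        assert 0.3 < out["mean_auc"] < 0.7


class TestNNAnalysis:
    def _fps(self, rows):
        return np.array(rows, dtype=np.uint8)

    def test_identical_training_compound_counts_as_hit(self):
        train_fps = self._fps([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]])
        train_y = np.array([True, False, False])
        test_fps = self._fps([[1, 1, 0, 0]])
        out = nn_analysis(
            test_fps,
            np.array([True]),
            np.array([True]),
            train_fps,
            train_y,
            k=1,
            test_ids=["q"],
        )
        row = out.iloc[0]
        assert row["group"] == "TP"
        assert row["mean_tc_ciat"] == 1.0  # k=1: the single max similarity

    def test_groups_and_k_reduction(self):
        train_fps = self._fps([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 1]])
        train_y = np.array([True, False, False])
        test_fps = self._fps([[1, 0, 0, 0], [0, 0, 1, 1]])
        out = nn_analysis(
            test_fps,
            np.array([True, True]),
            np.array([True, False]),
            train_fps,
            train_y,
            k=5,  # larger than either class: reduced with a warning
        )
        assert sorted(out["group"]) == ["FN", "TP"]
        assert out["mean_tc_ciat"].between(0, 1).all()

    def test_true_positives_closer_to_training_ciats(self, separable_dataset):
        ds = separable_dataset
        half = len(ds) // 2
        train = ds.subset(np.arange(len(ds)) < half)
        test = ds.subset(np.arange(len(ds)) >= half)
        if train.labels.sum() < 5 or test.labels.sum() < 5:
            pytest.skip("fixture too small")
        from ciat_triage import predict, train as fit

        model = fit(train, seed=0)
        probs = predict(model, test.fingerprints)
        out = nn_analysis(
            test.fingerprints,
            test.labels,
            probs >= 0.5,
            train.fingerprints,
            train.labels,
        )
        tp = out[out["group"] == "TP"]["mean_tc_ciat"]
        if (out["group"] == "FN").any():
            fn = out[out["group"] == "FN"]["mean_tc_ciat"]
            assert tp.mean() >= fn.mean() - 0.05
        assert tp.mean() > out[out["group"] == "TP"]["mean_tc_nciat"].mean()


class TestScalingAndRecovery:
    def test_crossover_detection(self):
        df = pd.DataFrame(
            {
                "fraction": [0.2, 0.6, 1.0],
                "bsf_auc": [0.6, 0.8, 0.9],
                "rfc_auc": [0.75, 0.75, 0.75],
            }
        )
        assert crossover_fraction(df) == 0.6
        df["bsf_auc"] = [0.5, 0.6, 0.7]
        assert crossover_fraction(df) is None

    def test_stronger_motif_coupling_raises_set_b_auc(self):
        # parameter recovery: a tighter structure-interference link must
        # yield better novel-compound (Set B) predictions
        aucs = {}
        for tag, p_m in (("weak", 0.05), ("strong", 0.6)):
            cfg = GeneratorConfig(
                n_compounds=2500,
                technologies=("AlphaScreen",),
                n_primary_assays=4,
                n_extra_primary_assays=0,
                p_ciat_given_motif=p_m,
                p_ciat_no_motif=0.01,
                target_ciat_prevalence=None,
                seed=31,
            )
            camp = simulate_campaign(cfg)
            ds = curate_campaign(camp)["AlphaScreen"]
            rep = loao_run(ds, methods=("rfc",), seed=0, min_ciat=3)
            ok = rep[(rep["excluded_reason"] == "") & (rep["subset"] == "SetB")]
            aucs[tag] = ok["auc"].mean()
        assert aucs["strong"] > aucs["weak"] + 0.05
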