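"""Comparison machinery for the three triage methods (RFC, BSF, PAINS).

Implements the leave-one-assay-out (LOAO) protocol: for each assay of a
technology, train/score on all other assays and predict that assay's
primary actives.  Held-out compounds that also occur in a training assay
form Set A (previously seen); compounds found only in the held-out assay
form Set B (novel).  Metrics are MCC, recall, precision and ROC AUC;
assays with five or fewer interference compounds, or without Set-B
compounds, are flagged excluded rather than silently dropped.  When
methods are compared, metrics are restricted to the compounds every
method can predict (BSF cannot score never-tested compounds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import bsf as bsf_mod
from . import rfc as rfc_mod
from .chem import SubstructureCatalog, cross_tanimoto, load_pains_catalog, mol_from_smiles
from .curation import LABEL_CIAT, TechnologyDataset

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "technology",
    "holdout_assay",
    "method",
    "subset",
    "n",
    "TP",
    "FP",
    "TN",
    "FN",
    "mcc",
    "recall",
    "precision",
    "auc",
    "excluded_reason",
]

MIN_CIAT_COUNT = 5  # assays need strictly more CIATs than this


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("label and prediction vectors differ in length")
    return ConfusionCounts(
        TP=int(np.sum(y_true & y_pred)),
        FP=int(np.sum(~y_true & y_pred)),
        TN=int(np.sum(~y_true & ~y_pred)),
        FN=int(np.sum(y_true & ~y_pred)),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def recall(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when there are no positives."""
    denom = counts.TP + counts.FN
    return counts.TP / denom if denom else 0.0


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when nothing is predicted positive."""
    denom = counts.TP + counts.FP
    return counts.TP / denom if denom else 0.0


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC from score ranking (midrank tie convention); NaN if one class."""
    y_true = np.asarray(y_true, dtype=bool)
    if len(y_true) == 0 or y_true.all() or not y_true.any():
        return float("nan")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def compute_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    y_pred: np.ndarray | None = None,
    threshold: float = 0.5,
) -> dict:
    """MCC, recall, precision and ROC AUC for one evaluation slice."""
    y_true = np.asarray(y_true, dtype=bool)
    if len(y_true) == 0:
        raise ValueError("empty label set")
    if y_pred is None:
        y_pred = np.asarray(scores, dtype=float) >= threshold
    counts = confusion(y_true, y_pred)
    return {
        "counts": counts,
        "mcc": mcc(counts),
        "recall": recall(counts),
        "precision": precision(counts),
        "auc": roc_auc(y_true, scores),
    }


def split_sets(
    held_out_assay: str, active_assays_by_compound: Mapping[str, frozenset[str]]
) -> tuple[list[str], list[str]]:
    """Partition the held-out assay's actives into Set A and Set B.

    Set A: compounds also active in at least one other (training) assay of
    the technology.  Set B: compounds found only in the held-out assay.
    """
    set_a, set_b = [], []
    for cid, assays in active_assays_by_compound.items():
        if held_out_assay not in assays:
            continue
        if assays - {held_out_assay}:
            set_a.append(cid)
        else:
            set_b.append(cid)
    return sorted(set_a), sorted(set_b)


def ciat_count_filter(labels: Sequence[str] | np.ndarray, minimum: int = MIN_CIAT_COUNT) -> bool:
    """Keep an assay only if it has strictly more than ``minimum`` CIATs."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        n_ciat = int(arr.sum())
    else:
        n_ciat = int((arr == LABEL_CIAT).sum())
    return n_ciat > minimum


def _pains_flags(dataset: TechnologyDataset, catalog: SubstructureCatalog) -> np.ndarray:
    return np.array(
        [catalog.matches_any(mol_from_smiles(s)) for s in dataset.table["smiles"]],
        dtype=bool,
    )


def _excluded_rows(
    technology: str, holdout: str, methods: Sequence[str], reason: str
) -> list[dict]:
    return [
        {
            "technology": technology,
            "holdout_assay": holdout,
            "method": method,
            "subset": "all",
            "n": 0,
            "TP": 0,
            "FP": 0,
            "TN": 0,
            "FN": 0,
            "mcc": float("nan"),
            "recall": float("nan"),
            "precision": float("nan"),
            "auc": float("nan"),
            "excluded_reason": reason,
        }
        for method in methods
    ]


def loao_run(
    dataset: TechnologyDataset,
    results: pd.DataFrame | None = None,
    methods: Sequence[str] = ("rfc", "bsf", "pains"),
    pains_catalog: SubstructureCatalog | None = None,
    hyperparameters: Mapping | None = None,
    tune: bool = False,
    model_config: rfc_mod.ModelConfig | None = None,
    bsf_assays: Iterable[str] | None = None,
    bsf_cutoff: float = bsf_mod.BSF_CUTOFF,
    min_ciat: int = MIN_CIAT_COUNT,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-assay-out evaluation of the requested methods.

    For every artefact-linked primary assay: train/score each method on
    all other assays, predict the held-out actives, split them into Sets A
    and B, and compute metrics per subset on the common predictable
    compound set.  ``results`` (long primary-result table) is required for
    BSF; ``bsf_assays`` is BSF's assay universe (default: every primary
    assay in ``results``).

    Returns the evaluation report as a tidy DataFrame (one row per
    technology x held-out assay x method x subset).
    """
    methods = [m.lower() for m in methods]
    if "bsf" in methods and results is None:
        raise ValueError("BSF evaluation requires the primary results table")
    if "pains" in methods and pains_catalog is None:
        pains_catalog = load_pains_catalog()

    membership = dataset.active_assay_sets()
    holdouts = dataset.assay_ids()
    ids = dataset.compound_ids
    idx_of = {cid: i for i, cid in enumerate(ids)}
    y_all = dataset.labels
    pains_all = (
        _pains_flags(dataset, pains_catalog) if "pains" in methods else None
    )
    primary_results = None
    if results is not None:
        primary_results = results[results["assay_kind"] == "primary"]
        if bsf_assays is None:
            bsf_assays = sorted(set(primary_results["assay_id"]))

    rows: list[dict] = []
    for holdout in holdouts:
        set_a, set_b = split_sets(holdout, membership)
        test_ids = set_a + set_b
        test_idx = np.array([idx_of[c] for c in test_ids], dtype=int)
        y_test = y_all[test_idx]

        if not ciat_count_filter(y_test, minimum=min_ciat):
            rows.extend(
                _excluded_rows(
                    dataset.technology, holdout, methods, f"ciat_count<={min_ciat}"
                )
            )
            continue
        if len(set_b) == 0:
            rows.extend(
                _excluded_rows(dataset.technology, holdout, methods, "no_set_b")
            )
            continue

        train_mask = np.array(
            [bool(membership[c] - {holdout}) for c in ids], dtype=bool
        )
        scores: dict[str, np.ndarray] = {}
        preds: dict[str, np.ndarray] = {}
        predictable = np.ones(len(test_ids), dtype=bool)

        if "rfc" in methods:
            train_ds = dataset.subset(train_mask)
            if len(np.unique(train_ds.labels)) < 2:
                rows.extend(
                    _excluded_rows(
                        dataset.technology, holdout, methods, "single_class_training"
                    )
                )
                continue
            params = hyperparameters
            if tune:
                cfg = model_config or rfc_mod.ModelConfig(seed=seed)
                params = rfc_mod.tune_hyperparameters(train_ds, cfg)
            model = rfc_mod.train(train_ds, params, seed=seed)
            p = rfc_mod.predict(model, dataset.fingerprints[test_idx])
            scores["rfc"] = p
            preds["rfc"] = p >= 0.5

        if "bsf" in methods:
            bsf_table = bsf_mod.bsf_loao(
                primary_results, holdout, assays=bsf_assays, cutoff=bsf_cutoff
            ).set_index("compound_id")
            bsf_table = bsf_table.reindex(test_ids)
            sc = bsf_table["pbsf"].fillna(0.0).to_numpy(dtype=float)
            ok = bsf_table["predictable"].fillna(False).to_numpy(dtype=bool)
            scores["bsf"] = sc
            preds["bsf"] = sc >= bsf_cutoff
            predictable &= ok

        if "pains" in methods:
            flags = pains_all[test_idx]
            scores["pains"] = flags.astype(float)
            preds["pains"] = flags

        subset_masks = {
            "all": np.ones(len(test_ids), dtype=bool),
            "SetA": np.array([c in set(set_a) for c in test_ids], dtype=bool),
            "SetB": np.array([c in set(set_b) for c in test_ids], dtype=bool),
        }
        for subset, smask in subset_masks.items():
            emask = smask & predictable
            for method in methods:
                if emask.sum() == 0:
                    rows.extend(
                        _excluded_rows(
                            dataset.technology, holdout, [method], "empty_common_subset"
                        )
                    )
                    continue
                m = compute_metrics(
                    y_test[emask], scores[method][emask], y_pred=preds[method][emask]
                )
                c = m["counts"]
                rows.append(
                    {
                        "technology": dataset.technology,
                        "holdout_assay": holdout,
                        "method": method,
                        "subset": subset,
                        "n": int(emask.sum()),
                        "TP": c.TP,
                        "FP": c.FP,
                        "TN": c.TN,
                        "FN": c.FN,
                        "mcc": m["mcc"],
                        "recall": m["recall"],
                        "precision": m["precision"],
                        "auc": m["auc"],
                        "excluded_reason": "",
                    }
                )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def crossval_10fold(
    dataset: TechnologyDataset,
    seed: int = 0,
    hyperparameters: Mapping | None = None,
    n_splits: int = 10,
) -> dict:
    """Stratified k-fold cross-validation; returns mean and sd of ROC AUC.

    Folds are disjoint in compounds (each appears in exactly one
    validation fold).  Raises if a class is too small to stratify.
    """
    y = dataset.labels
    n_minority = int(min(y.sum(), (~y).sum()))
    if n_minority < n_splits:
        raise ValueError(
            f"minority class has {n_minority} members; cannot stratify "
            f"{n_splits} folds"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_aucs = []
    for k, (train_idx, val_idx) in enumerate(skf.split(dataset.fingerprints, y)):
        model = rfc_mod.train(
            dataset.subset(np.isin(np.arange(len(y)), train_idx)),
            hyperparameters,
            seed=seed,
        )
        p = rfc_mod.predict(model, dataset.fingerprints[val_idx])
        fold_aucs.append(roc_auc(y[val_idx], p))
    fold_aucs = np.array(fold_aucs, dtype=float)
    return {
        "mean_auc": float(np.nanmean(fold_aucs)),
        "sd_auc": float(np.nanstd(fold_aucs, ddof=1)),
        "fold_aucs": fold_aucs.tolist(),
    }


def label_randomization_cv(
    dataset: TechnologyDataset,
    seed: int = 0,
    hyperparameters: Mapping | None = None,
    n_splits: int = 10,
) -> dict:
    """Overfitting control: shuffle labels, repeat cross-validation."""
    shuffled = rfc_mod.randomize_labels(dataset, seed=seed)
    return crossval_10fold(
        shuffled, seed=seed, hyperparameters=hyperparameters, n_splits=n_splits
    )


def nn_analysis(
    test_fps: np.ndarray,
    test_is_ciat: np.ndarray,
    test_pred_ciat: np.ndarray,
    train_fps: np.ndarray,
    train_is_ciat: np.ndarray,
    k: int = 5,
    test_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Nearest-neighbor error analysis of interference predictions.

    For every test CIAT, grouped into true positives (TP) and false
    negatives (FN), computes the mean Tanimoto similarity to its k nearest
    neighbors among the training CIATs and, separately, among the training
    NCIATs.  Ties at equal similarity break deterministically by training
    row order.  If a training class is smaller than ``k``, k is reduced
    with a warning.  The raw per-compound values are returned; densities
    (for plotting) are a rendering of these.
    """
    test_is_ciat = np.asarray(test_is_ciat, dtype=bool)
    test_pred_ciat = np.asarray(test_pred_ciat, dtype=bool)
    train_is_ciat = np.asarray(train_is_ciat, dtype=bool)
    groups = {
        "TP": test_is_ciat & test_pred_ciat,
        "FN": test_is_ciat & ~test_pred_ciat,
    }
    class_fps = {
        "CIAT": np.asarray(train_fps)[train_is_ciat],
        "NCIAT": np.asarray(train_fps)[~train_is_ciat],
    }
    ks = {}
    for cls, fps in class_fps.items():
        kk = min(k, len(fps))
        if kk < k:
            logger.warning(
                "training %s class has only %d members; using k=%d", cls, len(fps), kk
            )
        if kk == 0:
            raise ValueError(f"training set has no {cls} compounds")
        ks[cls] = kk

    rows = []
    ids = list(test_ids) if test_ids is not None else list(range(len(test_is_ciat)))
    for group, gmask in groups.items():
        idxs = np.flatnonzero(gmask)
        if len(idxs) == 0:
            continue
        sims = {
            cls: cross_tanimoto(np.asarray(test_fps)[idxs], class_fps[cls])
            for cls in class_fps
        }
        for row_pos, i in enumerate(idxs):
            rec = {"compound_id": ids[i], "group": group}
            for cls in ("CIAT", "NCIAT"):
                tc = sims[cls][row_pos]
                order = np.argsort(-tc, kind="stable")[: ks[cls]]
                rec[f"mean_tc_{cls.lower()}"] = float(tc[order].mean())
            rows.append(rec)
    return pd.DataFrame(
        rows, columns=["compound_id", "group", "mean_tc_ciat", "mean_tc_nciat"]
    )


def bsf_scaling_experiment(
    results: pd.DataFrame,
    dataset: TechnologyDataset,
    base_assays: Sequence[str],
    pool_assays: Sequence[str],
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    seeds: Sequence[int] = (0,),
    holdouts: Sequence[str] | None = None,
    hyperparameters: Mapping | None = None,
    bsf_cutoff: float = bsf_mod.BSF_CUTOFF,
    rfc_seed: int = 0,
) -> pd.DataFrame:
    """Promiscuity-score performance as screening history grows.

    For each fraction of the unlinked-assay pool (the artefact-linked
    ``base_assays`` are always included) and each subsampling seed, BSF is
    evaluated leave-one-assay-out over ``holdouts`` (default: all base
    assays) on the compounds it can predict; the RFC metrics on the same
    compounds serve as the structure-based baseline.  Records the average
    number of screens per evaluated compound so statements like "BSF
    overtakes RFC once compounds are tested ~10 times" can be checked.

    Returns one row per (fraction, seed): mean AUC/MCC for BSF and RFC
    across holdouts plus the mean history size.
    """
    primary = results[results["assay_kind"] == "primary"]
    holdouts = list(holdouts) if holdouts is not None else list(base_assays)
    membership = dataset.active_assay_sets()
    ids = dataset.compound_ids
    idx_of = {cid: i for i, cid in enumerate(ids)}
    y_all = dataset.labels

    # constant RFC baseline per holdout (trained once, independent of fraction)
    rfc_scores: dict[str, pd.Series] = {}
    for holdout in holdouts:
        train_mask = np.array(
            [bool(membership[c] - {holdout}) for c in ids], dtype=bool
        )
        test_ids = [c for c in ids if holdout in membership[c]]
        train_ds = dataset.subset(train_mask)
        if len(np.unique(train_ds.labels)) < 2 or not test_ids:
            continue
        model = rfc_mod.train(train_ds, hyperparameters, seed=rfc_seed)
        p = rfc_mod.predict(
            model, dataset.fingerprints[[idx_of[c] for c in test_ids]]
        )
        rfc_scores[holdout] = pd.Series(p, index=test_ids)

    rows = []
    for fraction in fractions:
        for seed in seeds:
            sub = bsf_mod.subsample_assay_fraction(
                primary, fraction, seed=seed, base_assays=base_assays,
                pool_assays=pool_assays,
            )
            universe = sorted(set(sub["assay_id"]))
            bsf_aucs, bsf_mccs, rfc_aucs, n_tests = [], [], [], []
            for holdout in rfc_scores:
                table = bsf_mod.bsf_loao(
                    sub, holdout, assays=universe, cutoff=bsf_cutoff
                ).set_index("compound_id")
                test_ids = rfc_scores[holdout].index
                table = table.reindex(test_ids)
                ok = table["predictable"].fillna(False).to_numpy(dtype=bool)
                if ok.sum() < 2:
                    continue
                y = y_all[[idx_of[c] for c in test_ids]][ok]
                if y.all() or not y.any():
                    continue
                sc = table["pbsf"].to_numpy(dtype=float)[ok]
                bsf_aucs.append(roc_auc(y, sc))
                bsf_mccs.append(
                    mcc(confusion(y, sc >= bsf_cutoff))
                )
                rfc_aucs.append(roc_auc(y, rfc_scores[holdout].to_numpy()[ok]))
                n_tests.append(float(table["n_tested"].to_numpy()[ok].mean()))
            rows.append(
                {
                    "fraction": fraction,
                    "seed": seed,
                    "bsf_auc": float(np.mean(bsf_aucs)) if bsf_aucs else float("nan"),
                    "bsf_mcc": float(np.mean(bsf_mccs)) if bsf_mccs else float("nan"),
                    "rfc_auc": float(np.mean(rfc_aucs)) if rfc_aucs else float("nan"),
                    "mean_tests_per_compound": float(np.mean(n_tests))
                    if n_tests
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def crossover_fraction(scaling: pd.DataFrame) -> float | None:
    """Smallest assay fraction where mean BSF AUC reaches mean RFC AUC.

    Returns ``None`` when BSF never overtakes the structure-based model.
    """
    agg = scaling.groupby("fraction")[["bsf_auc", "rfc_auc"]].mean().sort_index()
    hit = agg[agg["bsf_auc"] >= agg["rfc_auc"]]
    return float(hit.index[0]) if len(hit) else None


def compare_report(
    report: pd.DataFrame, out_dir: str | Path, plots: bool = True
) -> dict[str, Path]:
    """Consolidate an evaluation report: CSV plus method-comparison plots."""
    from .io import write_report

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.csv"}
    write_report(report, paths["report"])
    if plots:
        paths["plot"] = out / "method_comparison.png"
        plot_method_comparison(report, paths["plot"])
    return paths


def plot_method_comparison(report: pd.DataFrame, path: str | Path) -> None:
    """Per-assay metric bars for each method, split by Set A / Set B."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = report[report["excluded_reason"] == ""]
    metrics = ["mcc", "recall", "precision", "auc"]
    subsets = ["SetA", "SetB"]
    fig, axes = plt.subplots(
        len(subsets), len(metrics), figsize=(4 * len(metrics), 3 * len(subsets)),
        squeeze=False,
    )
    colors = {"rfc": "tab:green", "bsf": "tab:blue", "pains": "tab:purple"}
    for i, subset in enumerate(subsets):
        sub = data[data["subset"] == subset]
        for j, metric in enumerate(metrics):
            ax = axes[i][j]
            for method, grp in sub.groupby("method"):
                vals = grp.sort_values("holdout_assay")[metric]
                ax.plot(
                    range(len(vals)),
                    vals,
                    "o-",
                    label=method.upper(),
                    color=colors.get(method, "gray"),
                    alpha=0.8,
                )
            ax.set_title(f"{subset} {metric.upper()}")
            ax.set_ylim(-0.05, 1.05)
            if i == 0 and j == 0:
                ax.legend(fontsize=8)
            ax.set_xlabel("held-out assay")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_nn_density(nn_table: pd.DataFrame, path: str | Path) -> None:
    """Kernel-density rendering of the nearest-neighbor similarity analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col, title in zip(
        axes,
        ["mean_tc_ciat", "mean_tc_nciat"],
        ["5-NN among training CIATs", "5-NN among training NCIATs"],
    ):
        for group, color in (("TP", "tab:blue"), ("FN", "tab:green")):
            vals = nn_table.loc[nn_table["group"] == group, col].dropna()
            if len(vals) > 1 and vals.std() > 0:
                xs = np.linspace(0, 1, 200)
                ax.plot(xs, gaussian_kde(vals)(xs), label=group, color=color)
            elif len(vals):
                ax.axvline(vals.iloc[0], label=group, color=color)
        ax.set_xlabel("mean Tanimoto to 5 NN")
        ax.set_title(title)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
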