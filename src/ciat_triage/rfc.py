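"""Random-forest CIAT classifier.

A random forest over 1024-bit circular fingerprints predicts the
probability that a compound interferes with a given assay technology.
Hyperparameters are chosen by random search with 3-fold cross-validation
scored by the Matthews correlation coefficient; a label-randomization
control (shuffle labels, re-run cross-validation) guards against reading
overfitting as signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold

from .curation import TechnologyDataset

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "DEFAULT_SEARCH_SPACE",
    "DEFAULT_HYPERPARAMETERS",
    "tune_hyperparameters",
    "train",
    "predict",
    "randomize_labels",
]

# Standard forest search space; the selection metric (MCC) and the 3-fold
# scheme are fixed, the space itself is configurable.
DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "n_estimators": [100, 200, 300, 500, 1000],
    "max_depth": [None, 10, 20],
    "min_samples_leaf": [1, 2, 5, 10],
    "max_features": ["sqrt", "log2"],
}

DEFAULT_HYPERPARAMETERS: dict[str, Any] = {
    "n_estimators": 300,
    "max_depth": None,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameter-search configuration.

    ``cv_folds`` defaults to 3 (two thirds train / one third validation per
    fold) and ``selection_metric`` is fixed to MCC.
    """

    search_space: Mapping[str, list] | None = None
    n_search_iters: int = 20
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_search_iters < 1:
            raise ValueError("n_search_iters must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def space(self) -> dict[str, list]:
        return dict(self.search_space or DEFAULT_SEARCH_SPACE)


@dataclass
class TrainedModel:
    """A fitted forest plus the provenance needed to rebuild its training set."""

    forest: RandomForestClassifier
    hyperparameters: dict[str, Any]
    technology: str
    training_assay_ids: list[str]
    n_bits: int
    seed: int = 0

    def save(self, path: str | Path) -> None:
        """Persist the forest (joblib) with a JSON provenance sidecar."""
        path = Path(path)
        joblib.dump(self.forest, path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "hyperparameters": {
                        k: v for k, v in self.hyperparameters.items()
                    },
                    "technology": self.technology,
                    "training_assay_ids": self.training_assay_ids,
                    "n_bits": self.n_bits,
                    "seed": self.seed,
                },
                indent=2,
                default=str,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        forest = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        hp = meta["hyperparameters"]
        if hp.get("max_depth") == "None":
            hp["max_depth"] = None
        return cls(
            forest=forest,
            hyperparameters=hp,
            technology=meta["technology"],
            training_assay_ids=list(meta["training_assay_ids"]),
            n_bits=int(meta["n_bits"]),
            seed=int(meta["seed"]),
        )


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(
            "training data contains a single class; both CIATs and NCIATs "
            "are required"
        )


def tune_hyperparameters(
    dataset: TechnologyDataset, config: ModelConfig | None = None
) -> dict[str, Any]:
    """Random search over the forest space, selected by mean 3-fold CV MCC.

    Deterministic given ``config.seed``.
    """
    config = config or ModelConfig()
    y = dataset.labels
    _check_two_classes(y)
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=config.seed, n_jobs=1),
        param_distributions=config.space,
        n_iter=config.n_search_iters,
        scoring=make_scorer(matthews_corrcoef),
        cv=StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        ),
        random_state=config.seed,
        n_jobs=1,
        refit=False,
    )
    search.fit(dataset.fingerprints, y)
    return dict(search.best_params_)


def train(
    dataset: TechnologyDataset,
    hyperparameters: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the forest on a curated technology dataset."""
    y = dataset.labels
    _check_two_classes(y)
    params = dict(hyperparameters or DEFAULT_HYPERPARAMETERS)
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    forest.fit(dataset.fingerprints, y)
    return TrainedModel(
        forest=forest,
        hyperparameters=params,
        technology=dataset.technology,
        training_assay_ids=dataset.assay_ids(),
        n_bits=dataset.n_bits,
        seed=seed,
    )


def predict(model: TrainedModel, fingerprints: np.ndarray) -> np.ndarray:
    """Probability of CIAT per compound (class at threshold 0.5)."""
    fps = np.atleast_2d(np.asarray(fingerprints))
    if fps.shape[1] != model.n_bits:
        raise ValueError(
            f"fingerprint length {fps.shape[1]} does not match the model's "
            f"{model.n_bits} bits"
        )
    proba = model.forest.predict_proba(fps)
    ciat_col = list(model.forest.classes_).index(True)
    return proba[:, ciat_col]


def randomize_labels(dataset: TechnologyDataset, seed: int) -> TechnologyDataset:
    """Shuffle CIAT/NCIAT labels across compounds (class counts preserved)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    table = dataset.table.copy()
    table["label"] = table["label"].to_numpy()[perm]
    return TechnologyDataset(
        technology=dataset.technology,
        table=table,
        fingerprints=dataset.fingerprints,
        radius=dataset.radius,
        n_bits=dataset.n_bits,
    )
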