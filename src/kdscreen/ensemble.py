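"""Stacking ensemble: three boosting base learners + logistic meta-classifier.

Base learners (published hyperparameters, everything else fixed defaults):

* gradient boosting, XGBoost flavour — learning rate 0.1, max depth 6,
  100 rounds;
* AdaBoost over trees capped at 31 leaf nodes with per-learner random
  feature subsampling at rate 0.8 (the stated parameter set reads like a
  LightGBM configuration; it is honoured literally as an AdaBoost variant);
* gradient boosting, LightGBM flavour — 50 boosting iterations.

Meta-features are out-of-fold (OOF) positive-class probabilities: row i's
meta-feature from learner b comes from a model trained on every stratified
fold except row i's, so no meta-feature derives from a model that saw its
own row. The meta-classifier is logistic regression (C = 1.0) fitted on
the OOF matrix against the true labels; internally it applies a logit link
to the probabilities (clipped away from 0/1), since base learners squash
their probability ranges very differently and a linear combination on the
raw probability scale lets the most squashed learner dominate the fit. For
inference, base learners are refit on the full table (standard stacking
practice) and their probabilities are combined by the meta-classifier.

Determinism: all learners are single-threaded and seeded; identical
table + config reproduce identical models and scores.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cohort import CohortTable
from .seeds import derive_seed

# lightgbm's sklearn wrapper names ndarray columns internally, which trips
# sklearn's feature-name consistency warning on every ndarray predict call
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)

_LOGIT_EPS = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class BaseSpec:
    name: str
    params: dict = field(default_factory=dict)


def default_base_specs() -> tuple[BaseSpec, ...]:
    return (
        BaseSpec("xgb", {"learning_rate": 0.1, "max_depth": 6, "n_estimators": 100}),
        BaseSpec("ada", {"max_leaf_nodes": 31, "feature_subsample": 0.8,
                         "n_estimators": 100}),
        BaseSpec("lgbm", {"n_estimators": 50}),
    )


@dataclass(frozen=True)
class StackingConfig:
    n_folds: int = 5
    base_specs: tuple[BaseSpec, ...] = field(default_factory=default_base_specs)
    meta_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.base_specs:
            raise ValueError("need at least one base learner")


class FeatureSubsampledAdaBoost:
    """AdaBoost over leaf-capped trees on a seeded random feature subset.

    The feature subset (rate 0.8 by default) is drawn once per learner at
    fit time; predictions are made on the same subset. Minimal estimator
    surface: fit / predict_proba.
    """

    def __init__(self, max_leaf_nodes: int = 31, feature_subsample: float = 0.8,
                 n_estimators: int = 100, seed: int = 0):
        self.max_leaf_nodes = max_leaf_nodes
        self.feature_subsample = feature_subsample
        self.n_estimators = n_estimators
        self.seed = seed
        self._cols: np.ndarray | None = None
        self._model: AdaBoostClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeatureSubsampledAdaBoost":
        rng = np.random.default_rng(self.seed)
        p = X.shape[1]
        m = max(1, int(np.ceil(self.feature_subsample * p)))
        self._cols = np.sort(rng.choice(p, size=m, replace=False))
        base = DecisionTreeClassifier(
            max_leaf_nodes=self.max_leaf_nodes, random_state=self.seed
        )
        self._model = AdaBoostClassifier(
            estimator=base, n_estimators=self.n_estimators, random_state=self.seed
        )
        self._model.fit(X[:, self._cols], y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        assert self._model is not None and self._cols is not None
        return self._model.predict_proba(X[:, self._cols])


def _make_base(spec: BaseSpec, seed: int) -> Any:
    if spec.name == "xgb":
        return XGBClassifier(
            learning_rate=spec.params.get("learning_rate", 0.1),
            max_depth=spec.params.get("max_depth", 6),
            n_estimators=spec.params.get("n_estimators", 100),
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            tree_method="hist",
            verbosity=0,
        )
    if spec.name == "ada":
        return FeatureSubsampledAdaBoost(
            max_leaf_nodes=spec.params.get("max_leaf_nodes", 31),
            feature_subsample=spec.params.get("feature_subsample", 0.8),
            n_estimators=spec.params.get("n_estimators", 100),
            seed=seed,
        )
    if spec.name == "lgbm":
        return LGBMClassifier(
            n_estimators=spec.params.get("n_estimators", 50),
            n_jobs=1,
            random_state=seed,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
        )
    raise ValueError(f"unknown base learner {spec.name!r}")


@dataclass
class StackingModel:
    config: StackingConfig
    base_models: list[Any]
    meta: LogisticRegression
    fold_assignment: np.ndarray
    feature_names: list[str]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "StackingModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_meta_features(
    table: CohortTable, config: StackingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """OOF positive-class probability matrix (n x B) + fold assignment.

    Folding is stratified so both classes appear in every fold even at 1:24
    imbalance; a fold that still lacks a class raises.
    """
    X, y = table.values, table.labels
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed % (2**31)
    )
    n, B = table.n_rows, len(config.base_specs)
    meta = np.full((n, B), np.nan)
    fold_assignment = np.empty(n, dtype=int)
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        fold_assignment[va] = fold
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError(f"fold {fold} lacks one of the classes")
        for b, spec in enumerate(config.base_specs):
            model = _make_base(spec, derive_seed(config.seed, f"{spec.name}:{fold}"))
            model.fit(X[tr], y[tr])
            meta[va, b] = model.predict_proba(X[va])[:, 1]
    assert not np.isnan(meta).any()
    return meta, fold_assignment


def train_stacking(table: CohortTable, config: StackingConfig = StackingConfig()) -> StackingModel:
    """Fit the full stacking model: OOF meta-features -> logistic meta, then
    refit each base learner on the complete table for inference."""
    meta, folds = build_meta_features(table, config)
    lr = LogisticRegression(C=config.meta_c, max_iter=1000)
    lr.fit(_logit(meta), table.labels)
    base_models = [
        _make_base(spec, derive_seed(config.seed, f"{spec.name}:full")).fit(
            table.values, table.labels
        )
        for spec in config.base_specs
    ]
    return StackingModel(
        config=config,
        base_models=base_models,
        meta=lr,
        fold_assignment=folds,
        feature_names=table.schema.names,
    )


def predict_scores(model: StackingModel, table: CohortTable) -> np.ndarray:
    """Positive-class scores in [0, 1], one per row."""
    if table.schema.names != model.feature_names:
        raise ValueError("table schema does not match the training schema")
    base_probs = np.column_stack(
        [m.predict_proba(table.values)[:, 1] for m in model.base_models]
    )
    return model.meta.predict_proba(_logit(base_probs))[:, 1]
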