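"""Gradient-boosted refinement classifier on the metric features.

Protocol: binary-logistic objective; grid search over learning rate
{0.01, 0.05, 0.1} x gamma {0.1, 1, 10} x max_depth {3, 6, 9} (27 points)
with ten-fold cross-validation selecting the best mean fold AUC; the chosen
point is refit on the full data. Label 1 = true variant, so the predicted
probability is the probability of being true.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold
from xgboost import XGBClassifier

from .core import GERMLINE_METRICS, SOMATIC_METRICS, ScoredVariant

logger = logging.getLogger(__name__)


@dataclass
class TrainingSpec:
    """Hyperparameter protocol for the refinement classifier."""

    objective: str = "binary:logistic"
    learning_rates: tuple[float, ...] = (0.01, 0.05, 0.1)
    gammas: tuple[float, ...] = (0.1, 1.0, 10.0)
    max_depths: tuple[int, ...] = (3, 6, 9)
    folds: int = 10
    seed: int = 0
    n_rounds: int = 100  # boosting rounds; the protocol leaves this at default

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @property
    def grid(self) -> list[dict]:
        return list(ParameterGrid({
            "learning_rate": list(self.learning_rates),
            "gamma": list(self.gammas),
            "max_depth": list(self.max_depths),
        }))


@dataclass
class FeatureMatrix:
    features: pd.DataFrame  # columns in canonical metric order
    labels: np.ndarray  # 1 = true variant
    keys: list[tuple]  # (chrom, pos, ref, alt) per row
    somatic: bool = False


@dataclass
class FittedModel:
    booster: XGBClassifier
    columns: tuple[str, ...]
    best_params: dict
    cv_table: pd.DataFrame
    spec: TrainingSpec

    @property
    def config_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr((self.columns, sorted(self.best_params.items()),
                       self.spec.seed, self.spec.n_rounds)).encode())
        h.update(self.booster.get_booster().save_raw(raw_format="json"))
        return h.hexdigest()

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "FittedModel":
        model = joblib.load(path)
        if not isinstance(model, FittedModel):
            raise ValueError(f"{path} does not contain a fitted refinement model")
        return model


def build_feature_matrix(
    scored: Sequence[ScoredVariant],
    truth: dict[tuple, int],
    somatic: bool = False,
) -> FeatureMatrix:
    """Join scored variants with labels by (chrom, pos, ref, alt).

    Unlabeled variants are excluded (counted in the log); column order is
    the canonical metric order and is embedded in any trained model.
    """
    names = SOMATIC_METRICS if somatic else GERMLINE_METRICS
    rows, labels, keys = [], [], []
    dropped = 0
    for sv in scored:
        key = sv.variant.key
        if key not in truth:
            dropped += 1
            continue
        md = sv.metrics.as_dict(somatic=somatic)
        rows.append([md[n] for n in names])
        labels.append(int(truth[key]))
        keys.append(key)
    if dropped:
        logger.warning("excluded %d scored variants without truth labels", dropped)
    return FeatureMatrix(
        features=pd.DataFrame(rows, columns=list(names)),
        labels=np.asarray(labels, dtype=int),
        keys=keys,
        somatic=somatic,
    )


def _make_estimator(spec: TrainingSpec, **params) -> XGBClassifier:
    return XGBClassifier(
        objective=spec.objective,
        n_estimators=spec.n_rounds,
        tree_method="hist",
        n_jobs=1,
        random_state=spec.seed,
        eval_metric="logloss",
        **params,
    )


def train(matrix: FeatureMatrix, spec: TrainingSpec) -> FittedModel:
    """Grid search + stratified k-fold CV on mean AUC, refit on full data."""
    y = matrix.labels
    pos, neg = int(y.sum()), int(len(y) - y.sum())
    if pos < spec.folds or neg < spec.folds:
        raise ValueError(
            f"need >= {spec.folds} examples per class, have {pos} positive / {neg} negative")
    cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec),
        param_grid={
            "learning_rate": list(spec.learning_rates),
            "gamma": list(spec.gammas),
            "max_depth": list(spec.max_depths),
        },
        scoring="roc_auc",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(matrix.features.values, y)
    cv_table = pd.DataFrame(search.cv_results_)[
        ["param_learning_rate", "param_gamma", "param_max_depth", "mean_test_score"]
    ]
    logger.info("grid search over %d points; best %s (mean CV AUC %.4f)",
                len(cv_table), search.best_params_, search.best_score_)
    return FittedModel(
        booster=search.best_estimator_,
        columns=tuple(matrix.features.columns),
        best_params=dict(search.best_params_),
        cv_table=cv_table,
        spec=spec,
    )


def predict(model: FittedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Per-variant probability of being a true variant."""
    cols = tuple(matrix.features.columns)
    if cols != model.columns:
        raise ValueError(
            f"feature columns {cols} do not match the model's embedded order {model.columns}")
    return model.booster.predict_proba(matrix.features.values)[:, 1]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney rank AUC (ties averaged) of scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
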