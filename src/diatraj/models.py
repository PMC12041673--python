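"""The five classifier families and gradient-boosting feature ranking.

Decision tree, random forest and AdaBoost come from scikit-learn, XGBoost
from the xgboost package.  LogitBoost — stagewise additive logistic
regression with depth-limited regression trees as base learners — has no
standard single implementation and is written here directly.

Feature ranking fits a gradient-boosted tree ensemble and orders features
by total gain; zero-importance features follow all positive ones, ordered
by feature index, so the ranking is a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from xgboost import XGBClassifier

MODEL_FAMILIES = ("decision_tree", "random_forest", "xgboost", "adaboost", "logitboost")

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "decision_tree": {},
    "random_forest": {"n_estimators": 100},
    "xgboost": {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.1},
    "adaboost": {"n_estimators": 100},
    "logitboost": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2},
}


@dataclass
class ModelSpec:
    family: str
    seed: int = 0
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    def params(self) -> dict[str, Any]:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        return merged


class LogitBoostClassifier:
    """Additive logistic boosting with regression-tree base learners.

    Each round fits a tree to the Newton working response
    z = (y - p) / (p (1 - p)) with weights w = p (1 - p), then updates the
    additive logit F by ``learning_rate`` times the tree's prediction.
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 2, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state
        self.trees_: list[DecisionTreeRegressor] = []
        self.f0_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogitBoostClassifier":
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("LogitBoost requires both classes in training data")
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        self.f0_ = float(np.log(pbar / (1 - pbar)))
        F = np.full(len(y), self.f0_)
        self.trees_ = []
        for m in range(self.n_estimators):
            p = expit(F)
            w = np.clip(p * (1 - p), 1e-5, None)
            z = np.clip((y - p) / w, -4.0, 4.0)
            seed = None if self.random_state is None else self.random_state + m
            tree = DecisionTreeRegressor(max_depth=self.max_depth,
                                         random_state=seed)
            tree.fit(X, z, sample_weight=w)
            F = F + self.learning_rate * tree.predict(X)
            self.trees_.append(tree)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        F = np.full(X.shape[0], self.f0_)
        for tree in self.trees_:
            F = F + self.learning_rate * tree.predict(X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])


def _build_estimator(spec: ModelSpec):
    p = spec.params()
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **p)
    if spec.family == "xgboost":
        return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", tree_method="hist", **p)
    if spec.family == "adaboost":
        return AdaBoostClassifier(random_state=spec.seed, **p)
    return LogitBoostClassifier(random_state=spec.seed, **p)


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: Any

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability per row."""
        return self.estimator.predict_proba(X)[:, 1]


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    est = _build_estimator(spec)
    est.fit(np.asarray(X, dtype=float), y)
    return FittedModel(spec, est)


@dataclass
class RankedFeatures:
    order: np.ndarray  # feature indices, importance descending
    scores: np.ndarray  # importance per feature index
    seed: int

    def top(self, k: int | str) -> np.ndarray:
        if k == "all":
            return self.order.copy()
        return self.order[: int(k)].copy()


def rank_features_xgb(
    X: np.ndarray, y: np.ndarray, seed: int = 0,
    n_estimators: int = 100, max_depth: int = 6, learning_rate: float = 0.1,
) -> RankedFeatures:
    """Order features by total gain of a gradient-boosted tree fit."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking requires both classes")
    model = XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        learning_rate=learning_rate, random_state=seed, n_jobs=1,
        verbosity=0, eval_metric="logloss", tree_method="hist",
    )
    model.fit(np.asarray(X, dtype=float), y)
    gains = model.get_booster().get_score(importance_type="total_gain")
    scores = np.zeros(X.shape[1])
    for name, gain in gains.items():
        scores[int(name[1:])] = gain
    order = np.array(sorted(range(X.shape[1]), key=lambda i: (-scores[i], i)))
    return RankedFeatures(order=order, scores=scores, seed=seed)
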