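"""Classifiers: two-class averaged perceptron, RUSBoost, baseline adapters.

The averaged perceptron is the primary model.  Training visits examples in a
seed-shuffled order each epoch under the +-1 label convention; on a
misclassification (y * w.x <= 0) the weights move by lr * y * x, and the
running average of the weight vector over *every* visit (updated or not) is
returned.  Features are standardized to zero mean / unit SD (SD floor 1e-8)
before training because a learning rate of 20 is only meaningful on a
bounded scale; the class score is the averaged-weight dot product on the
standardized input and a logistic squashing of that score serves as the
event probability.

RUSBoost is AdaBoost.M1 with a fresh random undersample of the majority
class in every boosting round, built on shallow sklearn decision trees; it
is used as the scorer of the greedy feature-combination search.  SVM /
logistic regression / decision forest baselines are thin adapters around
scikit-learn exposing the same train/score contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PerceptronConfig",
    "AveragedPerceptron",
    "RUSBoostConfig",
    "RUSBoostClassifier",
    "SkAdapter",
    "make_model",
]

SD_FLOOR = 1e-8


class Classifier(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier": ...
    def decision_function(self, X: np.ndarray) -> np.ndarray: ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"need both classes 0 and 1, got {classes.tolist()}")
    return X, y


@dataclass(frozen=True, slots=True)
class PerceptronConfig:
    learning_rate: float = 20.0
    max_iterations: int = 20
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class AveragedPerceptron:
    """Two-class averaged perceptron with internal standardization."""

    def __init__(self, config: PerceptronConfig | None = None):
        self.config = config or PerceptronConfig()
        self.weights_: np.ndarray | None = None  # length d+1, bias last
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.n_updates_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AveragedPerceptron":
        X, y = _check_training_inputs(X, y)
        cfg = self.config
        if cfg.standardize:
            self.mean_ = X.mean(axis=0)
            self.sd_ = np.maximum(X.std(axis=0), SD_FLOOR)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.sd_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.sd_
        Xb = np.hstack([Xs, np.ones((Xs.shape[0], 1))])
        yy = np.where(y == 1, 1.0, -1.0)

        rng = np.random.default_rng(cfg.seed)
        n, d = Xb.shape
        w = np.zeros(d)
        wsum = np.zeros(d)
        steps = 0
        updates = 0
        lr = cfg.learning_rate
        for _ in range(cfg.max_iterations):
            order = rng.permutation(n)
            for i in order:
                if yy[i] * (w @ Xb[i]) <= 0.0:
                    w += lr * yy[i] * Xb[i]
                    updates += 1
                wsum += w
                steps += 1
        self.weights_ = wsum / steps
        self.n_updates_ = updates
        return self

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.weights_ is None:
            raise ValueError("model is not fitted")
        if X.shape[1] != self.weights_.size - 1:
            raise ValueError(
                f"dimension mismatch: model expects {self.weights_.size - 1} "
                f"features, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.sd_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardized(X)
        return Xs @ self.weights_[:-1] + self.weights_[-1]

    def predict(self, X: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        # ties classify as 0 (specificity-favoring operating point)
        return (self.decision_function(X) > threshold).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Event probability as a logistic squashing of the score."""
        s = self.decision_function(X)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-s))

    # JSON round-trip -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        if self.weights_ is None:
            raise ValueError("model is not fitted")
        Path(path).write_text(
            json.dumps(
                {
                    "model": "averaged_perceptron",
                    "config": {
                        "learning_rate": self.config.learning_rate,
                        "max_iterations": self.config.max_iterations,
                        "seed": self.config.seed,
                        "standardize": self.config.standardize,
                    },
                    "weights": self.weights_.tolist(),
                    "mean": self.mean_.tolist(),
                    "sd": self.sd_.tolist(),
                    "n_updates": self.n_updates_,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AveragedPerceptron":
        data = json.loads(Path(path).read_text())
        model = cls(PerceptronConfig(**data["config"]))
        model.weights_ = np.asarray(data["weights"], dtype=float)
        model.mean_ = np.asarray(data["mean"], dtype=float)
        model.sd_ = np.asarray(data["sd"], dtype=float)
        model.n_updates_ = int(data["n_updates"])
        return model


@dataclass(frozen=True, slots=True)
class RUSBoostConfig:
    n_rounds: int = 100
    max_depth: int = 4
    min_samples_leaf: int = 1
    undersample_ratio: float = 1.0  # majority:minority per round
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.undersample_ratio <= 0:
            raise ValueError("undersample_ratio must be > 0")


class RUSBoostClassifier:
    """AdaBoost.M1 with per-round random undersampling of the majority class."""

    def __init__(self, config: RUSBoostConfig | None = None):
        self.config = config or RUSBoostConfig()
        self.trees_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        self.weight_history_: list[np.ndarray] = []  # example-weight distributions

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RUSBoostClassifier":
        X, y = _check_training_inputs(X, y)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = y.size
        yy = np.where(y == 1, 1.0, -1.0)
        minority = int(np.argmin(np.bincount(y, minlength=2)))
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y != minority)

        w = np.full(n, 1.0 / n)
        self.trees_, self.alphas_, self.weight_history_ = [], [], []
        for _ in range(cfg.n_rounds):
            take = min(maj_idx.size, max(1, int(round(cfg.undersample_ratio * min_idx.size))))
            sampled_maj = rng.choice(maj_idx, size=take, replace=False)
            idx = np.concatenate([min_idx, sampled_maj])
            tree = DecisionTreeClassifier(
                max_depth=cfg.max_depth,
                min_samples_leaf=cfg.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            )
            sw = w[idx]
            tree.fit(X[idx], y[idx], sample_weight=sw / sw.sum())
            pred = tree.predict(X)
            err = float(w[(pred != y)].sum())
            err = float(np.clip(err, 1e-10, 1.0 - 1e-10))
            alpha = 0.5 * np.log((1.0 - err) / err)
            self.trees_.append(tree)
            self.alphas_.append(float(alpha))
            pred_pm = np.where(pred == 1, 1.0, -1.0)
            w = w * np.exp(-alpha * yy * pred_pm)
            w /= w.sum()
            self.weight_history_.append(w.copy())
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        score = np.zeros(X.shape[0])
        for tree, alpha in zip(self.trees_, self.alphas_):
            score += alpha * np.where(tree.predict(X) == 1, 1.0, -1.0)
        return score

    def predict(self, X: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        return (self.decision_function(X) > threshold).astype(int)


class SkAdapter:
    """Uniform train/score wrapper around a scikit-learn estimator."""

    def __init__(self, estimator, use_proba: bool = False):
        self.estimator = estimator
        self.use_proba = use_proba

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SkAdapter":
        X, y = _check_training_inputs(X, y)
        self.estimator.fit(X, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.use_proba:
            # centered so that the natural threshold stays at 0
            return self.estimator.predict_proba(X)[:, 1] - 0.5
        return np.asarray(self.estimator.decision_function(X), dtype=float)

    def predict(self, X: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        return (self.decision_function(X) > threshold).astype(int)


def make_model(name: str, seed: int = 0, **params) -> Classifier:
    """Factory for the uniform train/score contract.

    ``name`` is one of perceptron, svm, logistic, forest, rusboost.
    """
    if name == "perceptron":
        return AveragedPerceptron(PerceptronConfig(seed=seed, **params))
    if name == "rusboost":
        return RUSBoostClassifier(RUSBoostConfig(seed=seed, **params))
    if name == "svm":
        est = Pipeline(
            [("scale", StandardScaler()),
             ("svm", LinearSVC(random_state=seed, **params))]
        )
        return SkAdapter(est)
    if name == "logistic":
        est = Pipeline(
            [("scale", StandardScaler()),
             ("logit", LogisticRegression(max_iter=2000, random_state=seed, **params))]
        )
        return SkAdapter(est)
    if name == "forest":
        est = RandomForestClassifier(random_state=seed, **params)
        return SkAdapter(est, use_proba=True)
    raise ValueError(f"unknown model {name!r}")
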