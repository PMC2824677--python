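"""Train and apply overlap classifiers; compute accuracy / FPR / FNR.

Feature vectors x_i per read pair, binary labels y_i (True = real overlap).
Four algorithms are supported: an entropy-split decision tree, a random
forest of 100 such trees, and naive Bayes with either per-class normal
densities or per-class kernel density estimates.  Missing feature values
(NaN; e.g. an undefined comparative score) are first-class: trees route them
through scikit-learn's native missing-value support, and the naive Bayes
variants simply omit the missing feature's likelihood term — a missing score
is deliberately *not* imputed as 0, because 0 means "tie".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

ALGORITHMS = ("decision_tree", "naive_bayes_gaussian", "naive_bayes_kde",
              "random_forest")

#: columns of a feature table that identify the pair rather than describe it
KEY_COLUMNS = ("readA_id", "readB_id", "orientation")
LABEL_COLUMN = "label"


def feature_matrix(features: pd.DataFrame,
                   schema: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Numeric feature matrix and column names from a feature table."""
    cols = [c for c in features.columns if c not in KEY_COLUMNS and c != LABEL_COLUMN]
    if schema is not None:
        missing = [c for c in schema if c not in features.columns]
        extra = [c for c in cols if c not in schema]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing {missing or 'none'}, "
                f"unexpected {extra or 'none'}")
        cols = list(schema)
    X = features[cols].to_numpy(dtype=float)
    return X, cols


class _NaiveBayes:
    """Naive Bayes over continuous features with NaN-tolerant likelihoods."""

    def __init__(self, kde: bool, seed: int, grid_size: int = 512,
                 max_kde_samples: int = 3000):
        self.kde = kde
        self.seed = seed
        self.grid_size = grid_size
        self.max_kde_samples = max_kde_samples

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NaiveBayes":
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.array([False, True])
        self.log_prior_ = np.log(np.array([(y == c).mean() for c in self.classes_]))
        n_feat = X.shape[1]
        if self.kde:
            self.grids_ = [[None] * n_feat for _ in self.classes_]
        else:
            self.mu_ = np.zeros((2, n_feat))
            self.sd_ = np.ones((2, n_feat))
        global_sd = np.nanstd(X, axis=0)
        for ci, c in enumerate(self.classes_):
            Xc = X[y == c]
            for f in range(n_feat):
                vals = Xc[:, f]
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    continue
                sd_floor = max(1e-9, 1e-3 * (global_sd[f] if global_sd[f] > 0 else 1.0))
                if self.kde:
                    if vals.size > self.max_kde_samples:
                        vals = rng.choice(vals, self.max_kde_samples, replace=False)
                    bw = max(1.06 * vals.std() * vals.size ** (-0.2), sd_floor)
                    lo, hi = vals.min() - 4 * bw, vals.max() + 4 * bw
                    grid = np.linspace(lo, hi, self.grid_size)
                    dens = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / bw) ** 2)
                    dens = dens.sum(axis=1) / (vals.size * bw * np.sqrt(2 * np.pi))
                    self.grids_[ci][f] = (grid, np.maximum(dens, 1e-300))
                else:
                    self.mu_[ci, f] = vals.mean()
                    self.sd_[ci, f] = max(vals.std(), sd_floor)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        log_post = np.tile(self.log_prior_, (n, 1))
        for ci in range(2):
            for f in range(X.shape[1]):
                x = X[:, f]
                ok = ~np.isnan(x)
                if self.kde:
                    entry = self.grids_[ci][f]
                    if entry is None:
                        continue
                    grid, dens = entry
                    ll = np.log(np.interp(x[ok], grid, dens, left=1e-300,
                                          right=1e-300))
                else:
                    mu, sd = self.mu_[ci, f], self.sd_[ci, f]
                    ll = (-0.5 * ((x[ok] - mu) / sd) ** 2
                          - np.log(sd * np.sqrt(2 * np.pi)))
                log_post[ok, ci] += ll
        return self.classes_[np.argmax(log_post, axis=1)]


@dataclass
class OverlapClassifier:
    """A trained overlap classification function C: x -> {true, false}."""

    algorithm: str
    estimator: object
    schema: list[str]
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Boolean predictions (True = true overlap), one per table row."""
        if len(features) == 0:
            return np.zeros(0, dtype=bool)
        X, _ = feature_matrix(features, self.schema)
        return np.asarray(self.estimator.predict(X), dtype=bool)


def train(features: pd.DataFrame, labels: Sequence[bool] | np.ndarray,
          algorithm: str = "decision_tree", seed: int = 0,
          **hyperparams) -> OverlapClassifier:
    """Fit a classifier on a labeled feature table.

    Hyperparameter defaults follow common toolkit practice: entropy splits
    with a minimum leaf size of 2 for trees, 100 trees for the forest, and a
    normal-reference bandwidth for the KDE naive Bayes.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(features):
        raise ValueError("labels and features differ in length")
    if y.all() or not y.any():
        raise ValueError("training set contains a single class")
    X, schema = feature_matrix(features)

    if algorithm == "decision_tree":
        est = DecisionTreeClassifier(criterion="entropy",
                                     min_samples_leaf=hyperparams.pop("min_samples_leaf", 2),
                                     random_state=seed, **hyperparams)
        est.fit(X, y)
    elif algorithm == "random_forest":
        est = RandomForestClassifier(n_estimators=hyperparams.pop("n_estimators", 100),
                                     criterion="entropy", random_state=seed,
                                     n_jobs=1, **hyperparams)
        est.fit(X, y)
    else:
        est = _NaiveBayes(kde=(algorithm == "naive_bayes_kde"), seed=seed,
                          **hyperparams).fit(X, y)
    return OverlapClassifier(algorithm, est, schema, seed)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts and the derived rates.

    "Positive" means predicted to be a true overlap.  Accuracy is the
    fraction of correct predictions; the false positive rate divides by the
    actual false overlaps and the false negative rate by the actual true
    overlaps.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_true(self) -> int:
        return self.tp + self.fn

    @property
    def n_false(self) -> int:
        return self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def false_positive_rate(self) -> float:
        return self.fp / self.n_false if self.n_false else 0.0

    @property
    def false_negative_rate(self) -> float:
        return self.fn / self.n_true if self.n_true else 0.0

    def summary(self) -> str:
        return (f"n={self.n} (true={self.n_true}, false={self.n_false})\n"
                f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}\n"
                f"accuracy={self.accuracy:.4f} "
                f"FPR={self.false_positive_rate:.4f} "
                f"FNR={self.false_negative_rate:.4f}")


def evaluate(predicted: Sequence[bool] | np.ndarray,
             actual: Sequence[bool] | np.ndarray) -> ClassificationMetrics:
    """Confusion counts of predicted vs actual labels (True = true overlap)."""
    pred = np.asarray(predicted, dtype=bool)
    act = np.asarray(actual, dtype=bool)
    if pred.shape != act.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {act.shape}")
    if pred.size == 0:
        raise ValueError("cannot evaluate empty label lists")
    return ClassificationMetrics(
        tp=int((pred & act).sum()),
        fp=int((pred & ~act).sum()),
        tn=int((~pred & ~act).sum()),
        fn=int((~pred & act).sum()),
    )
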