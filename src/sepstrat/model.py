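"""Shared model containers: fitted gene signatures and cross-validation reports.

A :class:`SignatureModel` stores per-class linear weights on the *original*
log2-expression scale, so a stored model can be applied to new cohorts
without access to the training data. Binary models are represented as the
two-class special case (softmax over two rows equals the logistic sigmoid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio

__all__ = ["SignatureModel", "CVReport", "SklearnOnGenes"]


@dataclass
class SignatureModel:
    name: str
    genes: list[str]
    classes: list[str]
    weights: np.ndarray  # (n_classes, n_genes), original log2-expression scale
    intercepts: np.ndarray  # (n_classes,)
    training: dict = field(default_factory=dict)  # comparison, penalty, folds, seed, ...

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(len(self.classes), len(self.genes))
        self.intercepts = np.asarray(self.intercepts, dtype=float).reshape(len(self.classes))

    def _design(self, expr: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise KeyError(f"expression matrix is missing model genes: {missing}")
        x = expr.loc[self.genes].to_numpy(dtype=float).T
        if not np.isfinite(x).all():
            raise ValueError("non-finite expression values")
        return x

    def decision(self, expr: pd.DataFrame) -> pd.DataFrame:
        x = self._design(expr)
        scores = x @ self.weights.T + self.intercepts
        return pd.DataFrame(scores, index=expr.columns, columns=self.classes)

    def predict_proba(self, expr: pd.DataFrame) -> pd.DataFrame:
        scores = self.decision(expr).to_numpy()
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return pd.DataFrame(e / e.sum(axis=1, keepdims=True), index=expr.columns, columns=self.classes)

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(expr)
        labels = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
        return pd.Series(labels, index=proba.index, name="predicted")

    def to_json(self, path: str | Path) -> Path:
        return sio.write_json(
            {
                "name": self.name,
                "genes": self.genes,
                "classes": self.classes,
                "weights": self.weights.tolist(),
                "intercepts": self.intercepts.tolist(),
                "training": self.training,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = sio.read_json(path)
        return cls(
            name=d["name"],
            genes=d["genes"],
            classes=d["classes"],
            weights=np.asarray(d["weights"]),
            intercepts=np.asarray(d["intercepts"]),
            training=d.get("training", {}),
        )


class SklearnOnGenes:
    """Adapter exposing the package prediction protocol over an sklearn
    estimator restricted to a fixed gene set (optionally standardized with
    training-fold statistics)."""

    def __init__(self, genes: list[str], estimator, standardize: bool = False):
        self.genes = list(genes)
        self.estimator = estimator
        self.standardize = standardize
        self._mu = None
        self._sd = None

    def _design(self, expr: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise KeyError(f"expression matrix is missing genes: {missing}")
        x = expr.loc[self.genes].to_numpy(dtype=float).T
        if self._mu is not None:
            x = (x - self._mu) / self._sd
        return x

    def fit(self, expr: pd.DataFrame, labels) -> "SklearnOnGenes":
        x = expr.loc[self.genes].to_numpy(dtype=float).T
        if self.standardize:
            self._mu = x.mean(axis=0)
            self._sd = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
            x = (x - self._mu) / self._sd
        self.estimator.fit(x, np.asarray(labels))
        return self

    @property
    def classes(self) -> list:
        return list(self.estimator.classes_)

    def predict_proba(self, expr: pd.DataFrame) -> pd.DataFrame:
        proba = self.estimator.predict_proba(self._design(expr))
        return pd.DataFrame(proba, index=expr.columns, columns=self.classes)

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(expr)
        labels = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
        return pd.Series(labels, index=proba.index, name="predicted")


@dataclass
class CVReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: pd.DataFrame  # one row per fold x repeat
    folds: int
    repeats: int
    seed: int

    def __post_init__(self) -> None:
        for m in (self.auc, self.accuracy, self.sensitivity, self.specificity):
            if not 0.0 <= m <= 1.0:
                raise ValueError("CV metrics must lie in [0, 1]")
        if len(self.per_fold) != self.folds * self.repeats:
            raise ValueError("per-fold rows must equal folds x repeats")

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
        }
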