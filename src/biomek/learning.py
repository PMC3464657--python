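"""One-vs-rest linear max-margin classification.

One binary L2-regularised squared-hinge linear model is trained per legal
value of a dimension.  Positive examples of each class carry a cost factor
equal to the negative:positive example ratio of that class (negatives keep
factor 1), counteracting the class imbalance inherent in one-vs-rest.
Prediction returns the argmax decision score even when every score is
negative, so every instance receives a label; ties break on the fixed value
order of the dimension (default value first).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

NEG_SENTINEL = float("-inf")


@dataclass
class TrainingConfig:
    C: float = 1.0  # regularisation for negative examples
    use_bias_factors: bool = True
    tol: float = 1e-4
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


def compute_bias_factors(label_counts: Mapping[str, int]) -> dict[str, float]:
    """Per-class positive cost factor = negatives / positives for the class.

    Classes with zero positives are skipped (no model can be trained for
    them); the caller warns and predicts them always-negative.
    """
    total = sum(label_counts.values())
    factors: dict[str, float] = {}
    for label, positives in label_counts.items():
        if positives <= 0:
            continue
        factors[label] = (total - positives) / positives
    return factors


@dataclass
class BinaryModel:
    """Sparse weight vector + intercept; constant models cover the
    single-class degenerate cases."""

    coef: sparse.csr_matrix | None
    intercept: float
    constant_score: float | None = None  # set for degenerate models

    def decision(self, X: sparse.csr_matrix) -> np.ndarray:
        if self.constant_score is not None:
            return np.full(X.shape[0], self.constant_score)
        return np.asarray((X @ self.coef.T).todense()).ravel() + self.intercept


@dataclass
class ModelSet:
    """Per-value binary models of one dimension plus training metadata."""

    dimension: str
    value_order: tuple[str, ...]
    models: dict[str, BinaryModel] = field(default_factory=dict)
    config: TrainingConfig = field(default_factory=TrainingConfig)
    bias_factors: dict[str, float] = field(default_factory=dict)

    def scores(self, X: sparse.csr_matrix) -> dict[str, np.ndarray]:
        out = {}
        for value in self.value_order:
            model = self.models.get(value)
            if model is None:
                out[value] = np.full(X.shape[0], NEG_SENTINEL)
            else:
                out[value] = model.decision(X)
        return out


def train_ovr(
    X: sparse.csr_matrix,
    labels: Sequence[str],
    dimension: str,
    value_order: Sequence[str],
    config: TrainingConfig | None = None,
) -> ModelSet:
    """Train one binary model per value of ``dimension``.

    Values absent from the training labels get no model (warned) and are
    never predicted; a value covering every instance gets a constant
    positive model.
    """
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if len(labels) != X.shape[0]:
        raise ValueError("labels/instances length mismatch")
    config = config or TrainingConfig()
    labels = list(labels)
    counts = {v: labels.count(v) for v in value_order}
    factors = compute_bias_factors(counts) if config.use_bias_factors else {
        v: 1.0 for v, c in counts.items() if c > 0
    }
    model_set = ModelSet(
        dimension=dimension,
        value_order=tuple(value_order),
        config=config,
        bias_factors=dict(factors),
    )
    y_all = np.asarray(labels)
    for value in value_order:
        positives = counts.get(value, 0)
        if positives == 0:
            logger.warning("%s: no positive examples for %r; value unlearnable", dimension, value)
            continue
        if positives == len(labels):
            model_set.models[value] = BinaryModel(coef=None, intercept=0.0, constant_score=1.0)
            continue
        y = (y_all == value).astype(int)
        clf = LinearSVC(
            C=config.C,
            loss="squared_hinge",
            penalty="l2",
            dual=True,
            tol=config.tol,
            max_iter=config.max_iter,
            fit_intercept=True,
            intercept_scaling=1.0,
            class_weight={0: 1.0, 1: factors[value]},
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # occasional ConvergenceWarning
            clf.fit(X, y)
        model_set.models[value] = BinaryModel(
            coef=sparse.csr_matrix(clf.coef_), intercept=float(clf.intercept_[0])
        )
    if not model_set.models:
        raise ValueError(f"{dimension}: no trainable value")
    return model_set


def train_ovr_multilabel(
    X: sparse.csr_matrix,
    label_sets: Sequence[set[str]],
    dimension: str,
    value_order: Sequence[str],
    config: TrainingConfig | None = None,
) -> ModelSet:
    """One-vs-rest training where each instance may carry several labels
    (used for token-level cue classes)."""
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if len(label_sets) != X.shape[0]:
        raise ValueError("labels/instances length mismatch")
    config = config or TrainingConfig()
    n = X.shape[0]
    counts = {v: sum(1 for s in label_sets if v in s) for v in value_order}
    model_set = ModelSet(
        dimension=dimension, value_order=tuple(value_order), config=config
    )
    for value in value_order:
        positives = counts[value]
        if positives == 0:
            logger.warning("%s: no positive examples for %r; value unlearnable", dimension, value)
            continue
        if positives == n:
            model_set.models[value] = BinaryModel(coef=None, intercept=0.0, constant_score=1.0)
            continue
        factor = (n - positives) / positives if config.use_bias_factors else 1.0
        model_set.bias_factors[value] = factor
        y = np.asarray([1 if value in s else 0 for s in label_sets])
        clf = LinearSVC(
            C=config.C,
            loss="squared_hinge",
            penalty="l2",
            dual=True,
            tol=config.tol,
            max_iter=config.max_iter,
            fit_intercept=True,
            intercept_scaling=1.0,
            class_weight={0: 1.0, 1: factor},
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        model_set.models[value] = BinaryModel(
            coef=sparse.csr_matrix(clf.coef_), intercept=float(clf.intercept_[0])
        )
    if not model_set.models:
        raise ValueError(f"{dimension}: no trainable value")
    return model_set


def _argmax_label(model_set: ModelSet, score_row: Mapping[str, float]) -> str:
    best_value, best_score = None, None
    for value in model_set.value_order:  # fixed order => deterministic ties
        s = score_row[value]
        if best_score is None or s > best_score:
            best_value, best_score = value, s
    return best_value


def predict_single_label(model_set: ModelSet, X: sparse.csr_matrix) -> list[str]:
    """Argmax decision score per instance; always yields a label."""
    scores = model_set.scores(X)
    out = []
    for i in range(X.shape[0]):
        out.append(_argmax_label(model_set, {v: s[i] for v, s in scores.items()}))
    return out


def predict_multi_label(model_set: ModelSet, X: sparse.csr_matrix) -> list[set[str]]:
    """Labels with positive score plus the argmax label (never empty)."""
    scores = model_set.scores(X)
    out = []
    for i in range(X.shape[0]):
        row = {v: s[i] for v, s in scores.items()}
        chosen = {v for v, s in row.items() if s > 0}
        chosen.add(_argmax_label(model_set, row))
        out.append(chosen)
    return out
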