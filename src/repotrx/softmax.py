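"""Multi-label softmax regression with thresholded classification.

The model is a single softmax layer over the landmark-gene Z-scores:
``p(class j | x) = exp(theta_j . x) / sum_l exp(theta_l . x)`` with theta a
q x (n+1) matrix whose last column is the bias unit. Multi-label targets
are the label rows normalised to sum to 1, the loss is mean cross-entropy
plus an L2 structural-risk term ``lambda * ||W||_F^2`` on the non-bias
weights, and optimisation is seeded mini-batch gradient descent from a
zero initialisation (the objective is convex, so the start point affects
only the trajectory).

Classification is by probability threshold, not argmax: ``CF_ij = 1`` iff
``p_ij >= threshold``. A sample counts as correctly predicted when at
least one of its true labels is called positive; training and validation
accuracy are the fraction of correctly predicted samples in their folds,
evaluated at the training (0.30) and validation (0.06) thresholds
respectively. The repositioning probability matrix is the elementwise mean
of the full-data probabilities over the final ``averaging_window`` epochs,
then averaged per drug over that drug's credible-set samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrainingHistory",
    "make_label_matrix",
    "normalize_targets",
    "softmax_probabilities",
    "objective",
    "gradient",
    "train",
    "predict_classification",
    "confusion_counts",
    "sample_accuracy",
    "confusion_matrix",
    "k_fold_split",
    "averaged_probability_matrix",
]

_LOG_FLOOR = 1e-300  # clamp for log(p) only; finite results are unaffected


def make_label_matrix(
    sample_drugs: list[str], labels: dict[str, set[str]], classes: list[str]
) -> np.ndarray:
    """Binary m x q label matrix for samples, from their drugs' label sets."""
    index = {c: j for j, c in enumerate(classes)}
    lb = np.zeros((len(sample_drugs), len(classes)), dtype=float)
    for i, drug in enumerate(sample_drugs):
        if drug not in labels:
            raise ValueError(f"drug {drug!r} missing from label table")
        for c in labels[drug]:
            lb[i, index[c]] = 1.0
    return lb


def normalize_targets(lb: np.ndarray) -> np.ndarray:
    """Row-normalise a binary label matrix into a distribution per sample."""
    lb = np.asarray(lb, dtype=float)
    sums = lb.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        bad = np.flatnonzero(sums[:, 0] == 0)
        raise ValueError(f"label matrix has all-zero rows at {bad[:5].tolist()}")
    return lb / sums


def _augment(x: np.ndarray) -> np.ndarray:
    """Append the bias input 1 as the last feature column."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.hstack([x, np.ones((x.shape[0], 1))])


def softmax_probabilities(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class probabilities for samples ``x`` (m x n, bias added internally).

    Computed with max-logit subtraction for numerical stability; returns an
    m x q row-stochastic matrix (1-d input gives a 1 x q matrix).
    """
    logits = _augment(x) @ np.asarray(theta, dtype=float).T
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in softmax")
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _penalty(theta: np.ndarray) -> float:
    return float(np.sum(theta[:, :-1] ** 2))  # bias column excluded


def objective(theta: np.ndarray, dm: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Mean cross-entropy over samples plus ``lam * ||W||_F^2`` (no bias)."""
    p = softmax_probabilities(theta, dm)
    m = p.shape[0]
    ce = -float(np.sum(y * np.log(np.maximum(p, _LOG_FLOOR)))) / m
    return ce + lam * _penalty(theta)


def gradient(theta: np.ndarray, batch: np.ndarray, y_batch: np.ndarray, lam: float) -> np.ndarray:
    """Analytic gradient of :func:`objective` restricted to one batch."""
    batch = np.atleast_2d(batch)
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    xa = _augment(batch)
    p = softmax_probabilities(theta, batch)
    g = (p - y_batch).T @ xa / batch.shape[0]
    reg = 2.0 * lam * np.asarray(theta, dtype=float)
    reg[:, -1] = 0.0
    return g + reg


def predict_classification(theta: np.ndarray, dm: np.ndarray, threshold: float) -> np.ndarray:
    """Binary classification matrix: ``CF_ij = 1`` iff ``p_ij >= threshold``."""
    if not 0.0 <= threshold <= 1.0:
        # thresholds above 1 are allowed to yield the empty classification
        pass
    p = softmax_probabilities(theta, dm)
    return (p >= threshold).astype(float)


def confusion_counts(lb: np.ndarray, cf: np.ndarray) -> dict[str, np.ndarray]:
    """Per-label TP/TN/FP/FN counts; each quadruple sums to the sample count."""
    lb = np.asarray(lb)
    cf = np.asarray(cf)
    if lb.shape != cf.shape:
        raise ValueError(f"shape mismatch {lb.shape} vs {cf.shape}")
    tp = np.sum((lb == 1) & (cf == 1), axis=0)
    tn = np.sum((lb == 0) & (cf == 0), axis=0)
    fp = np.sum((lb == 0) & (cf == 1), axis=0)
    fn = np.sum((lb == 1) & (cf == 0), axis=0)
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def sample_accuracy(lb: np.ndarray, cf: np.ndarray) -> float:
    """Fraction of samples with at least one true-positive label call."""
    lb = np.asarray(lb)
    cf = np.asarray(cf)
    if lb.shape != cf.shape:
        raise ValueError(f"shape mismatch {lb.shape} vs {cf.shape}")
    if lb.shape[0] == 0:
        return float("nan")
    correct = np.any((lb == 1) & (cf == 1), axis=1)
    return float(correct.mean())


def confusion_matrix(lb: np.ndarray, predicted_argmax: np.ndarray) -> np.ndarray:
    """q x q confusion counts: rows = actual class, columns = predicted.

    Multi-label samples contribute one (actual, predicted) pair per actual
    label, so row sums equal actual-label instance counts.
    """
    lb = np.asarray(lb)
    pred = np.asarray(predicted_argmax, dtype=int)
    q = lb.shape[1]
    counts = np.zeros((q, q), dtype=int)
    for i in range(lb.shape[0]):
        for j in np.flatnonzero(lb[i] == 1):
            counts[j, pred[i]] += 1
    return counts


def k_fold_split(
    drugs: list[str], k: int, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Partition *drugs* (not samples) into k train/validation folds.

    All replicate trials of a drug stay on one side of every split, and
    each drug validates exactly once.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(drugs):
        raise ValueError(f"k={k} exceeds the number of drugs ({len(drugs)})")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(drugs, dtype=object)[rng.permutation(len(drugs))])
    folds = [list(f) for f in np.array_split(np.array(shuffled, dtype=object), k)]
    splits = []
    for i in range(k):
        val = folds[i]
        train_drugs = [d for j, f in enumerate(folds) if j != i for d in f]
        splits.append((train_drugs, val))
    return splits


@dataclass
class TrainingHistory:
    """Per-epoch training record, including the probability matrices of the
    final averaging window."""

    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    window_probabilities: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def train(
    dm: np.ndarray,
    lb: np.ndarray,
    *,
    learning_rate: float = 0.06,
    lam: float = 1.0,
    batch_size: int = 32,
    iterations: int = 200,
    averaging_window: int = 100,
    training_threshold: float = 0.30,
    validation_threshold: float = 0.06,
    seed: int = 0,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, TrainingHistory]:
    """Train by mini-batch gradient descent; one iteration = one epoch.

    Returns the fitted q x (n+1) parameter matrix and the per-epoch
    history. Within the final ``averaging_window`` epochs the full-data
    probability matrix is recorded for downstream averaging. Raises
    ``RuntimeError`` if the loss becomes non-finite.
    """
    dm = np.atleast_2d(np.asarray(dm, dtype=float))
    m, n = dm.shape
    q = lb.shape[1]
    if batch_size > m:
        batch_size = m
    y = normalize_targets(lb)
    theta = np.zeros((q, n + 1))
    history = TrainingHistory()
    rng = np.random.default_rng(seed)
    for epoch in range(iterations):
        perm = rng.permutation(m)
        for start in range(0, m, batch_size):
            idx = perm[start : start + batch_size]
            theta -= learning_rate * gradient(theta, dm[idx], y[idx], lam)
        p = softmax_probabilities(theta, dm)
        loss = -float(np.sum(y * np.log(np.maximum(p, _LOG_FLOOR)))) / m + lam * _penalty(theta)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={loss}, "
                f"max|theta|={np.abs(theta).max():.3g}"
            )
        history.loss.append(loss)
        cf = (p >= training_threshold).astype(float)
        history.train_accuracy.append(sample_accuracy(lb, cf))
        if val is not None:
            vdm, vlb = val
            vcf = predict_classification(theta, vdm, validation_threshold)
            history.val_accuracy.append(sample_accuracy(vlb, vcf))
        if epoch >= iterations - averaging_window:
            history.window_probabilities.append(p)
    return theta, history


def averaged_probability_matrix(
    window_probabilities: list[np.ndarray],
    sample_drugs: list[str],
    classes: list[str],
) -> pd.DataFrame:
    """Drugs x classes repositioning-probability matrix.

    Elementwise mean of the recorded per-epoch probability matrices, then
    averaged per drug over that drug's samples. Rows remain stochastic
    (means of row-stochastic matrices).
    """
    if not window_probabilities:
        raise ValueError("empty averaging window")
    mean_p = np.mean(np.stack(window_probabilities), axis=0)
    df = pd.DataFrame(mean_p, columns=classes)
    df["__drug"] = sample_drugs
    seen: dict[str, None] = {}
    for d in sample_drugs:
        seen.setdefault(d, None)
    out = df.groupby("__drug", sort=False).mean()
    out.index.name = "drug"
    return out.loc[list(seen)]
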