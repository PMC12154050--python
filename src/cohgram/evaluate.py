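"""Training, evaluation and subject-wise cross-validation.

The evaluation protocol is leakage-free by construction: folds are
assigned at the subject level (see :mod:`cohgram.split`) and a hard
assertion re-checks on every fold that no subject contributes segments
to both the training and the test partition.  The coherence transform
has no fitted parameters, so per-fold preprocessing independence holds
structurally.

Metrics follow the standard multi-class classification report: overall
accuracy, per-class precision/recall/F1/support, the confusion matrix,
and one-vs-rest ROC AUC from the softmax scores (NaN for a class absent
from the test set).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support as _sk_prfs,
    roc_auc_score as _sk_auc,
)

from .errors import ConfigurationError, ContractError
from .models import ModelSpec, build_model, prepare_batch
from .nn import Adam, Sequential, softmax, softmax_cross_entropy
from .split import SplitPlan

__all__ = [
    "TrainConfig", "EvalReport", "train", "evaluate",
    "subject_wise_cv", "assert_no_leakage",
]


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.1  # subject-wise holdout from the training fold

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ConfigurationError("learning_rate must be positive")
        if not 0 <= self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in [0, 1)")


@dataclasses.dataclass
class EvalReport:
    """Table-style classification report for one evaluation."""

    classes: list[str]
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    confusion: np.ndarray
    roc_auc: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "confusion_matrix": self.confusion.tolist(),
            "roc_auc": self.roc_auc.tolist(),
        }


def _one_hot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y_idx.size, n_classes))
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


def _encode(labels: Sequence[str], classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels], dtype=np.int64)


def train(
    model: Sequential,
    images: np.ndarray,
    labels: Sequence[str],
    cfg: TrainConfig,
    spec: ModelSpec,
    val_images: np.ndarray | None = None,
    val_labels: Sequence[str] | None = None,
    classes: list[str] | None = None,
) -> dict[str, list[float]]:
    """Train a model in place; returns the per-epoch history.

    History keys: ``loss``, ``accuracy`` and, when validation data is
    supplied, ``val_loss`` and ``val_accuracy``.  Deterministic given
    ``cfg.seed`` (pure NumPy backend).
    """
    classes = classes or sorted(set(labels))
    if len(set(labels)) < 2:
        raise ConfigurationError("training set contains a single class")
    x = prepare_batch(images, spec)
    y = _encode(labels, classes)
    onehot = _one_hot(y, spec.n_classes)
    has_val = val_images is not None and len(val_images) > 0
    if has_val:
        xv = prepare_batch(val_images, spec)
        yv = _encode(val_labels, classes)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if has_val:
        history["val_loss"] = []
        history["val_accuracy"] = []
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, onehot[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * idx.size
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        if has_val:
            vlogits = model.forward(xv, training=False)
            vloss, _ = softmax_cross_entropy(vlogits, _one_hot(yv, spec.n_classes))
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(
                float((vlogits.argmax(axis=1) == yv).mean()))
    return history


def predict_proba(model: Sequential, images: np.ndarray,
                  spec: ModelSpec) -> np.ndarray:
    return softmax(model.forward(prepare_batch(images, spec), training=False))


def evaluate(
    model: Sequential,
    images: np.ndarray,
    labels: Sequence[str],
    spec: ModelSpec,
    classes: list[str] | None = None,
) -> EvalReport:
    """Classification report on a test set.

    One-vs-rest ROC AUC is NaN for any class absent from the test set
    (undefined, not an error).
    """
    if len(labels) == 0:
        raise ConfigurationError("empty test set")
    classes = classes or sorted(set(labels))
    y = _encode(labels, classes)
    probs = predict_proba(model, images, spec)
    pred = probs.argmax(axis=1)
    all_idx = np.arange(len(classes))
    precision, recall, f1, support = _sk_prfs(
        y, pred, labels=all_idx, zero_division=0)
    confusion = _sk_confusion(y, pred, labels=all_idx)
    auc = np.full(len(classes), np.nan)
    for i in all_idx:
        pos = y == i
        if pos.any() and (~pos).any():
            auc[i] = _sk_auc(pos.astype(int), probs[:, i])
    return EvalReport(
        classes=list(classes),
        accuracy=float((pred == y).mean()),
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        confusion=confusion,
        roc_auc=auc,
    )


def assert_no_leakage(
    train_subjects: Sequence[str], test_subjects: Sequence[str]
) -> None:
    """Hard guarantee that no subject spans train and test."""
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise ContractError(
            f"subject leakage between train and test: {sorted(overlap)}"
        )


def subject_wise_cv(
    images: np.ndarray,
    labels: Sequence[str],
    subjects: Sequence[str],
    plan: SplitPlan,
    spec: ModelSpec,
    cfg: TrainConfig,
) -> tuple[list[EvalReport], dict[str, float]]:
    """Subject-wise k-fold cross-validation.

    For each fold: train a fresh model on the segments of the other
    folds' subjects (with an optional subject-wise validation holdout),
    evaluate on the held-out fold's segments.  Returns per-fold reports
    and the aggregate mean/sd of fold accuracies.
    """
    labels = np.asarray(labels, dtype=object)
    subjects = np.asarray(subjects, dtype=object)
    known = set(plan.assignment)
    missing = sorted(set(subjects) - known)
    if missing:
        raise ConfigurationError(f"subjects not in SplitPlan: {missing}")
    classes = sorted(set(labels))
    if len(classes) != spec.n_classes:
        raise ConfigurationError(
            f"dataset has {len(classes)} classes but spec.n_classes="
            f"{spec.n_classes}"
        )
    reports: list[EvalReport] = []
    for fold in range(plan.k):
        train_subj, test_subj = plan.train_test_subjects(fold)
        assert_no_leakage(train_subj, test_subj)
        tr = np.isin(subjects, sorted(train_subj))
        te = np.isin(subjects, sorted(test_subj))
        assert_no_leakage(subjects[tr], subjects[te])

        val_mask = np.zeros_like(tr)
        if cfg.val_fraction > 0:
            rng = np.random.default_rng(cfg.seed + 7919 * fold)
            pool = sorted(set(subjects[tr]))
            n_val = max(1, int(round(cfg.val_fraction * len(pool))))
            # keep at least one training subject per class
            n_val = min(n_val, len(pool) - len(classes))
            if n_val > 0:
                val_subj = set(rng.choice(pool, size=n_val, replace=False))
                val_mask = np.isin(subjects, sorted(val_subj)) & tr
                tr = tr & ~val_mask

        model = build_model(spec, seed=cfg.seed + fold)
        train(
            model, images[tr], labels[tr], cfg, spec,
            val_images=images[val_mask] if val_mask.any() else None,
            val_labels=labels[val_mask] if val_mask.any() else None,
            classes=classes,
        )
        reports.append(evaluate(model, images[te], labels[te], spec,
                                classes=classes))
    accs = np.array([r.accuracy for r in reports])
    aggregate = {
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
    }
    return reports, aggregate
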