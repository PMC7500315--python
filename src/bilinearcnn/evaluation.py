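"""Accuracy, ROC/AUC, throughput and 2-D feature embeddings.

Accuracy is the fraction of correctly classified samples; the confusion
matrix and per-class accuracies are reported alongside.  ROC curves are
one-vs-rest per class with trapezoidal AUC and a macro average (classes
absent from the test labels get a missing AUC, never a propagated NaN).
Frames-per-second is wall-clock single-image throughput — hardware
dependent and informational only.  t-SNE embeds the pre-softmax features
(the last layer's activations) into 2-D for cluster inspection.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve

__all__ = [
    "EvaluationReport",
    "EmbeddingResult",
    "evaluate",
    "roc_curves",
    "extract_embedding_features",
    "tsne_embed",
    "measure_fps",
]


@dataclass
class EvaluationReport:
    accuracy: float
    per_class_accuracy: dict
    confusion: np.ndarray
    class_names: list
    roc: dict
    auc: dict
    fps: float | None = None

    def to_json(self, path) -> None:
        doc = {
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": np.asarray(self.confusion).tolist(),
            "class_names": [str(c) for c in self.class_names],
            "auc": {str(k): v for k, v in self.auc.items()},
            "roc": {
                str(k): {"fpr": f.tolist(), "tpr": t.tolist()}
                for k, (f, t) in self.roc.items()
            },
            "fps": self.fps,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    labels: np.ndarray
    seed: int


def evaluate(estimator, X, y) -> EvaluationReport:
    """Score a fitted classifier on labeled images.

    Deterministic given the model and data; the confusion matrix, overall
    accuracy and per-class accuracies are consistent by construction
    (accuracy = trace / total).
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("no records to evaluate")
    classes = list(estimator.classes_)
    unknown = set(np.unique(y)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the model's class set: {unknown}")
    scores = estimator.predict_proba(X)
    pred = np.asarray(classes, dtype=y.dtype)[scores.argmax(axis=1)]
    cm = confusion_matrix(y, pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    per_class = {}
    for i, c in enumerate(classes):
        row = cm[i].sum()
        per_class[c] = float(cm[i, i] / row) if row else float("nan")
    roc, aucs = roc_curves(scores, y, class_names=classes)
    return EvaluationReport(accuracy=accuracy, per_class_accuracy=per_class,
                            confusion=cm, class_names=classes, roc=roc,
                            auc=aucs)


def roc_curves(scores: np.ndarray, labels, class_names=None):
    """One-vs-rest ROC per class plus trapezoidal AUCs.

    Returns ``(roc, auc)`` where ``roc[class] = (fpr, tpr)`` and ``auc``
    maps each class (and ``"macro"``) to a float.  A class with only one
    label value present has an undefined AUC, reported as ``None`` and
    excluded from the macro average.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    row_sums = scores.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-3):
        raise ValueError("score rows must sum to ~1 (probabilities)")
    if class_names is None:
        class_names = list(np.unique(labels))
    if len(class_names) != scores.shape[1]:
        raise ValueError("one score column per class required")
    roc: dict = {}
    aucs: dict = {}
    defined = []
    for j, c in enumerate(class_names):
        binary = (labels == c).astype(int)
        if binary.min() == binary.max():
            aucs[c] = None
            continue
        fpr, tpr, _ = roc_curve(binary, scores[:, j])
        roc[c] = (fpr, tpr)
        aucs[c] = float(_trapezoid_auc(fpr, tpr))
        defined.append(aucs[c])
    aucs["macro"] = float(np.mean(defined)) if defined else None
    return roc, aucs


def extract_embedding_features(estimator, X) -> np.ndarray:
    """Pre-softmax activations per image, in input order (n x K)."""
    return estimator.decision_function(X)


def tsne_embed(features: np.ndarray, seed: int = 0,
               perplexity: float = 30.0) -> EmbeddingResult:
    """Seeded 2-D t-SNE of a feature matrix.

    The perplexity is capped at ``(n - 1) / 3`` (t-SNE requires
    ``n > 3 * perplexity``); fewer than 8 samples is an error.
    """
    features = np.asarray(features, dtype=float)
    n = len(features)
    if n < 8:
        raise ValueError(f"too few samples for t-SNE: {n}")
    perplexity = min(float(perplexity), (n - 1) / 3)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    coords = tsne.fit_transform(features)
    return EmbeddingResult(coords=coords, labels=np.arange(n), seed=seed)


def measure_fps(net, n_frames: int = 30, input_size: int = 64,
                n_trials: int = 5, warmup: int = 10) -> float:
    """Single-image forward-pass throughput (frames per second).

    Protocol: batch size 1, ``warmup`` untimed frames, then the median
    over ``n_trials`` timed runs of ``n_frames`` frames each.  The result
    depends on the hardware and is informational only.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    net = getattr(net, "net_", net)
    frame = np.zeros((1, 3, input_size, input_size))
    for _ in range(warmup):
        net.forward(frame, train=False)
    rates = []
    for _ in range(n_trials):
        t0 = time.perf_counter()
        for _ in range(n_frames):
            net.forward(frame, train=False)
        rates.append(n_frames / (time.perf_counter() - t0))
    return float(np.median(rates))
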