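"""SGD training protocol and the cross-validation driver.

The protocol: mini-batch SGD (initial learning rate 0.1, batch size 16) on
categorical cross-entropy over softmax outputs; when the training loss has
not decreased for ``lr_patience_epochs`` consecutive epochs, the learning
rate is multiplied by ``lr_factor`` (a tenfold reduction by default).
Training stops at ``max_epochs`` or once the rate falls below ``min_lr``.
Evaluation uses k-fold cross-validation (k = 5): the model is trained from
a fresh initialization on k-1 folds — with oversampling applied inside the
training split only — and tested on the held-out fold; the fold accuracies
are averaged.

Everything is seeded: two runs with the same config and data produce
identical histories on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import AugmentParams, DatasetManifest, augment, load_images, \
    make_folds, oversample
from .models import BackboneSpec, BackboneUnavailableError
from .nn import SGD, update_bn_statistics

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "CVResult",
    "fit_network",
    "train_model",
    "cross_validate",
    "load_pretrained",
]


@dataclass
class TrainConfig:
    """The training protocol as explicit, serializable fields."""

    optimizer: str = "sgd"
    initial_lr: float = 0.1
    batch_size: int = 16
    lr_factor: float = 0.1
    lr_patience_epochs: int = 10
    max_epochs: int = 100
    min_lr: float = 1e-5
    momentum: float = 0.0
    seed: int = 0
    pretrained: bool = False
    image_size: int = 64

    def __post_init__(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError("only SGD is supported")
        if not (0.0 < self.lr_factor < 1.0):
            raise ValueError("lr_factor must be in (0, 1)")
        if self.lr_patience_epochs < 1:
            raise ValueError("lr_patience_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc.pop("backbone", None)
        return cls(**doc)


@dataclass
class TrainHistory:
    """Per-epoch training loss, validation accuracy and learning rate."""

    train_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class CVResult:
    """Fold accuracies of one cross-validation run."""

    fold_accuracy: list
    mean_accuracy: float
    std_error: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _to_nchw(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4:
        raise ValueError(f"expected a 4-D image batch; got shape {X.shape}")
    if X.shape[-1] == 3 and X.shape[1] != 3:
        return np.ascontiguousarray(X.transpose(0, 3, 1, 2))
    if X.shape[1] == 3:
        return X
    raise ValueError(f"cannot identify channel axis in shape {X.shape}")


def _batch_predict(net, X_nchw: np.ndarray, batch_size: int = 64):
    out = []
    for i in range(0, len(X_nchw), batch_size):
        out.append(net.predict_proba(X_nchw[i : i + batch_size]))
    return np.concatenate(out)


def fit_network(net, X, y, config: TrainConfig, X_val=None, y_val=None,
                augment_params: AugmentParams | None = None) -> TrainHistory:
    """Run the SGD + plateau-decay loop on in-memory images.

    ``X`` is ``(N, H, W, 3)`` (or channels-first) in [0, 1]; ``y`` integer
    class indices.  Augmentation, when given, is redrawn per epoch from
    the run's seeded generator.  Raises on an empty training set or a
    non-finite loss.
    """
    X = _to_nchw(X)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValueError("empty training set")
    if X_val is not None:
        X_val = _to_nchw(X_val)
        y_val = np.asarray(y_val, dtype=int)
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(net.params(), lr=config.initial_lr,
                    momentum=config.momentum)
    history = TrainHistory()
    best_loss = np.inf
    stall = 0
    lr = config.initial_lr
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            if augment_params is not None:
                xb = np.stack(
                    [augment(im.transpose(1, 2, 0), augment_params, rng)
                     .transpose(2, 0, 1) for im in xb]
                )
            optimizer.zero_grad()
            loss = net.loss_and_grad(xb, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            optimizer.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= len(order)
        val_acc = np.nan
        if X_val is not None and len(X_val):
            pred = _batch_predict(net, X_val).argmax(axis=1)
            val_acc = float((pred == y_val).mean())
        history.train_loss.append(float(epoch_loss))
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        # Plateau schedule: decay when the loss has not improved for
        # `patience` consecutive epochs.
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience_epochs:
                lr *= config.lr_factor
                optimizer.lr = lr
                stall = 0
                if lr < config.min_lr:
                    break
    # Align eval-mode normalization statistics with the final weights.
    update_bn_statistics(net, X)
    return history


def train_model(model, train_records: pd.DataFrame,
                val_records: pd.DataFrame | None, config: TrainConfig,
                label_column: str, class_names: list[str],
                augment_params: AugmentParams | None = None):
    """Train a network on manifest records (paths + labels).

    ``class_names`` fixes the label -> index mapping so that folds of a
    cross-validation share one encoding.  Train and validation records
    must be disjoint by path.  Returns ``(model, TrainHistory)``.
    """
    if val_records is not None and len(val_records):
        overlap = set(train_records["path"]) & set(val_records["path"])
        if overlap:
            raise ValueError(
                f"{len(overlap)} records appear in both train and "
                "validation sets"
            )
    index = {c: i for i, c in enumerate(class_names)}
    X = load_images(train_records["path"], size=config.image_size)
    y = np.array([index[c] for c in train_records[label_column]])
    X_val = y_val = None
    if val_records is not None and len(val_records):
        X_val = load_images(val_records["path"], size=config.image_size)
        y_val = np.array([index[c] for c in val_records[label_column]])
    history = fit_network(model, X, y, config, X_val, y_val,
                          augment_params=augment_params)
    return model, history


def cross_validate(manifest: DatasetManifest, model_factory,
                   config: TrainConfig, k: int = 5,
                   group_by_slide: bool = False,
                   augment_params: AugmentParams | None = None) -> CVResult:
    """k-fold cross-validation with per-fold oversampled training splits.

    ``model_factory(seed)`` must return a freshly initialized network.
    Oversampling is applied to the training portion of each fold only; the
    held-out fold is evaluated untouched.
    """
    folds = make_folds(manifest, k=k, seed=config.seed,
                       group_by_slide=group_by_slide)
    df = manifest.df
    label_col = manifest.label_column
    class_names = manifest.classes()
    index = {c: i for i, c in enumerate(class_names)}
    accuracies = []
    for fold in range(k):
        test_df = df[folds == fold]
        train_df = oversample(df[folds != fold], label_col,
                              seed=config.seed + fold)
        model = model_factory(config.seed + fold)
        model, _ = train_model(model, train_df, None, config, label_col,
                               class_names, augment_params=augment_params)
        X_test = load_images(test_df["path"], size=config.image_size)
        y_test = np.array([index[c] for c in test_df[label_col]])
        pred = _batch_predict(model, _to_nchw(X_test)).argmax(axis=1)
        accuracies.append(float((pred == y_test).mean()))
    mean = float(np.mean(accuracies))
    sem = float(np.std(accuracies, ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    return CVResult(accuracies, mean, sem)


def load_pretrained(spec: BackboneSpec):
    """Initialize a backbone from published ImageNet weights.

    Transfer learning is how the method is normally deployed on the
    standard backbones; no weights ship with this package, so this raises
    an explicit error rather than silently falling back to random
    initialization.
    """
    if spec.name == "tiny":
        raise BackboneUnavailableError(
            "the tiny backbone has no pretrained weights; use init='random'"
        )
    raise BackboneUnavailableError(
        f"ImageNet weights for {spec.name!r} are not bundled and no "
        "deep-learning framework is available to load them; train from "
        "random initialization or provide a framework-backed adapter "
        "offline"
    )
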