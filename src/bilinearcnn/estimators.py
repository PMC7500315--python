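"""Scikit-learn-style classifiers wrapping the bilinear networks.

Three estimators share one fit/predict surface:

* :class:`FastBCNNClassifier` — single-stream (fast) bilinear model, the
  package's headline method.
* :class:`BilinearCNNClassifier` — the two-stream model; with
  ``share_streams=True`` it collapses to the fast variant's function.
* :class:`GAPCNNClassifier` — a first-order global-average-pooling
  baseline used to isolate the value of the orderless second-order
  descriptor (``width_scale`` lets it be parameter-matched to a bilinear
  model).

``X`` is a batch of RGB images, ``(n, H, W, 3)`` or ``(n, 3, H, W)``, with
values in [0, 1]; ``y`` is any label array.  Estimators are clonable and
compose with sklearn model selection; all randomness flows from
``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .models import (
    BackboneSpec,
    GAPClassifierNet,
    assemble_bcnn,
    assemble_fast_bcnn,
    build_backbone,
    count_parameters,
)
from .nn import softmax
from .training import TrainConfig, _to_nchw, _batch_predict, fit_network

__all__ = [
    "FastBCNNClassifier",
    "BilinearCNNClassifier",
    "GAPCNNClassifier",
    "matched_gap_width_scale",
]


class _ConvNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses build the network."""

    def __init__(self, n_channels=16, input_size=64, se_blocks=False,
                 reduction_ratio=4, width_scale=1.0, learning_rate=0.1,
                 batch_size=16, lr_factor=0.1, lr_patience=10,
                 max_epochs=10, min_lr=1e-5, momentum=0.0, random_state=0):
        self.n_channels = n_channels
        self.input_size = input_size
        self.se_blocks = se_blocks
        self.reduction_ratio = reduction_ratio
        self.width_scale = width_scale
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.max_epochs = max_epochs
        self.min_lr = min_lr
        self.momentum = momentum
        self.random_state = random_state

    # -- subclass hook -----------------------------------------------------
    def _build_net(self, n_classes: int, rng: np.random.Generator):
        raise NotImplementedError

    def _backbone_spec(self) -> BackboneSpec:
        return BackboneSpec(
            name="tiny",
            output_channels=self.n_channels,
            input_size=self.input_size,
            se_blocks=self.se_blocks,
            reduction_ratio=self.reduction_ratio,
            width_scale=self.width_scale,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            initial_lr=self.learning_rate,
            batch_size=self.batch_size,
            lr_factor=self.lr_factor,
            lr_patience_epochs=self.lr_patience,
            max_epochs=self.max_epochs,
            min_lr=self.min_lr,
            momentum=self.momentum,
            seed=self.random_state,
            image_size=self.input_size,
        )

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, augment_params=None):
        X = _to_nchw(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(len(self.classes_), rng)
        self.n_parameters_ = count_parameters(self.net_)
        self.history_ = fit_network(self.net_, X, y_enc,
                                    self._train_config(),
                                    augment_params=augment_params)
        return self

    def decision_function(self, X):
        """Pre-softmax logits — the embedding features of the last layer."""
        check_is_fitted(self, "net_")
        X = _to_nchw(X)
        out = []
        for i in range(0, len(X), 64):
            out.append(self.net_.forward(X[i : i + 64], train=False))
        return np.concatenate(out)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return _batch_predict(self.net_, _to_nchw(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class FastBCNNClassifier(_ConvNetClassifier):
    """Fast bilinear-pooling classifier ``(f, P, C)``.

    One tiny convolutional extractor whose D-channel feature map is
    outer-multiplied with itself, sum-pooled over locations, passed
    through signed sqrt + L2 normalization, and classified by an affine
    softmax layer on the D^2 descriptor.
    """

    def __init__(self, n_channels=16, input_size=64, se_blocks=False,
                 reduction_ratio=4, width_scale=1.0, learning_rate=0.1,
                 batch_size=16, lr_factor=0.1, lr_patience=10,
                 max_epochs=10, min_lr=1e-5, momentum=0.0, random_state=0,
                 pooling="sum"):
        super().__init__(n_channels, input_size, se_blocks, reduction_ratio,
                         width_scale, learning_rate, batch_size, lr_factor,
                         lr_patience, max_epochs, min_lr, momentum,
                         random_state)
        self.pooling = pooling

    def _build_net(self, n_classes, rng):
        backbone = build_backbone(self._backbone_spec(), rng)
        return assemble_fast_bcnn(backbone, n_classes, pooling=self.pooling,
                                  rng=rng)


class BilinearCNNClassifier(_ConvNetClassifier):
    """Two-stream bilinear classifier ``(f_A, f_B, P, C)``.

    ``share_streams=True`` uses one extractor for both streams, which is
    functionally identical to :class:`FastBCNNClassifier`.
    """

    def __init__(self, n_channels=16, input_size=64, se_blocks=False,
                 reduction_ratio=4, width_scale=1.0, learning_rate=0.1,
                 batch_size=16, lr_factor=0.1, lr_patience=10,
                 max_epochs=10, min_lr=1e-5, momentum=0.0, random_state=0,
                 pooling="sum", share_streams=False):
        super().__init__(n_channels, input_size, se_blocks, reduction_ratio,
                         width_scale, learning_rate, batch_size, lr_factor,
                         lr_patience, max_epochs, min_lr, momentum,
                         random_state)
        self.pooling = pooling
        self.share_streams = share_streams

    def _build_net(self, n_classes, rng):
        spec = self._backbone_spec()
        f_a = build_backbone(spec, rng)
        f_b = f_a if self.share_streams else build_backbone(spec, rng)
        return assemble_bcnn(f_a, f_b, n_classes, pooling=self.pooling,
                             rng=rng)


class GAPCNNClassifier(_ConvNetClassifier):
    """Global-average-pooling softmax baseline on the same backbone."""

    def _build_net(self, n_classes, rng):
        backbone = build_backbone(self._backbone_spec(), rng)
        return GAPClassifierNet(backbone, n_classes, rng=rng)


def _tiny_backbone_param_count(d: int, width_scale: float,
                               first_kernel: int = 7) -> int:
    spec = BackboneSpec(name="tiny", output_channels=d,
                        width_scale=width_scale,
                        first_kernel=first_kernel)
    w1, w2, w3 = spec.tiny_stage_widths()
    total = 0
    in_ch = 3
    for i, out_ch in enumerate((w1, w2, w3)):
        k = first_kernel if i == 0 else 3
        total += out_ch * in_ch * k * k + out_ch  # conv kernel + bias
        total += 2 * out_ch                       # batch-norm scale + shift
        in_ch = out_ch
    return total


def matched_gap_width_scale(n_channels: int, n_classes: int,
                            fast_width_scale: float = 1.0,
                            grid_step: float = 0.005) -> float:
    """Width scale making a GAP baseline parameter-match a fast model.

    The fast model spends ``D^2 * K + K`` parameters on its classifier;
    the GAP head needs only ``D * K + K``, so its backbone stage widths
    are widened until the total trainable-parameter counts agree as
    closely as the integer layer widths allow.
    """
    d, k = n_channels, n_classes
    target = (_tiny_backbone_param_count(d, fast_width_scale)
              + d * d * k + k)
    best_scale, best_gap = 1.0, np.inf
    for s in np.arange(1.0, 6.0 + grid_step, grid_step):
        total = _tiny_backbone_param_count(d, float(s)) + d * k + k
        gap = abs(total - target)
        if gap < best_gap:
            best_gap, best_scale = gap, float(s)
    return best_scale
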