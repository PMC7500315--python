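"""Backbones and bilinear-pooling classifier networks.

A bilinear CNN is the quadruple ``(f_A, f_B, P, C)``: two convolutional
feature extractors applied to the same image, a bilinear pooling function
``P`` that sum-pools per-location outer products of their channel vectors,
and a classifier ``C`` (an affine layer + softmax on the signed-sqrt,
L2-normalized bilinear vector).  The *fast* variant is the triple
``(f, P, C)`` — one extractor whose output is paired with itself — which
reduces backbone cost and parameter count while producing the same
descriptor as a shared-weight two-stream model.

The desk-scale ``tiny`` backbone (three stride-2 conv stages) is fully
trainable here.  The standard ImageNet backbones the method is normally
deployed on (ResNet50, InceptionV3, InceptionResNetV2) require a deep
learning framework and published weights; they are registered with their
documented output widths and minimum input sizes so that configurations
and parameter accounting can refer to them, and :func:`build_backbone`
raises :class:`BackboneUnavailableError` with an explicit message when one
is requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core_ops import DimensionError
from .nn import (
    BatchNorm2d,
    Conv2d,
    Layer,
    Linear,
    Param,
    ReLU,
    SEBlock,
    Sequential,
    softmax,
    softmax_cross_entropy,
)

#: Documented properties of the standard backbones (channel width of the
#: last convolutional feature map, minimum square input).  Used for
#: configuration validation and closed-form head accounting only.
STANDARD_BACKBONES = {
    "resnet50": {"output_channels": 2048, "min_input": 197},
    "inceptionv3": {"output_channels": 2048, "min_input": 197},
    "inceptionresnetv2": {"output_channels": 1536, "min_input": 197},
}

TINY_MIN_INPUT = 16


class BackboneUnavailableError(RuntimeError):
    """A requested backbone (or its pretrained weights) cannot be built."""


@dataclass
class BackboneSpec:
    """Declarative description of a feature extractor.

    ``output_channels`` is the channel width D of the feature map fed to
    pooling; ``width_scale`` multiplies the tiny backbone's intermediate
    stage widths (used to parameter-match baselines without changing D
    semantics).
    """

    name: str = "tiny"
    output_channels: int = 16
    init: str = "random"
    input_size: int = 64
    se_blocks: bool = False
    reduction_ratio: int = 4
    width_scale: float = 1.0
    first_kernel: int = 7

    def __post_init__(self) -> None:
        if self.name not in ("tiny", *STANDARD_BACKBONES):
            raise ValueError(f"unknown backbone name: {self.name!r}")
        if self.init not in ("random", "imagenet-pretrained"):
            raise ValueError(f"unknown init: {self.init!r}")
        if self.name == "tiny" and self.init != "random":
            raise ValueError("tiny backbone supports only random init")
        min_input = (
            TINY_MIN_INPUT
            if self.name == "tiny"
            else STANDARD_BACKBONES[self.name]["min_input"]
        )
        if self.input_size < min_input:
            raise ValueError(
                f"input_size {self.input_size} below backbone minimum "
                f"{min_input} for {self.name}"
            )

    def tiny_stage_widths(self) -> tuple[int, int, int]:
        d = self.output_channels
        w1 = max(int(round(self.width_scale * d / 2)), 2)
        w2 = max(int(round(self.width_scale * 3 * d / 4)), 2)
        return (w1, w2, d)


def build_backbone(spec: BackboneSpec,
                   rng: np.random.Generator | None = None) -> Sequential:
    """Instantiate the feature extractor described by ``spec``.

    The returned network maps an image batch ``(N, 3, H, W)`` to a feature
    map batch ``(N, D, H', W')`` — a CNN with its classification head
    removed.  Only the ``tiny`` backbone is constructible in pure NumPy;
    the standard ImageNet architectures raise
    :class:`BackboneUnavailableError` (never a silent random stand-in).
    """
    if spec.name != "tiny":
        raise BackboneUnavailableError(
            f"backbone {spec.name!r} requires a deep-learning framework and "
            "published weights, neither of which is bundled with this "
            "package; use the 'tiny' backbone or install a framework-backed "
            "adapter"
        )
    if spec.init != "random":
        raise BackboneUnavailableError(
            "pretrained weights are not available for the tiny backbone"
        )
    rng = rng or np.random.default_rng(0)
    w1, w2, d = spec.tiny_stage_widths()
    layers: list[tuple[str, Layer]] = []
    in_ch = 3
    for i, out_ch in enumerate((w1, w2, d), start=1):
        # wide first kernel (as in standard backbones' stem convolutions)
        # gives orientation-selective responses from the start
        k = spec.first_kernel if i == 1 else 3
        layers.append(
            (f"stage{i}_conv",
             Conv2d(in_ch, out_ch, kernel_size=k, stride=2, padding=k // 2,
                    rng=rng, prefix=f"stage{i}_conv"))
        )
        layers.append(
            (f"stage{i}_bn", BatchNorm2d(out_ch, prefix=f"stage{i}_bn"))
        )
        layers.append((f"stage{i}_relu", ReLU()))
        in_ch = out_ch
    backbone = Sequential(layers)
    if spec.se_blocks:
        backbone = insert_se_blocks(
            backbone,
            positions=[f"stage{i}_relu" for i in range(1, 4)],
            reduction_ratio=spec.reduction_ratio,
            rng=rng,
        )
    return backbone


def insert_se_blocks(backbone: Sequential, positions: list[str],
                     reduction_ratio: int = 16,
                     rng: np.random.Generator | None = None) -> Sequential:
    """Append an SE recalibration block after each named stage boundary.

    Output shapes are unchanged; each block adds ``2 * C^2 / r`` trainable
    parameters where C is the channel width at that position.
    """
    rng = rng or np.random.default_rng(0)
    names = backbone.layer_names()
    for pos in positions:
        if pos not in names:
            raise ValueError(
                f"unknown position {pos!r}; available: {names}"
            )
    channel_at = _channel_widths(backbone)
    new_layers: list[tuple[str, Layer]] = []
    for name, layer in backbone.layers:
        new_layers.append((name, layer))
        if name in positions:
            c = channel_at[name]
            se_name = f"{name}_se"
            new_layers.append(
                (se_name,
                 SEBlock(c, reduction_ratio=reduction_ratio, rng=rng,
                         prefix=se_name))
            )
    return Sequential(new_layers)


def _channel_widths(backbone: Sequential) -> dict[str, int]:
    """Channel count of each layer's output, propagated structurally."""
    widths: dict[str, int] = {}
    current = 3
    for name, layer in backbone.layers:
        if isinstance(layer, Conv2d):
            current = layer.out_channels
        widths[name] = current
    return widths


def backbone_output_channels(backbone: Sequential) -> int:
    widths = _channel_widths(backbone)
    return widths[backbone.layers[-1][0]]


#: Subgradient smoothing for signed sqrt at zero: d/dz = 0.5 / sqrt(|z| + delta).
_SIGNED_SQRT_GRAD_DELTA = 1e-8
_L2_EPS = 1e-12


class _BilinearHead:
    """Pool -> signed sqrt -> L2 normalize -> affine, with backward."""

    def __init__(self, d_a: int, d_b: int, n_classes: int, pooling: str,
                 rng: np.random.Generator):
        if pooling not in ("sum", "mean"):
            raise ValueError("pooling must be 'sum' or 'mean'")
        self.d_a, self.d_b = d_a, d_b
        self.pooling = pooling
        self.fc = Linear(d_a * d_b, n_classes, rng=rng, prefix="head.fc")
        self._cache = None

    def params(self):
        return self.fc.params()

    def forward(self, fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
        n, da, h, w = fa.shape
        db = fb.shape[1]
        if fb.shape[2:] != fa.shape[2:]:
            raise DimensionError(
                f"stream spatial dims differ: {fa.shape[2:]} vs {fb.shape[2:]}"
            )
        ma = fa.reshape(n, da, h * w)
        mb = fb.reshape(n, db, h * w)
        phi = np.matmul(ma, mb.transpose(0, 2, 1))
        if self.pooling == "mean":
            phi = phi / (h * w)
        z = phi.reshape(n, da * db)
        u = np.sign(z) * np.sqrt(np.abs(z))
        norms = np.maximum(np.linalg.norm(u, axis=1, keepdims=True), _L2_EPS)
        v = u / norms
        logits = self.fc.forward(v)
        self._cache = (ma, mb, z, u, norms, (h, w))
        return logits

    def backward(self, dlogits: np.ndarray):
        ma, mb, z, u, norms, (h, w) = self._cache
        n, da, _ = ma.shape
        db = mb.shape[1]
        dv = self.fc.backward(dlogits)
        # v = u / max(||u||, eps): project out the radial component.
        udv = (u * dv).sum(axis=1, keepdims=True)
        du = dv / norms - u * (udv / norms**3)
        dz = du * (0.5 / np.sqrt(np.abs(z) + _SIGNED_SQRT_GRAD_DELTA))
        dphi = dz.reshape(n, da, db)
        if self.pooling == "mean":
            dphi = dphi / (h * w)
        dma = np.matmul(dphi, mb)
        dmb = np.matmul(dphi.transpose(0, 2, 1), ma)
        dfa = dma.reshape(n, da, h, w)
        dfb = dmb.reshape(n, db, h, w)
        return dfa, dfb

    @property
    def bilinear_dim(self) -> int:
        return self.d_a * self.d_b


class BilinearClassifierNet:
    """Two-stream or single-stream bilinear classifier.

    With ``backbone_b`` omitted (or the identical object) this is the fast
    model ``(f, P, C)``; with a distinct second extractor it is the full
    quadruple ``(f_A, f_B, P, C)``.
    """

    kind = "bilinear"

    def __init__(self, backbone_a: Sequential,
                 backbone_b: Sequential | None, n_classes: int,
                 pooling: str = "sum",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.backbone_a = backbone_a
        self.backbone_b = backbone_b if backbone_b is not backbone_a else None
        self.n_classes = int(n_classes)
        d_a = backbone_output_channels(backbone_a)
        d_b = (backbone_output_channels(self.backbone_b)
               if self.backbone_b is not None else d_a)
        self.head = _BilinearHead(d_a, d_b, self.n_classes, pooling, rng)

    @property
    def is_fast(self) -> bool:
        return self.backbone_b is None

    @property
    def streams(self) -> dict[str, Sequential]:
        if self.is_fast:
            return {"stream_a": self.backbone_a}
        return {"stream_a": self.backbone_a, "stream_b": self.backbone_b}

    def params(self) -> list[Param]:
        ps = list(self.backbone_a.params())
        if self.backbone_b is not None:
            ps += self.backbone_b.params()
        return ps + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fa = self.backbone_a.forward(x, train=train)
        fb = (fa if self.backbone_b is None
              else self.backbone_b.forward(x, train=train))
        return self.head.forward(fa, fb)

    def backward(self, dlogits: np.ndarray) -> None:
        dfa, dfb = self.head.backward(dlogits)
        if self.backbone_b is None:
            self.backbone_a.backward(dfa + dfb)
        else:
            self.backbone_b.backward(dfb)
            self.backbone_a.backward(dfa)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, y)
        self.backward(dlogits)
        return loss


class GAPClassifierNet:
    """Baseline: backbone -> global average pooling -> affine -> softmax.

    First-order counterpart to the bilinear models, used to isolate the
    contribution of the orderless second-order descriptor.
    """

    kind = "gap"

    def __init__(self, backbone: Sequential, n_classes: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.backbone_a = backbone
        self.backbone_b = None
        self.n_classes = int(n_classes)
        d = backbone_output_channels(backbone)
        self.fc = Linear(d, self.n_classes, rng=rng, prefix="head.fc")
        self._hw = None

    @property
    def streams(self) -> dict[str, Sequential]:
        return {"stream_a": self.backbone_a}

    def params(self):
        return list(self.backbone_a.params()) + self.fc.params()

    def forward(self, x, train=False):
        f = self.backbone_a.forward(x, train=train)
        self._hw = f.shape[2:]
        return self.fc.forward(f.mean(axis=(2, 3)))

    def backward(self, dlogits):
        dpool = self.fc.backward(dlogits)
        h, w = self._hw
        dfeat = np.broadcast_to(
            dpool[:, :, None, None] / (h * w),
            dpool.shape + (h, w),
        )
        self.backbone_a.backward(np.ascontiguousarray(dfeat))

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    def loss_and_grad(self, x, y):
        logits = self.forward(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, y)
        self.backward(dlogits)
        return loss


def assemble_bcnn(backbone_a: Sequential, backbone_b: Sequential,
                  n_classes: int, pooling: str = "sum",
                  rng: np.random.Generator | None = None
                  ) -> BilinearClassifierNet:
    """Assemble the two-stream quadruple ``(f_A, f_B, P, C)``.

    Passing the same object for both streams yields a shared-weight model
    whose outputs coincide with the fast variant.
    """
    return BilinearClassifierNet(backbone_a, backbone_b, n_classes,
                                 pooling=pooling, rng=rng)


def assemble_fast_bcnn(backbone: Sequential, n_classes: int,
                       pooling: str = "sum",
                       rng: np.random.Generator | None = None
                       ) -> BilinearClassifierNet:
    """Assemble the single-stream triple ``(f, P, C)``."""
    return BilinearClassifierNet(backbone, None, n_classes, pooling=pooling,
                                 rng=rng)


def predict(model, images: np.ndarray) -> np.ndarray:
    """Per-image softmax class probabilities for a batch ``(N, 3, H, W)``."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4:
        raise DimensionError(
            f"expected an image batch (N, 3, H, W); got shape {images.shape}"
        )
    return model.predict_proba(images)


def count_parameters(model) -> int:
    """Total number of trainable scalar parameters.

    For a two-stream model with unshared extractors this equals
    ``P(f_A) + P(f_B) + D_A * D_B * K + K``; for the fast model,
    ``P(f) + D^2 * K + K``.
    """
    seen: set[int] = set()
    total = 0
    for p in model.params():
        if id(p) not in seen:
            seen.add(id(p))
            total += p.size
    return total


# ---------------------------------------------------------------------------
# Serialization: NumPy .npz checkpoint + JSON sidecar.


def _state_dict(model) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for scope, params in _scoped_params(model):
        for p in params:
            state[f"{scope}.{p.name}"] = p.value
    for key, value in _named_buffers(model):
        state[key] = value
    return state


def _named_buffers(model):
    """Non-trainable state (batch-norm running statistics)."""
    scopes = [("a", model.backbone_a)]
    if getattr(model, "backbone_b", None) is not None:
        scopes.append(("b", model.backbone_b))
    for scope, backbone in scopes:
        for name, layer in backbone.layers:
            if isinstance(layer, BatchNorm2d):
                yield f"{scope}.{name}.running_mean", layer.running_mean
                yield f"{scope}.{name}.running_var", layer.running_var


def _scoped_params(model):
    yield "a", model.backbone_a.params()
    if getattr(model, "backbone_b", None) is not None:
        yield "b", model.backbone_b.params()
    head = model.head.params() if hasattr(model, "head") else model.fc.params()
    yield "head", head


def save_model(model, path, spec: BackboneSpec,
               class_names: list | None = None,
               pixel_scaling: str = "unit-interval") -> None:
    """Write ``<path>.npz`` (weights) and ``<path>.json`` (sidecar).

    The sidecar records the backbone spec, model kind, class names and the
    pixel-scaling convention so that a reload reproduces predictions
    bitwise in eval mode.
    """
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **_state_dict(model))
    meta = {
        "kind": model.kind,
        "fast": getattr(model, "is_fast", model.kind == "gap"),
        "n_classes": model.n_classes,
        "pooling": getattr(getattr(model, "head", None), "pooling", None),
        "backbone_spec": asdict(spec),
        "class_names": list(class_names) if class_names is not None else None,
        "pixel_scaling": pixel_scaling,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path):
    """Rebuild a model saved by :func:`save_model`.

    Returns ``(model, sidecar_dict)``.
    """
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = BackboneSpec(**meta["backbone_spec"])
    rng = np.random.default_rng(0)
    if meta["kind"] == "gap":
        model = GAPClassifierNet(build_backbone(spec, rng),
                                 meta["n_classes"], rng=rng)
    elif meta["fast"]:
        model = assemble_fast_bcnn(build_backbone(spec, rng),
                                   meta["n_classes"],
                                   pooling=meta["pooling"], rng=rng)
    else:
        model = assemble_bcnn(build_backbone(spec, rng),
                              build_backbone(spec, rng),
                              meta["n_classes"],
                              pooling=meta["pooling"], rng=rng)
    with np.load(path.with_suffix(".npz")) as data:
        state = dict(data)
    for scope, params in _scoped_params(model):
        for p in params:
            key = f"{scope}.{p.name}"
            if key not in state:
                raise KeyError(f"checkpoint missing parameter {key}")
            if state[key].shape != p.value.shape:
                raise DimensionError(
                    f"checkpoint parameter {key} has shape "
                    f"{state[key].shape}, expected {p.value.shape}"
                )
            p.value = state[key].astype(np.float64)
    scopes = [("a", model.backbone_a)]
    if getattr(model, "backbone_b", None) is not None:
        scopes.append(("b", model.backbone_b))
    for scope, backbone in scopes:
        for name, layer in backbone.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"{scope}.{name}.running_mean"]
                layer.running_var = state[f"{scope}.{name}.running_var"]
    return model, meta
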