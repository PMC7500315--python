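"""Grad-CAM localization heatmaps and convolution-activation visualization.

Grad-CAM: for a chosen class logit and convolutional layer, the gradient
of the logit with respect to the layer's feature map is spatially averaged
into per-channel importance weights; the weighted channel sum, rectified
and max-normalized, is a coarse localization map of the evidence the model
used.  For a two-stream bilinear model the two streams' maps are averaged.

Activation maps expose the raw per-channel response of a layer (min-max
scaled per channel for display) — used to compare the two streams of a
bilinear model, which turn out to respond almost identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .core_ops import DimensionError
from .training import _to_nchw

__all__ = ["Heatmap", "grad_cam", "activation_maps"]


@dataclass
class Heatmap:
    """A Grad-CAM map at feature resolution plus its upsampled copy.

    Values are nonnegative (post-ReLU) with the maximum normalized to 1
    whenever the map is not identically zero.
    """

    grid: np.ndarray
    upsampled: np.ndarray
    target_class: int
    layer: str


def _single_image_batch(image) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError(f"expected one (H, W, 3) image; got {img.shape}")
    return _to_nchw(img[None])


def _resolve_net(model):
    return getattr(model, "net_", model)


def _resolve_layer(backbone, layer: str | None) -> str:
    names = backbone.layer_names()
    if layer is None or layer == "last_conv":
        # Last layer of the extractor: the feature map fed to pooling.
        return names[-1]
    if layer == "first_conv":
        return names[0]
    if layer not in names:
        raise ValueError(f"unknown layer {layer!r}; available: {names}")
    return layer


def _bilinear_upsample(grid: np.ndarray, size: int) -> np.ndarray:
    im = Image.fromarray(grid.astype(np.float32), mode="F")
    return np.asarray(im.resize((size, size), Image.BILINEAR),
                      dtype=np.float64)


def grad_cam(model, image, target_class, layer: str | None = None) -> Heatmap:
    """Gradient-weighted class activation map for one image.

    ``target_class`` may be a label (for a fitted estimator) or a class
    index.  The heatmap combines ReLU of the importance-weighted channel
    sum at the chosen layer; an all-zero map is returned as zeros rather
    than NaN from normalization.
    """
    net = _resolve_net(model)
    if hasattr(model, "classes_") and not isinstance(target_class, (int, np.integer)):
        matches = np.flatnonzero(model.classes_ == target_class)
        if len(matches) != 1:
            raise ValueError(f"unknown class {target_class!r}")
        target_idx = int(matches[0])
    else:
        target_idx = int(target_class)
    x = _single_image_batch(image)
    logits = net.forward(x, train=False)
    if not (0 <= target_idx < logits.shape[1]):
        raise ValueError(
            f"class index {target_idx} outside [0, {logits.shape[1]})"
        )
    dlogits = np.zeros_like(logits)
    dlogits[0, target_idx] = 1.0
    net.backward(dlogits)
    for p in net.params():  # interpretability pass must not leave gradients
        p.grad[...] = 0.0
    grids = []
    layer_name = None
    for backbone in net.streams.values():
        layer_name = _resolve_layer(backbone, layer)
        fmap = backbone.activations[layer_name][0]
        grad = backbone.output_grads[layer_name][0]
        if fmap.ndim != 3:
            raise DimensionError("chosen layer has no spatial extent")
        weights = grad.mean(axis=(1, 2))
        grids.append(np.maximum(np.tensordot(weights, fmap, axes=1), 0.0))
    grid = np.mean(grids, axis=0)
    peak = grid.max()
    if peak > 0:
        grid = grid / peak
    upsampled = _bilinear_upsample(grid, x.shape[-1])
    return Heatmap(grid=grid, upsampled=upsampled, target_class=target_idx,
                   layer=layer_name)


def activation_maps(model, image, layer: str = "first_conv"
                    ) -> dict[str, np.ndarray]:
    """Per-channel activations of a layer, min-max scaled to [0, 1].

    Returns one ``(C, H', W')`` array per stream (key ``stream_a`` and,
    for an unshared two-stream model, ``stream_b``); constant channels
    scale to zeros.
    """
    net = _resolve_net(model)
    x = _single_image_batch(image)
    net.forward(x, train=False)
    out: dict[str, np.ndarray] = {}
    for stream, backbone in net.streams.items():
        name = _resolve_layer(backbone, layer)
        act = backbone.activations[name][0]
        lo = act.min(axis=(1, 2), keepdims=True)
        hi = act.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        scaled = np.where(span > 0, (act - lo) / np.where(span == 0, 1, span),
                          0.0)
        out[stream] = scaled
    return out
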