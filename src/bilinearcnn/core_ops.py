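"""Core numerical operations for bilinear pooling and channel attention.

This module holds the defining primitives of the method as pure functions
over NumPy arrays:

* **Bilinear pooling** — at every spatial location the channel vectors of
  two feature maps are combined with an outer product, and the resulting
  matrices are sum-pooled over locations.  The flattened result is an
  *orderless* descriptor: all spatial information is discarded, which gives
  the downstream classifier translation invariance — the right inductive
  bias when the class signal (e.g. a lesion texture) can appear anywhere in
  the image.
* **Fast (single-stream) bilinear pooling** — the same operation with one
  feature map outer-multiplied with itself, so only one backbone pass is
  needed; the pooled ``D x D`` matrix is symmetric positive semidefinite.
* **Signed square root and L2 normalization** — the standard conditioning
  chain applied to the bilinear vector before classification.
* **Squeeze-and-Excitation (SE)** — channel attention: global average
  pooling (squeeze), a two-layer gate with sigmoid output (excite), and a
  per-channel rescaling of the feature map (apply).

Everything here is differentiable in the mathematical sense; the gradient
implementations used during training live in :mod:`bilinearcnn.nn`.

Array conventions: feature maps are ``(C, H, W)`` (channels first); the
flattening of the pooled outer-product matrix into a vector is row-major,
with the first stream's channel index varying slowest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DimensionError",
    "ValidationError",
    "SEBlockParams",
    "bilinear_pool",
    "bilinear_pool_fast",
    "signed_sqrt",
    "l2_normalize",
    "se_squeeze",
    "se_excite",
    "se_apply",
]


class DimensionError(ValueError):
    """Raised when array shapes are inconsistent with an operation."""


class ValidationError(ValueError):
    """Raised when input values violate a precondition (e.g. non-finite)."""


def _as_feature_map(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise DimensionError(
            f"{name} must have shape (C, H, W); got ndim={x.ndim}"
        )
    if min(x.shape) < 1:
        raise DimensionError(f"{name} has an empty axis: shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")
    return x


def _as_finite_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} contains non-finite values")
    return v


def bilinear_pool(fmap_a, fmap_b) -> np.ndarray:
    """Two-stream bilinear pooling.

    Computes ``sum_l outer(f_a(l), f_b(l))`` over all ``H * W`` spatial
    locations ``l`` and flattens the resulting ``(C_a, C_b)`` matrix
    row-major (stream-A channel index varying slowest).

    Parameters
    ----------
    fmap_a, fmap_b
        Feature maps of shape ``(C_a, H, W)`` and ``(C_b, H, W)``.  The
        channel counts may differ; the spatial dimensions must match.

    Returns
    -------
    ndarray of shape ``(C_a * C_b,)``
        The orderless bilinear descriptor.  Accumulation is in float64
        regardless of the input dtype.
    """
    a = _as_feature_map(fmap_a, "fmap_a")
    b = _as_feature_map(fmap_b, "fmap_b")
    if a.shape[1:] != b.shape[1:]:
        raise DimensionError(
            f"spatial dimensions differ: {a.shape[1:]} vs {b.shape[1:]}"
        )
    ca, h, w = a.shape
    cb = b.shape[0]
    # Algebraic identity: reshape to (C, H*W) and contract over locations.
    phi = a.reshape(ca, h * w) @ b.reshape(cb, h * w).T
    return phi.reshape(ca * cb)


def bilinear_pool_fast(fmap) -> np.ndarray:
    """Single-stream (fast) bilinear pooling: the map paired with itself.

    Equivalent to ``bilinear_pool(fmap, fmap)``; the reshaped ``(D, D)``
    matrix is symmetric positive semidefinite by construction.
    """
    f = _as_feature_map(fmap, "fmap")
    return bilinear_pool(f, f)


def signed_sqrt(v) -> np.ndarray:
    """Elementwise signed square root ``sign(x) * sqrt(|x|)``.

    Applied to the bilinear vector to temper large activations; preserves
    the sign pattern and zeros exactly.
    """
    x = _as_finite_vector(v, "v")
    return np.sign(x) * np.sqrt(np.abs(x))


def l2_normalize(v, eps: float = 1e-12) -> np.ndarray:
    """Scale a vector to unit Euclidean norm.

    Returns ``v / max(||v||_2, eps)``; the ``eps`` floor makes the zero
    vector map to itself instead of producing NaN.
    """
    x = _as_finite_vector(v, "v")
    n = float(np.linalg.norm(x))
    return x / max(n, eps)


def se_squeeze(fmap) -> np.ndarray:
    """Squeeze step: per-channel global average pooling.

    ``s_c = (1 / (H * W)) * sum_{i,j} u_c(i, j)`` — integrates each channel
    of a ``(C, H, W)`` feature map into a single descriptor of length C.
    """
    u = _as_feature_map(fmap, "fmap")
    return u.mean(axis=(1, 2))


@dataclass
class SEBlockParams:
    """Weights of the two-layer excitation gate.

    ``W1`` has shape ``(C // r, C)`` (dimensionality reduction), ``W2`` has
    shape ``(C, C // r)`` (restoration); ``reduction_ratio`` r must divide
    the channel count C.  The gate carries no bias terms by default,
    matching the form ``sigmoid(W2 @ relu(W1 @ s))``; optional biases may
    be supplied for the conventional fully connected variant.
    """

    W1: np.ndarray
    W2: np.ndarray
    reduction_ratio: int
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise DimensionError("W1 and W2 must be matrices")
        hidden, c = self.W1.shape
        if self.W2.shape != (c, hidden):
            raise DimensionError(
                f"W2 shape {self.W2.shape} inconsistent with W1 {self.W1.shape}"
            )
        r = int(self.reduction_ratio)
        if r < 1 or c % r != 0 or c // r != hidden:
            raise DimensionError(
                f"reduction ratio {r} inconsistent with C={c}, hidden={hidden}"
            )

    @property
    def n_channels(self) -> int:
        return self.W1.shape[1]


def se_excite(s, params: SEBlockParams) -> np.ndarray:
    """Excitation step: ``e = sigmoid(W2 @ relu(W1 @ s))``.

    Maps the squeezed channel descriptor to per-channel gate weights, each
    strictly inside (0, 1).
    """
    s = _as_finite_vector(s, "s")
    if s.shape != (params.n_channels,):
        raise DimensionError(
            f"descriptor length {s.shape} does not match C={params.n_channels}"
        )
    z1 = params.W1 @ s
    if params.b1 is not None:
        z1 = z1 + params.b1
    h = np.maximum(z1, 0.0)
    z2 = params.W2 @ h
    if params.b2 is not None:
        z2 = z2 + params.b2
    return 1.0 / (1.0 + np.exp(-z2))


def se_apply(fmap, e) -> np.ndarray:
    """Rescale each channel of a feature map by its gate weight.

    Channel ``c`` of the output is ``e_c`` times channel ``c`` of the
    input; the shape is unchanged.
    """
    u = _as_feature_map(fmap, "fmap")
    e = _as_finite_vector(e, "e")
    if e.shape != (u.shape[0],):
        raise DimensionError(
            f"gate length {e.shape} does not match C={u.shape[0]}"
        )
    return u * e[:, None, None]
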