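"""Minimal trainable-layer framework with hand-written backpropagation.

The networks in this package are small (a three-stage convolutional
backbone plus a bilinear or global-average-pooled head), so the layers are
implemented directly on NumPy with explicit forward/backward passes rather
than through an autodiff framework.  Convolution uses the im2col identity;
all accumulation is float64.

Each layer caches what it needs during ``forward`` and consumes the cache
in ``backward``; a layer instance therefore supports one in-flight forward
at a time (the training loop and Grad-CAM both respect this).
"""

from __future__ import annotations

import numpy as np

from .core_ops import DimensionError


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N, C, H, W) into (N, C*k*k, L) patch columns."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    if ho < 1 or wo < 1:
        raise DimensionError(
            f"spatial input {h - 2 * pad}x{w - 2 * pad} too small for "
            f"kernel {k} stride {stride}"
        )
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo)
    return cols, (ho, wo), x.shape


def _col2im(dcols, padded_shape, k, stride, pad, out_hw):
    n, c, hp, wp = padded_shape
    ho, wo = out_hw
    dpad = np.zeros(padded_shape)
    d6 = dcols.reshape(n, c, k, k, ho, wo)
    for di in range(k):
        for dj in range(k):
            dpad[:, :, di : di + ho * stride : stride,
                 dj : dj + wo * stride : stride] += d6[:, :, di, dj]
    if pad:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with He-uniform init."""

    def __init__(self, in_channels, out_channels, kernel_size=3, stride=1,
                 padding=1, rng: np.random.Generator | None = None,
                 prefix: str = "conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        w = he_uniform((out_channels, in_channels, kernel_size, kernel_size),
                       fan_in, rng)
        self.W = Param(f"{prefix}.W", w)
        self.b = Param(f"{prefix}.b", np.zeros(out_channels))
        self.k = kernel_size
        self.stride = stride
        self.pad = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise DimensionError(
                f"expected (N, {self.in_channels}, H, W); got {x.shape}"
            )
        cols, (ho, wo), padded_shape = _im2col(x, self.k, self.stride, self.pad)
        w2d = self.W.value.reshape(self.out_channels, -1)
        out = np.matmul(w2d, cols) + self.b.value[:, None]
        self._cache = (cols, padded_shape, (ho, wo))
        return out.reshape(x.shape[0], self.out_channels, ho, wo)

    def backward(self, grad):
        cols, padded_shape, out_hw = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, self.out_channels, -1)
        self.W.grad += np.einsum("nol,nkl->ok", g, cols).reshape(
            self.W.value.shape
        )
        self.b.grad += g.sum(axis=(0, 2))
        w2d = self.W.value.reshape(self.out_channels, -1)
        dcols = np.matmul(w2d.T, g)
        return _col2im(dcols, padded_shape, self.k, self.stride, self.pad,
                       out_hw)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable scale and shift.

    Training mode normalizes by batch statistics and updates running
    estimates; eval mode uses the running estimates, so inference is
    deterministic and batch-independent.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, prefix: str = "bn"):
        self.gamma = Param(f"{prefix}.gamma", np.ones(channels))
        self.beta = Param(f"{prefix}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels
        self._cache = None
        # cumulative mode: running stats become the plain average of batch
        # statistics (used to recalibrate after training)
        self.cumulative = False
        self._cum_count = 0

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if x.shape[1] != self.channels:
            raise DimensionError(
                f"expected {self.channels} channels, got {x.shape[1]}"
            )
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.cumulative:
                n = self._cum_count
                self.running_mean = (n * self.running_mean + mu) / (n + 1)
                self.running_var = (n * self.running_var + var) / (n + 1)
                self._cum_count = n + 1
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[:, None, None] * xhat \
            + self.beta.value[:, None, None]

    def backward(self, grad):
        xhat, inv_std, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * self.gamma.value[:, None, None]
        if not train:
            return dxhat * inv_std[:, None, None]
        # standard batch-norm backward over the (N, H, W) axes
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return (inv_std[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class SEBlock(Layer):
    """Squeeze-and-Excitation channel recalibration as a trainable layer.

    squeeze: global average pool -> s (N, C)
    excite:  e = sigmoid(W2 @ relu(W1 @ s))      (no biases by default)
    apply:   out = e[:, :, None, None] * input
    """

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 rng: np.random.Generator | None = None, bias: bool = False,
                 prefix: str = "se"):
        if channels % reduction_ratio != 0:
            raise DimensionError(
                f"reduction ratio {reduction_ratio} does not divide "
                f"C={channels}"
            )
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction_ratio
        self.W1 = Param(f"{prefix}.W1", he_uniform((hidden, channels),
                                                   channels, rng))
        self.W2 = Param(f"{prefix}.W2", he_uniform((channels, hidden),
                                                   hidden, rng))
        self.b1 = Param(f"{prefix}.b1", np.zeros(hidden)) if bias else None
        self.b2 = Param(f"{prefix}.b2", np.zeros(channels)) if bias else None
        self.channels = channels
        self.reduction_ratio = reduction_ratio
        self._cache = None

    def params(self):
        ps = [self.W1, self.W2]
        if self.b1 is not None:
            ps += [self.b1, self.b2]
        return ps

    def forward(self, x, train=False):
        if x.shape[1] != self.channels:
            raise DimensionError(
                f"expected {self.channels} channels, got {x.shape[1]}"
            )
        n, c, h, w = x.shape
        s = x.mean(axis=(2, 3))
        z1 = s @ self.W1.value.T
        if self.b1 is not None:
            z1 = z1 + self.b1.value
        hdd = np.maximum(z1, 0.0)
        z2 = hdd @ self.W2.value.T
        if self.b2 is not None:
            z2 = z2 + self.b2.value
        e = 1.0 / (1.0 + np.exp(-z2))
        self._cache = (x, s, z1, hdd, e, h * w)
        return x * e[:, :, None, None]

    def backward(self, grad):
        x, s, z1, hdd, e, hw = self._cache
        dx = grad * e[:, :, None, None]
        de = (grad * x).sum(axis=(2, 3))
        dz2 = de * e * (1.0 - e)
        self.W2.grad += dz2.T @ hdd
        if self.b2 is not None:
            self.b2.grad += dz2.sum(axis=0)
        dh = dz2 @ self.W2.value
        dz1 = np.where(z1 > 0, dh, 0.0)
        self.W1.grad += dz1.T @ s
        if self.b1 is not None:
            self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.W1.value
        dx += ds[:, :, None, None] / hw
        return dx


class Linear(Layer):
    def __init__(self, in_features, out_features,
                 rng: np.random.Generator | None = None, prefix: str = "fc"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{prefix}.W",
                       he_uniform((out_features, in_features), in_features,
                                  rng))
        self.b = Param(f"{prefix}.b", np.zeros(out_features))
        self.in_features = in_features
        self.out_features = out_features
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise DimensionError(
                f"expected (N, {self.in_features}); got {x.shape}"
            )
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Sequential(Layer):
    """An ordered chain of named layers with per-layer activation caching.

    Activations and the gradients flowing back into each layer's output are
    retained after forward/backward so that interpretability code
    (Grad-CAM, activation visualization) can read them by layer name.
    """

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = list(layers)
        self.activations: dict[str, np.ndarray] = {}
        self.output_grads: dict[str, np.ndarray] = {}

    def params(self):
        return [p for _, layer in self.layers for p in layer.params()]

    def layer_names(self) -> list[str]:
        return [name for name, _ in self.layers]

    def forward(self, x, train=False):
        self.activations = {}
        for name, layer in self.layers:
            x = layer.forward(x, train=train)
            self.activations[name] = x
        return x

    def backward(self, grad):
        self.output_grads = {}
        for name, layer in reversed(self.layers):
            self.output_grads[name] = grad
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def update_bn_statistics(net, X: np.ndarray, batch_size: int = 64) -> None:
    """Recompute batch-norm running statistics over a dataset.

    Resets every :class:`BatchNorm2d` in the model's streams and replaces
    its running mean/variance with the plain average of batch statistics
    under the final weights.  Small-batch training can leave the
    exponential running estimates far from the statistics the converged
    network actually produces; this pass realigns eval-mode behavior with
    training-mode behavior.
    """
    backbones = [net.backbone_a]
    if getattr(net, "backbone_b", None) is not None:
        backbones.append(net.backbone_b)
    bns = [layer for bb in backbones for _, layer in bb.layers
           if isinstance(layer, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean = np.zeros(bn.channels)
        bn.running_var = np.ones(bn.channels)
        bn.cumulative = True
        bn._cum_count = 0
    for i in range(0, len(X), batch_size):
        net.forward(X[i : i + batch_size], train=True)
    for bn in bns:
        bn.cumulative = False


class SGD:
    """Plain mini-batch SGD with optional momentum (default 0)."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.value -= self.lr * v
            else:
                p.value -= self.lr * p.grad
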