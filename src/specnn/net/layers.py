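"""NumPy layers for small 1D conv nets, with hand-written backward passes.

Feature tensors have shape (B, C, L): batch, channels, spectral length.
Each layer caches what its backward pass needs during forward; ``backward``
accumulates parameter gradients in ``grads`` and returns the gradient with
respect to the layer input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "Linear",
    "Dropout",
    "ECA",
    "ResidualBlock1d",
    "eca_forward",
    "sigmoid",
    "softmax",
    "cross_entropy",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv1d(Layer):
    """1D convolution (cross-correlation), stride 1, symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        scale = np.sqrt(2.0 / (in_channels * kernel_size))  # He init
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)),
            "b": np.zeros(out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p, k = self.padding, self.kernel_size
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        self._xpad = xpad
        B, C, Lp = xpad.shape
        L_out = Lp - k + 1
        if L_out < 1:
            raise ValueError(f"input length {x.shape[2]} too short for kernel {k}")
        W, b = self.params["W"], self.params["b"]
        out = np.zeros((B, self.out_channels, L_out))
        for j in range(k):
            out += np.einsum("oc,bcl->bol", W[:, :, j], xpad[:, :, j : j + L_out])
        return out + b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xpad = self._xpad
        p, k = self.padding, self.kernel_size
        L_out = grad.shape[2]
        W = self.params["W"]
        dxpad = np.zeros_like(xpad)
        for j in range(k):
            self.grads["W"][:, :, j] += np.einsum("bol,bcl->oc", grad, xpad[:, :, j : j + L_out])
            dxpad[:, :, j : j + L_out] += np.einsum("oc,bol->bcl", W[:, :, j], grad)
        self.grads["b"] += grad.sum(axis=(0, 2))
        return dxpad[:, :, p:-p] if p else dxpad


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (batch, length) axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        g, b = self.params["gamma"], self.params["beta"]
        return g[None, :, None] * xhat + b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] += (grad * xhat).sum(axis=(0, 2))
        self.grads["beta"] += grad.sum(axis=(0, 2))
        dxhat = grad * g[None, :, None]
        if not train:
            return dxhat * inv[None, :, None]
        N = shape[0] * shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[None, :, None] / N) * (N * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    pool size is dropped (floor semantics)."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        p = self.pool_size
        L_out = L // p
        if L_out < 1:
            raise ValueError(f"length {L} shorter than pool size {p}")
        xv = x[:, :, : L_out * p].reshape(B, C, L_out, p)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = x.shape
        return xv.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        p = self.pool_size
        L_out = grad.shape[2]
        dx = np.zeros((B, C, L_out, p))
        b, c, l = np.indices(grad.shape)
        dx[b, c, l, self._argmax] = grad
        out = np.zeros((B, C, L))
        out[:, :, : L_out * p] = dx.reshape(B, C, L_out * p)
        return out


class GlobalAvgPool1d(Layer):
    """Adaptive average pooling to length 1, returned as (B, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        return np.repeat(grad[:, :, None], L, axis=2) / L


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_features, in_features)),
            "b": np.zeros(out_features),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += grad.T @ self._x
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time.  ``rng`` is injected
    by the model so all stochasticity keys off one run seed."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class ECA(Layer):
    """Efficient channel attention.

    Mean-pools the (B, C, L) input over the spectral axis into a per-channel
    descriptor, runs a single k-tap 1D convolution (zero padding, no bias)
    across the channel axis, squashes through a sigmoid, and rescales each
    input channel by its gate.  No channel dimensionality reduction occurs.
    """

    def __init__(self, channels: int, kernel_size: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError(f"ECA kernel size must be odd and positive, got {kernel_size}")
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.kernel_size = kernel_size
        scale = np.sqrt(1.0 / kernel_size)
        self.params = {"w": rng.normal(0.0, scale, size=kernel_size)}
        self.grads = {"w": np.zeros(kernel_size)}

    def _gates(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Channel gates from descriptors s of shape (B, C)."""
        k = self.kernel_size
        p = (k - 1) // 2
        spad = np.pad(s, ((0, 0), (p, p)))
        C = s.shape[1]
        y = np.zeros_like(s)
        w = self.params["w"]
        for j in range(k):
            y += w[j] * spad[:, j : j + C]
        return sigmoid(y), spad

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        s = x.mean(axis=2)  # (B, C) global channel descriptor
        g, spad = self._gates(s)
        self._cache = (x, g, spad)
        return x * g[:, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, g, spad = self._cache
        B, C, L = x.shape
        k = self.kernel_size
        p = (k - 1) // 2
        w = self.params["w"]
        dg = (grad * x).sum(axis=2)          # (B, C)
        dy = dg * g * (1.0 - g)              # through sigmoid
        for j in range(k):
            self.grads["w"][j] += (dy * spad[:, j : j + C]).sum()
        dspad = np.zeros_like(spad)
        for j in range(k):
            dspad[:, j : j + C] += w[j] * dy
        ds = dspad[:, p : p + C] if p else dspad
        return grad * g[:, :, None] + ds[:, :, None] / L


def eca_forward(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Functional ECA forward pass with explicit filter taps.

    ``weights`` must have odd length k; the gate for channel c is
    ``sigmoid(sum_j w_j * mean_L(x)[c + j - (k-1)/2])`` with zero padding,
    and the output is the input scaled channel-wise by its gate.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (B, C, L) input, got shape {x.shape}")
    if weights.ndim != 1 or weights.size % 2 == 0:
        raise ValueError(f"weights must be a 1D odd-length filter, got shape {weights.shape}")
    if weights.size > 2 * x.shape[1] - 1:
        raise ValueError(
            f"filter length {weights.size} exceeds 2C-1 for C={x.shape[1]} channels"
        )
    layer = ECA(channels=x.shape[1], kernel_size=weights.size)
    layer.params["w"] = weights.copy()
    return layer.forward(x, train=False)


class ResidualBlock1d(Layer):
    """Residual block: conv-bn-relu-conv-bn (+ optional ECA) + skip, then ReLU.

    A 1x1 convolution aligns the skip path when input and output channel
    counts differ; otherwise the skip is the identity.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 eca_kernel: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        pad = (kernel_size - 1) // 2
        self.conv1 = Conv1d(in_channels, out_channels, kernel_size, pad, rng)
        self.bn1 = BatchNorm1d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, kernel_size, pad, rng)
        self.bn2 = BatchNorm1d(out_channels)
        self.eca = ECA(out_channels, eca_kernel, rng) if eca_kernel else None
        self.proj = Conv1d(in_channels, out_channels, 1, 0, rng) if in_channels != out_channels else None
        self.relu_out = ReLU()

    def children(self) -> list[Layer]:
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.eca is not None:
            out.append(self.eca)
        if self.proj is not None:
            out.append(self.proj)
        out.append(self.relu_out)
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        if self.eca is not None:
            h = self.eca.forward(h, train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(h + skip, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu_out.backward(grad)
        dskip = grad if self.proj is None else self.proj.backward(grad)
        h = grad
        if self.eca is not None:
            h = self.eca.backward(h)
        h = self.bn2.backward(h)
        h = self.conv2.backward(h)
        h = self.relu1.backward(h)
        h = self.bn1.backward(h)
        h = self.conv1.backward(h)
        return h + dskip

    def zero_grad(self) -> None:
        for c in self.children():
            c.zero_grad()
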