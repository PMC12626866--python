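"""Minimal CPU neural-network engine (numpy) for the gait classifiers.

Implements exactly the pieces the lightweight gait CNN needs: same-padding
stride-1 2-D/1-D convolutions (im2col + BLAS matmul), 2x max-pooling,
ReLU, inverted dropout, dense layers, global average pooling, He-normal
initialisation, softmax cross-entropy with label smoothing, and Adam with
L2 weight decay. Everything runs in float32 and is deterministic given the
generator passed to training.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    """Base layer; subclasses fill params/grads dicts with matching keys."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """Same-padding, stride-1 2-D convolution, channels-last (B, H, W, C).

    ``skip_input_grad`` elides the input-gradient computation; set it on
    the first layer of a network, whose input needs no gradient.
    """

    def __init__(self, c_in, c_out, kernel, rng, skip_input_grad=False):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.skip_input_grad = skip_input_grad
        fan_in = c_in * kernel * kernel
        self.params["W"] = he_normal(rng, (fan_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def _im2col(self, x):
        b, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (B, H, W, C, k, k) -> (B*H*W, k*k*C); single copy at reshape
        return view.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, self.k * self.k * c)

    def forward(self, x, train=False, rng=None):
        self.x_shape = x.shape
        b, h, w, c = x.shape
        self.cols = self._im2col(x)
        y = self.cols @ self.params["W"] + self.params["b"]
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dy):
        b, h, w, c = self.x_shape
        dyf = dy.reshape(b * h * w, self.c_out)
        self.grads["W"] = self.cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        if self.skip_input_grad:
            return None
        dcols = (dyf @ self.params["W"].T).reshape(b, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class Conv1D(Layer):
    """Same-padding, stride-1 1-D convolution, channels-last (B, L, C)."""

    def __init__(self, c_in, c_out, kernel, rng, skip_input_grad=False):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.skip_input_grad = skip_input_grad
        fan_in = c_in * kernel
        self.params["W"] = he_normal(rng, (fan_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        self.x_shape = x.shape
        b, n, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # (B, L, C, k) -> (B*L, k*C)
        self.cols = view.transpose(0, 1, 3, 2).reshape(b * n, self.k * c)
        y = self.cols @ self.params["W"] + self.params["b"]
        return y.reshape(b, n, self.c_out)

    def backward(self, dy):
        b, n, c = self.x_shape
        dyf = dy.reshape(b * n, self.c_out)
        self.grads["W"] = self.cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        if self.skip_input_grad:
            return None
        dcols = (dyf @ self.params["W"].T).reshape(b, n, self.k, c)
        p = self.k // 2
        dxp = np.zeros((b, n + 2 * p, c), dtype=DTYPE)
        for i in range(self.k):
            dxp[:, i : i + n, :] += dcols[:, :, i, :]
        return dxp[:, p : p + n, :]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2, channels-last; odd trailing rows/cols
    are cropped. Gradient routes to the first maximal element of each
    pooling window (deterministic tie-break)."""

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self.x_shape = x.shape
        self.x = x
        m = x[:, 0 : 2 * h2 : 2, 0 : 2 * w2 : 2, :]
        for di, dj in ((0, 1), (1, 0), (1, 1)):
            m = np.maximum(m, x[:, di : 2 * h2 : 2, dj : 2 * w2 : 2, :])
        self.m = m
        return m

    def backward(self, dy):
        b, h, w, c = self.x_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((b, h, w, c), dtype=DTYPE)
        used = np.zeros(dy.shape, dtype=bool)
        for di, dj in ((0, 0), (0, 1), (1, 0), (1, 1)):
            view = self.x[:, di : 2 * h2 : 2, dj : 2 * w2 : 2, :]
            sel = (view == self.m) & ~used
            dst = dx[:, di : 2 * h2 : 2, dj : 2 * w2 : 2, :]
            dst[sel] = dy[sel]
            used |= sel
        return dx


class MaxPool1D(Layer):
    """Length-2 max pooling, stride 2, channels-last (B, L, C)."""

    def forward(self, x, train=False, rng=None):
        b, n, c = x.shape
        n2 = n // 2
        self.x_shape = x.shape
        r = x[:, : 2 * n2, :].reshape(b, n2, 2, c).transpose(0, 1, 3, 2)
        self.arg = r.argmax(axis=-1)
        return r.max(axis=-1)

    def backward(self, dy):
        b, n, c = self.x_shape
        n2 = n // 2
        dr = np.zeros((b, n2, c, 2), dtype=DTYPE)
        np.put_along_axis(dr, self.arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros((b, n, c), dtype=DTYPE)
        dx[:, : 2 * n2, :] = dr.transpose(0, 1, 3, 2).reshape(b, 2 * n2, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self.mask

    def backward(self, dy):
        return dy if self.mask is None else dy * self.mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self.x_shape)


class GlobalAvgPool(Layer):
    """Mean over all spatial positions (channels-last) -> (B, C)."""

    def forward(self, x, train=False, rng=None):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1, x.shape[-1]).mean(axis=1)

    def backward(self, dy):
        spatial = int(np.prod(self.x_shape[1:-1]))
        out = np.broadcast_to(dy[:, None, :] / spatial, (dy.shape[0], spatial, dy.shape[1]))
        return out.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        self.params["W"] = he_normal(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        self.x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self.x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_smoothing(
    logits: np.ndarray, labels: np.ndarray, smoothing: float = 0.0
) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy with label smoothing; returns (loss, dlogits)."""
    n, k = logits.shape
    p = softmax(logits)
    target = np.full((n, k), smoothing / k, dtype=DTYPE)
    target[np.arange(n), labels] += 1.0 - smoothing
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(target * logp).sum() / n)
    return loss, (p - target) / n


class Sequential:
    """A feed-forward stack with Adam + L2 weight-decay training support."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def trainable(self):
        for layer in self.layers:
            for key in layer.params:
                yield layer, key

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[k].copy() for layer, k in self.trainable()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, k), w in zip(self.trainable(), weights):
            layer.params[k] = w.copy()


class Adam:
    def __init__(self, net: Sequential, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7, weight_decay=0.0):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in net.trainable()]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in net.trainable()]

    def step(self):
        self.t += 1
        for i, (layer, key) in enumerate(self.net.trainable()):
            g = layer.grads[key].astype(DTYPE)
            if self.weight_decay and key == "W":
                g = g + self.weight_decay * layer.params[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[key] = layer.params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
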