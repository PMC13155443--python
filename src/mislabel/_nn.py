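"""Minimal numpy neural-network kernels for the tiny CNN base learners.

Implements just what the ensemble needs: valid-padding convolution via
im2col, ReLU, 2x2 mean pooling, dense layers, softmax cross-entropy, and
mini-batch SGD with optional momentum. Everything is float32, single
threaded, and deterministic given a seed. Forward activations needed for
the backward pass are cached on the layer between calls.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MeanPool2",
    "Flatten",
    "Dense",
    "Network",
    "softmax",
    "sgd_fit",
]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N,OH,OW,k*k*C) patch matrix for a k x k valid conv."""
    N, H, W, C = x.shape
    OH, OW = H - k + 1, W - k + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (N, OH, OW, k, k, C), (s0, s1, s2, s1, s2, s3)
    )
    return np.ascontiguousarray(cols).reshape(N, OH, OW, k * k * C)


class Layer:
    params: tuple[np.ndarray, ...] = ()
    grads: tuple[np.ndarray, ...] = ()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, d: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k x k valid convolution, stride 1, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = k * k * in_ch
        self.k = k
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, out_ch)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = (self.W, self.b)
        self.grads = (np.zeros_like(self.W), np.zeros_like(self.b))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col(x, self.k)
        return self._cols @ self.W + self.b

    def backward(self, d: np.ndarray) -> np.ndarray:
        N, OH, OW, F = d.shape
        P = self.W.shape[0]
        cols2 = self._cols.reshape(-1, P)
        d2 = d.reshape(-1, F)
        self.grads[0][:] = cols2.T @ d2
        self.grads[1][:] = d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(N, OH, OW, self.k, self.k, -1)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i : i + OH, j : j + OW, :] += dcols[:, :, :, i, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, d: np.ndarray) -> np.ndarray:
        return np.where(self._mask, d, 0.0).astype(np.float32)


class MeanPool2(Layer):
    """2x2 mean pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, H, W, C = x.shape
        self._xshape = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, : 2 * H2, : 2 * W2, :]
        return xc.reshape(N, H2, 2, W2, 2, C).mean(axis=(2, 4)).astype(np.float32)

    def backward(self, d: np.ndarray) -> np.ndarray:
        N, H2, W2, C = d.shape
        dx = np.zeros(self._xshape, dtype=np.float32)
        up = np.repeat(np.repeat(d, 2, axis=1), 2, axis=2) * 0.25
        dx[:, : 2 * H2, : 2 * W2, :] = up
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, d: np.ndarray) -> np.ndarray:
        return d.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale=None):
        std = np.sqrt((2.0 if scale is None else scale) / n_in)
        self.W = rng.normal(0, std, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = (self.W, self.b)
        self.grads = (np.zeros_like(self.W), np.zeros_like(self.b))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, d: np.ndarray) -> np.ndarray:
        self.grads[0][:] = self._x.T @ d
        self.grads[1][:] = d.sum(axis=0)
        return d @ self.W.T


class Network:
    """A plain layer stack ending in logits (softmax applied separately)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d: np.ndarray) -> None:
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        probs = [
            softmax(self.forward(X[i : i + batch].astype(np.float32)))
            for i in range(0, len(X), batch)
        ]
        return np.concatenate(probs, axis=0)


def sgd_fit(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    epochs: int,
    learning_rate: float,
    batch_size: int,
    rng: np.random.Generator,
    momentum: float = 0.0,
) -> list[float]:
    """Minimize mean categorical cross-entropy by mini-batch (momentum) SGD.

    Returns the per-epoch mean training loss. ``epochs=0`` leaves the
    network at its initialization.
    """
    X = X.astype(np.float32)
    y = np.asarray(y, dtype=np.int64)
    onehot = np.eye(n_classes, dtype=np.float32)[y]
    velocities = [np.zeros_like(p) for p, _ in net.parameters()]
    history: list[float] = []
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            xb, yb = X[sel], onehot[sel]
            logits = net.forward(xb)
            p = softmax(logits)
            eps = 1e-12
            loss = -np.mean(np.sum(yb * np.log(p + eps), axis=1))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss}; lower the learning rate"
                )
            losses.append(float(loss) * len(sel))
            dlogits = ((p - yb) / len(sel)).astype(np.float32)
            net.backward(dlogits)
            for vel, (param, grad) in zip(velocities, net.parameters()):
                if momentum:
                    vel *= momentum
                    vel -= learning_rate * grad
                    param += vel
                else:
                    param -= learning_rate * grad
        history.append(sum(losses) / n)
    return history
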