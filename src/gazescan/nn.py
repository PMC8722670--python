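"""A compact, fully seeded NumPy CNN engine.

Implements exactly the pieces the scanpath classifier needs: 3x3
same-padding convolutions (im2col + matmul), 2x2 max pooling, inverted
dropout, dense layers, a sigmoid head with binary cross-entropy, and the
Adam optimizer.  Everything is driven by ``numpy.random.Generator``
streams derived from one integer seed, so weight initialisation, batch
shuffling and dropout masks -- and therefore whole training runs -- are
bit-reproducible.

Layout convention: batches are ``(N, H, W, C)`` float32 arrays.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

_EPS = 1e-7


class Layer:
    """Minimal layer protocol: forward caches what backward needs."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or k x k) convolution, stride 1, zero 'same' padding, He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = kernel * kernel * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        n, h, w = x.shape[0], x.shape[1], x.shape[2]
        return np.ascontiguousarray(win).reshape(n * h * w, k * k * self.in_ch)

    def forward(self, x, train, rng):
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout):
        n, h, w, c = self._shape
        k, p = self.kernel, self.kernel // 2
        dflat = dout.reshape(n * h * w, self.out_ch)
        self.grads["W"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2x2(Layer):
    """2x2 max pooling; ties route their gradient to the first maximum."""

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dims")
        tiles = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        tiles = tiles.reshape(n, h // 2, w // 2, 4, c)
        self._arg = tiles.argmax(axis=3)
        self._in_shape = x.shape
        return tiles.max(axis=3)

    def backward(self, dout):
        n, h, w, c = self._in_shape
        dtiles = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dtiles, self._arg[..., None, :], dout[..., None, :], axis=3)
        dx = dtiles.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)


class Dropout(Layer):
    """Inverted dropout: identity at inference, seeded mask in training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(n_out, np.float32)}

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Adam:
    def __init__(self, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict = {}
        self._v: dict = {}
        self._t = 0

    def step(self, layers: Sequence[Layer]) -> None:
        self._t += 1
        for li, layer in enumerate(layers):
            for name, param in layer.params.items():
                key = (li, name)
                g = layer.grads[name].astype(np.float32)
                m = self._m.get(key, np.zeros_like(param))
                v = self._v.get(key, np.zeros_like(param))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self._m[key], self._v[key] = m, v
                mhat = m / (1 - self.beta1 ** self._t)
                vhat = v / (1 - self.beta2 ** self._t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, lr: float = 1e-2, **_):
        self.lr = lr

    def step(self, layers: Sequence[Layer]) -> None:
        for layer in layers:
            for name, param in layer.params.items():
                param -= self.lr * layer.grads[name]


class SequentialNet:
    """A feed-forward stack with a sigmoid/BCE head.

    ``seed`` fixes initial weights; a separate stream drawn per
    ``fit_epoch`` call fixes shuffling and dropout, so identical seeds give
    identical loss trajectories.
    """

    def __init__(self, layers: Sequence[Layer], optimizer) -> None:
        self.layers = list(layers)
        self.optimizer = optimizer

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return sigmoid(out[:, 0])

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(probs) if probs else np.empty(0)

    def n_parameters(self) -> int:
        return sum(int(p.size) for l in self.layers for p in l.params.values())

    def fit_epoch(
        self,
        x: np.ndarray,
        y: np.ndarray,
        batch_size: int,
        rng: np.random.Generator,
    ) -> float:
        """One epoch of minibatch training; returns the mean training loss."""
        order = rng.permutation(len(x))
        total, count = 0.0, 0
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            prob = self.forward(xb, train=True, rng=rng)
            total += bce_loss(prob, yb) * len(idx)
            count += len(idx)
            # d(BCE)/d(logit) = (p - y) / n
            dlogit = ((prob - yb) / len(idx)).astype(np.float32)[:, None]
            dout = dlogit
            for layer in reversed(self.layers):
                dout = layer.backward(dout)
            self.optimizer.step(self.layers)
        return total / max(count, 1)

    def get_weights(self) -> list[dict]:
        return [
            {k: v.copy() for k, v in layer.params.items()} for layer in self.layers
        ]

    def set_weights(self, weights: list[dict]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]
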