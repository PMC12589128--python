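"""Minimal numpy neural-net layers for 1-D sequence models.

Implements exactly what the enhancer classifier needs: 1-D convolution
with 'same' padding, batch normalization, ReLU, max pooling, dense layers,
dropout, softmax cross-entropy with label smoothing, and Adam.  Forward
and backward passes are hand-written; the backward pass also propagates
gradients to the input, which the attribution code relies on.

Tensors are (batch, channels, length) for convolutional stages and
(batch, features) after flattening.
"""
from __future__ import annotations

import numpy as np


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k))
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.params = {
            "W": rng.normal(0, scale, size=(c_in * k, c_out)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # windows: (n, c, L, k)
        s0, s1, s2 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, L, self.k), strides=(s0, s1, s2, s2)
        )
        return win.transpose(0, 2, 1, 3).reshape(n, L, c * self.k)

    def forward(self, x, train):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.transpose(0, 2, 1)  # (n, c_out, L)

    def backward(self, dout):
        n, _, L = self._x_shape
        d = dout.transpose(0, 2, 1)  # (n, L, c_out)
        self.grads["W"][...] = np.einsum("nlf,nlo->fo", self._cols, d)
        self.grads["b"][...] = d.sum(axis=(0, 1))
        dcols = d @ self.params["W"].T  # (n, L, c_in*k)
        dcols = dcols.reshape(n, L, self.c_in, self.k).transpose(0, 2, 1, 3)
        pl = (self.k - 1) // 2
        dx = np.zeros((n, self.c_in, L + self.k - 1), dtype=dout.dtype)
        for kk in range(self.k):
            dx[:, :, kk : kk + L] += dcols[:, :, :, kk]
        return dx[:, :, pl : pl + L]


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and length axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def _axes(self, x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, v, x):
        return v[None, :, None] if x.ndim == 3 else v[None, :]

    def forward(self, x, train):
        ax = self._axes(x)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - self._shape(mean, x)) / self._shape(self._std, x)
        self._train = train
        return self._shape(self.params["gamma"], x) * self._xhat + self._shape(
            self.params["beta"], x
        )

    def backward(self, dout):
        ax = self._axes(dout)
        m = np.prod([dout.shape[a] for a in ax])
        self.grads["gamma"][...] = (dout * self._xhat).sum(axis=ax)
        self.grads["beta"][...] = dout.sum(axis=ax)
        g = self._shape(self.params["gamma"], dout)
        dxhat = dout * g
        if not self._train:
            return dxhat / self._shape(self._std, dout)
        term = (
            dxhat
            - self._shape(dxhat.sum(axis=ax) / m, dout)
            - self._xhat * self._shape((dxhat * self._xhat).sum(axis=ax) / m, dout)
        )
        return term / self._shape(self._std, dout)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (size = stride); remainder dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        n, c, L = x.shape
        Lo = L // self.size
        self._in_shape = x.shape
        xv = x[:, :, : Lo * self.size].reshape(n, c, Lo, self.size)
        self._arg = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, dout):
        n, c, L = self._in_shape
        Lo = L // self.size
        dx = np.zeros((n, c, Lo, self.size), dtype=dout.dtype)
        ii, jj, kk = np.meshgrid(
            np.arange(n), np.arange(c), np.arange(Lo), indexing="ij"
        )
        dx[ii, jj, kk, self._arg] = dout
        out = np.zeros((n, c, L), dtype=dout.dtype)
        out[:, :, : Lo * self.size] = dx.reshape(n, c, Lo * self.size)
        return out


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0, scale, size=(n_in, n_out)).astype(np.float32), "b": np.zeros(n_out, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray, n_classes: int, smoothing: float = 0.1
) -> tuple[float, np.ndarray]:
    """Label-smoothed cross-entropy loss and gradient wrt logits."""
    p = softmax(logits)
    t = np.full((len(y), n_classes), smoothing / n_classes)
    t[np.arange(len(y)), y] += 1 - smoothing
    loss = float(-(t * np.log(np.clip(p, 1e-12, None))).sum(axis=1).mean())
    return loss, (p - t) / len(y)


class Adam:
    def __init__(self, layers, lr: float = 0.01, b1=0.9, b2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mh = self.m[i][k] / (1 - self.b1**self.t)
                vh = self.v[i][k] / (1 - self.b2**self.t)
                layer.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class Sequential:
    """A stack of layers with manual forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Propagate an output gradient back to the input and return it."""
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """d logit[class] / d input, evaluated in inference mode."""
        logits = self.forward(x, train=False)
        dout = np.zeros_like(logits)
        dout[:, class_index] = 1.0
        return self.backward(dout)
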