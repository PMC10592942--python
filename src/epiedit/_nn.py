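"""Minimal 1-D convolutional network engine (numpy, hand-written backprop).

Implements exactly the layers the expression CNN needs: batch
normalization over channels, ReLU, same-padded 1-D convolution, inverted
dropout, max-pooling with width/stride 2, and dense layers, trained with
Adam on a mean-squared-error loss.  All randomness (initialization,
dropout masks, minibatch order) flows from a single numpy Generator, so
training is bit-reproducible given a seed.

Activations are kept channels-last, (batch, length, channels), in float32:
a same-padded convolution is then K shifted (B, L, Cin) @ (Cin, Cout)
matrix products with no transposes, which keeps the work inside BLAS.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

DTYPE = np.float32


class Layer:
    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> Dict[str, np.ndarray]:
        return {}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            getattr(self, k)[...] = v


class Conv1d(Layer):
    """Same-padded 1-D convolution, (B, L, Cin) -> (B, L, Cout)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))  # He initialization
        self.W = rng.normal(0.0, scale, size=(k, c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def state(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train):
        B, L, Cin = x.shape
        pad = self.k // 2
        xp = np.zeros((B, L + 2 * pad, Cin), dtype=DTYPE)
        xp[:, pad : pad + L] = x
        # contiguous copies of the K shifted views, reused by backward
        cols = np.stack([xp[:, k : k + L] for k in range(self.k)])
        self._cols, self._L, self._B = cols, L, B
        out = np.broadcast_to(self.b, (B, L, self.W.shape[2])).copy()
        tmp = np.empty_like(out)
        for k in range(self.k):
            np.matmul(cols[k], self.W[k], out=tmp)
            out += tmp
        return out

    def backward(self, dout):
        L, B = self._L, self._B
        cols = self._cols
        pad = self.k // 2
        flat_dout = dout.reshape(-1, dout.shape[2])
        dxp = np.zeros((B, L + 2 * pad, cols.shape[3]), dtype=DTYPE)
        for k in range(self.k):
            self.dW[k] = cols[k].reshape(-1, cols.shape[3]).T @ flat_dout
            dxp[:, k : k + L] += dout @ self.W[k].T
        self.db[...] = flat_dout.sum(axis=0)
        return dxp[:, pad : pad + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros(channels, dtype=DTYPE)
        self.dbeta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train):
        if train:
            n = x.shape[0] * x.shape[1]
            mean = x.mean(axis=(0, 1))
            # one-pass variance: E[x^2] - E[x]^2
            var = np.einsum("blc,blc->c", x, x, optimize=True) / n - mean * mean
            np.maximum(var, 0.0, out=var)
            m = DTYPE(self.momentum)
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv, n = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma
        # standard batchnorm backward, reduced over (batch, length)
        dx = (inv / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 1), keepdims=True)
        )
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape, dtype=np.float32) >= self.p
        self._mask = keep.astype(DTYPE) / DTYPE(1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1d(Layer):
    """Max pooling with width and stride 2; a trailing odd element is dropped."""

    def forward(self, x, train):
        B, L, C = x.shape
        L2 = L // 2
        a, b = x[:, 0 : 2 * L2 : 2], x[:, 1 : 2 * L2 : 2]
        self._left = a >= b  # ties go left
        self._shape = (B, L, C)
        return np.maximum(a, b)

    def backward(self, dout):
        B, L, C = self._shape
        L2 = L // 2
        dx = np.zeros((B, L, C), dtype=DTYPE)
        left = self._left
        dx[:, 0 : 2 * L2 : 2] = dout * left
        dx[:, 1 : 2 * L2 : 2] = dout * ~left
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def state(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Adam:
    def __init__(self, params: List[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = DTYPE(self.beta1), DTYPE(self.beta2)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / DTYPE(1 - self.beta1 ** self.t)
            vhat = v / DTYPE(1 - self.beta2 ** self.t)
            p -= DTYPE(self.lr) * mhat / (np.sqrt(vhat) + DTYPE(self.eps))


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def params(self) -> List[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def state(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            for k, v in l.state().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            sub = {k.split(".", 1)[1]: v for k, v in state.items()
                   if k.startswith(f"{i}.")}
            l.load_state(sub)


def build_cnn(
    n_marks: int,
    width: int,
    rng: np.random.Generator,
    n_blocks: int = 5,
    kernels: int = 32,
    kernel_width: int = 5,
    dropout: float = 0.1,
    pool: int = 2,
    fc_units: int = 16,
) -> Tuple[Sequential, int]:
    """Assemble the expression CNN and return (network, flattened width).

    Each block is batchnorm -> ReLU -> conv -> dropout -> maxpool; the head
    is flatten -> dense(fc_units) -> ReLU -> dense(1).
    """
    if width < pool ** n_blocks:
        raise ValueError(f"window width {width} too small for {n_blocks} pooling blocks")
    layers: List[Layer] = []
    c, L = n_marks, width
    for _ in range(n_blocks):
        layers += [
            BatchNorm1d(c),
            ReLU(),
            Conv1d(c, kernels, kernel_width, rng),
            Dropout(dropout, rng),
            MaxPool1d(),
        ]
        c = kernels
        L //= pool
    flat = c * L
    layers += [Flatten(), Dense(flat, fc_units, rng), ReLU(), Dense(fc_units, 1, rng)]
    return Sequential(layers), flat


def _to_channels_last(X: np.ndarray) -> np.ndarray:
    """(B, marks, W) model-facing layout -> (B, W, marks) engine layout."""
    return np.ascontiguousarray(X.transpose(0, 2, 1), dtype=DTYPE)


def train_mse(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    schedule: List[Tuple[int, float]],
    batch_size: int = 64,
) -> List[float]:
    """Train with minibatch Adam on MSE; returns per-epoch training losses.

    ``X`` is (B, marks, W); ``schedule`` is a list of (epochs, learning
    rate) stages.  Adam moments persist across stages, only the step size
    changes.
    """
    Xc = _to_channels_last(X)
    yc = np.asarray(y, dtype=DTYPE)
    n = Xc.shape[0]
    losses: List[float] = []
    opt = Adam(net.params(), lr=schedule[0][1])
    for epochs, lr in schedule:
        opt.lr = lr
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for s in range(0, n, batch_size):
                idx = order[s : s + batch_size]
                xb, yb = Xc[idx], yc[idx]
                pred = net.forward(xb, train=True)[:, 0]
                err = pred - yb
                total += float(err @ err)
                net.backward((2.0 * err / DTYPE(idx.size))[:, None])
                opt.step(net.grads())
            losses.append(total / n)
    return losses


def predict(net: Sequential, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    Xc = _to_channels_last(X)
    out = np.empty(X.shape[0])
    for s in range(0, X.shape[0], batch_size):
        out[s : s + batch_size] = net.forward(Xc[s : s + batch_size], train=False)[:, 0]
    return out
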