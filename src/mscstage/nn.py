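"""Minimal NumPy convolutional network used by the staging models.

Architecture (fixed, the "small CNN" configuration): an input
convolution block and one hidden convolution block (3x3 valid
convolutions with 16 and 32 filters, each followed by ReLU and 2x2 max
pooling), then a dense output layer — softmax over 5 classes for
classification or a single linear unit for regression. Training is
mini-batch Adam on categorical cross-entropy or mean squared error.

Everything is deterministic given the seed; there is no threading and no
global random state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, L) patch matrix for valid convolution."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo), (ho, wo)


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _im2col(x)
        self._cols = np.ascontiguousarray(cols)
        self._in_shape = x.shape
        out = np.matmul(self.W[None], self._cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, ho, wo = dout.shape
        d = np.ascontiguousarray(dout.reshape(n, f, ho * wo))
        self.dW = np.matmul(d, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = d.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], d)  # (N, C*9, L)
        _, c, h, w = self._in_shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dcols = dcols.reshape(n, c, 3, 3, ho, wo)
        for di in range(3):
            for dj in range(3):
                dx[:, :, di : di + ho, dj : dj + wo] += dcols[:, :, di, dj]
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        xq = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = xq.argmax(axis=-1)
        self._in_shape = x.shape
        return xq.max(axis=-1)

    def backward(self, dout):
        n, c, h2, w2 = dout.shape
        dq = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dq, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dq.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = dxr.reshape(n, c, 2 * h2, 2 * w2)
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(layers):
            for name, p, _ in layer.params():
                self.m[(li, name)] = np.zeros_like(p)
                self.v[(li, name)] = np.zeros_like(p)

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, p, gname in layer.params():
                g = getattr(layer, gname)
                m = self.m[(li, name)]
                v = self.v[(li, name)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                mh = m / (1 - self.b1**self.t)
                vh = v / (1 - self.b2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """The 4-layer trunk+head network (see module docstring)."""

    def __init__(
        self,
        in_channels: int,
        input_side: int,
        n_out: int,
        task: str,
        filters: tuple[int, int] = (16, 32),
        seed: int = 0,
    ) -> None:
        if task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        rng = np.random.default_rng(seed)
        f1, f2 = filters
        side1 = (input_side - 2) // 2
        side2 = (side1 - 2) // 2
        if side2 < 1:
            raise ValueError(f"input_side {input_side} too small for the architecture")
        self.task = task
        self.layers = [
            _Conv3x3(in_channels, f1, rng),
            _ReLU(),
            _MaxPool2(),
            _Conv3x3(f1, f2, rng),
            _ReLU(),
            _MaxPool2(),
            _Flatten(),
            _Dense(f2 * side2 * side2, n_out, rng),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def _backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass; gradients left in the layers."""
        z = self.forward(x)
        n = x.shape[0]
        if self.task == "classification":
            p = _softmax(z)
            eps = 1e-12
            loss = -np.log(p[np.arange(n), y] + eps).mean()
            dz = p
            dz[np.arange(n), y] -= 1.0
            dz /= n
        else:
            yv = y.reshape(n, -1)
            diff = z - yv
            loss = float((diff**2).mean())
            dz = 2.0 * diff / diff.size
        self._backward(dz)
        return float(loss)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 25,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        """Mini-batch Adam training; returns per-epoch mean losses."""
        opt = _Adam(self.layers, lr=lr)
        n = x.shape[0]
        losses = []
        from .splits import shuffle_batches

        for epoch in range(epochs):
            order = shuffle_batches(n, seed=seed, epoch=epoch)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                epoch_loss += self.loss_and_grad(x[idx], y[idx])
                opt.step()
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        return losses

    def predict_raw(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)
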