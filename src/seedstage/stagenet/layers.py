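"""Differentiable layer primitives (numpy, NHWC, float32).

Each layer caches what its backward pass needs; ``backward`` returns the
input gradient and fills ``self.grads`` with parameter gradients keyed like
``self.params``.  Convolutions are same-padding im2col matmuls so the heavy
lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense",
           "Dropout", "conv2d_same", "conv2d_same_backward",
           "uniform_init"]


def uniform_init(rng: np.random.Generator, shape, fan_in: int,
                 fan_out: int | None = None) -> np.ndarray:
    """Fan-based uniform initialisation.

    He-uniform U(+/- sqrt(6/fan_in)) when only ``fan_in`` is given (weights
    feeding a ReLU, where it preserves activation variance through deep
    stacks); Glorot-uniform U(+/- sqrt(6/(fan_in+fan_out))) when ``fan_out``
    is supplied (recurrent and softmax-output weights).
    """
    denom = fan_in if fan_out is None else fan_in + fan_out
    lim = float(np.sqrt(6.0 / denom))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


# -- functional convolution (shared with the ConvLSTM cell) -----------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patches with same-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    col = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, w, -1)
    return np.ascontiguousarray(col)


def conv2d_same(x: np.ndarray, weight: np.ndarray,
                col: np.ndarray | None = None):
    """Same-padding 2-D convolution (cross-correlation), stride 1.

    ``weight`` has shape (k, k, C_in, C_out).  Returns ``(y, col)`` where
    ``col`` is the im2col patch matrix needed by the backward pass (pass it
    back in to reuse patches when convolving the same input twice).
    """
    k = weight.shape[0]
    if col is None:
        col = _im2col(np.asarray(x, dtype=np.float32), k)
    n, h, w, _ = col.shape
    wmat = weight.reshape(-1, weight.shape[-1])
    y = col.reshape(n * h * w, -1) @ wmat
    return y.reshape(n, h, w, -1), col


def conv2d_same_backward(dy: np.ndarray, col: np.ndarray, weight: np.ndarray,
                         input_shape) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``conv2d_same``: returns (dx, dweight)."""
    k = weight.shape[0]
    n, h, w, cin = input_shape
    cout = weight.shape[-1]
    dyf = dy.reshape(-1, cout)
    colf = col.reshape(-1, col.shape[-1])
    dweight = (colf.T @ dyf).reshape(weight.shape)
    dcol = (dyf @ weight.reshape(-1, cout).T).reshape(n, h, w, k, k, cin)
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, cin), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, i, j, :]
    return dxp[:, p:p + h, p:p + w, :], dweight


# -- layers -----------------------------------------------------------------

class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train: bool = False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.params["weight"] = uniform_init(
            rng, (kernel, kernel, c_in, c_out), kernel * kernel * c_in)
        self.params["bias"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        y, self._col = conv2d_same(x, self.params["weight"])
        return y + self.params["bias"]

    def backward(self, dy):
        dx, dw = conv2d_same_backward(dy, self._col, self.params["weight"],
                                      self._shape)
        self.grads["weight"] = dw
        self.grads["bias"] = dy.sum(axis=(0, 1, 2))
        self._col = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32, copy=False)


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        mh, mw = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :2 * mh, :2 * mw, :].reshape(n, mh, 2, mw, 2, c)
        xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, mh, mw, 4, c)
        self._argmax = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._argmax[:, :, :, None, :],
                                  axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        mh, mw = h // 2, w // 2
        dxr = np.zeros((n, mh, mw, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :2 * mh, :2 * mw, :] = (
            dxr.reshape(n, mh, mw, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, 2 * mh, 2 * mw, c))
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 glorot: bool = False):
        super().__init__()
        self.params["weight"] = uniform_init(rng, (n_in, n_out), n_in,
                                             n_out if glorot else None)
        self.params["bias"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dy):
        self.grads["weight"] = self._x.T @ dy
        self.grads["bias"] = dy.sum(axis=0)
        dx = dy @ self.params["weight"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask
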