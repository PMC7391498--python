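"""Peephole LSTM and ConvLSTM cells with backpropagation through time.

Gate equations (element-wise products throughout, ``s`` the logistic
sigmoid)::

    i_t = s(W_xi x_t + W_hi h_{t-1} + w_ci * c_{t-1} + b_i)
    f_t = s(W_xf x_t + W_hf h_{t-1} + w_cf * c_{t-1} + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = s(W_xo x_t + W_ho h_{t-1} + w_co * c_peep + b_o)
    h_t = o_t * tanh(c_t)

The output-gate peephole reads the *previous* cell state by default
(``c_peep = c_{t-1}``); many implementations use the freshly computed
``c_t`` instead — switch with ``output_peephole="new"``.  Peephole weights
are element-wise vectors (a diagonal matrix), per unit for the LSTM and per
channel (broadcast over space) for the ConvLSTM, so the ConvLSTM collapses
exactly onto the LSTM at 1x1 spatial extent with 1x1 kernels.

The ConvLSTM replaces every ``W x`` product by a same-padding 2-D
convolution; inputs, states and gates are then (rows, cols, channels)
tensors and the cell state of a grid location is driven by its local
spatial neighbourhood.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .layers import Layer, conv2d_same, conv2d_same_backward, uniform_init

__all__ = ["LSTMWeights", "ConvLSTMWeights", "lstm_step", "convlstm_step",
           "LSTMLayer", "ConvLSTMLayer"]

_GATES = ("i", "f", "c", "o")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclasses.dataclass
class LSTMWeights:
    """Dense peephole-LSTM parameters.

    ``w_x*`` are (input_dim, units), ``w_h*`` (units, units), peepholes
    ``w_c*`` and biases ``b_*`` (units,).  There is no cell peephole on the
    candidate (``c``) path.
    """

    w_xi: np.ndarray; w_hi: np.ndarray; w_ci: np.ndarray; b_i: np.ndarray
    w_xf: np.ndarray; w_hf: np.ndarray; w_cf: np.ndarray; b_f: np.ndarray
    w_xc: np.ndarray; w_hc: np.ndarray; b_c: np.ndarray
    w_xo: np.ndarray; w_ho: np.ndarray; w_co: np.ndarray; b_o: np.ndarray

    @classmethod
    def init(cls, input_dim: int, units: int, rng: np.random.Generator):
        def wx():
            return uniform_init(rng, (input_dim, units), input_dim, units)

        def wh():
            return uniform_init(rng, (units, units), units, units)

        def vec():
            return np.zeros(units, dtype=np.float32)

        return cls(w_xi=wx(), w_hi=wh(), w_ci=vec(), b_i=vec(),
                   w_xf=wx(), w_hf=wh(), w_cf=vec(),
                   b_f=np.ones(units, dtype=np.float32),  # open forget gate
                   w_xc=wx(), w_hc=wh(), b_c=vec(),
                   w_xo=wx(), w_ho=wh(), w_co=vec(), b_o=vec())


@dataclasses.dataclass
class ConvLSTMWeights:
    """ConvLSTM parameters: input kernels (k, k, c_in, filters), recurrent
    kernels (k, k, filters, filters), per-channel peepholes and biases
    (filters,)."""

    w_xi: np.ndarray; w_hi: np.ndarray; w_ci: np.ndarray; b_i: np.ndarray
    w_xf: np.ndarray; w_hf: np.ndarray; w_cf: np.ndarray; b_f: np.ndarray
    w_xc: np.ndarray; w_hc: np.ndarray; b_c: np.ndarray
    w_xo: np.ndarray; w_ho: np.ndarray; w_co: np.ndarray; b_o: np.ndarray

    @classmethod
    def init(cls, c_in: int, filters: int, kernel: int,
             rng: np.random.Generator):
        def wx():
            return uniform_init(rng, (kernel, kernel, c_in, filters),
                                kernel * kernel * c_in,
                                kernel * kernel * filters)

        def wh():
            return uniform_init(rng, (kernel, kernel, filters, filters),
                                kernel * kernel * filters,
                                kernel * kernel * filters)

        def vec():
            return np.zeros(filters, dtype=np.float32)

        return cls(w_xi=wx(), w_hi=wh(), w_ci=vec(), b_i=vec(),
                   w_xf=wx(), w_hf=wh(), w_cf=vec(),
                   b_f=np.ones(filters, dtype=np.float32),
                   w_xc=wx(), w_hc=wh(), b_c=vec(),
                   w_xo=wx(), w_ho=wh(), w_co=vec(), b_o=vec())


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------

def _lstm_step_full(x, h_prev, c_prev, w: LSTMWeights,
                    output_peephole: str = "prev"):
    i = _sigmoid(x @ w.w_xi + h_prev @ w.w_hi + c_prev * w.w_ci + w.b_i)
    f = _sigmoid(x @ w.w_xf + h_prev @ w.w_hf + c_prev * w.w_cf + w.b_f)
    g = np.tanh(x @ w.w_xc + h_prev @ w.w_hc + w.b_c)
    c = f * c_prev + i * g
    c_peep = c_prev if output_peephole == "prev" else c
    o = _sigmoid(x @ w.w_xo + h_prev @ w.w_ho + c_peep * w.w_co + w.b_o)
    tc = np.tanh(c)
    h = o * tc
    cache = (x, h_prev, c_prev, i, f, g, c, o, tc)
    return h, c, cache


def lstm_step(x, h_prev, c_prev, w: LSTMWeights,
              output_peephole: str = "prev"):
    """One peephole-LSTM step; returns ``(h, c)``.

    Inputs may be single vectors or batches (leading batch axis).
    """
    h, c, _ = _lstm_step_full(np.atleast_2d(np.asarray(x, dtype=np.float64)),
                              np.atleast_2d(h_prev), np.atleast_2d(c_prev),
                              w, output_peephole)
    if np.asarray(x).ndim == 1:
        return h[0], c[0]
    return h, c


def _convlstm_step_full(x, h_prev, c_prev, w: ConvLSTMWeights,
                        output_peephole: str = "prev"):
    ax_i, col_x = conv2d_same(x, w.w_xi)
    ax_f, _ = conv2d_same(x, w.w_xf, col=col_x)
    ax_c, _ = conv2d_same(x, w.w_xc, col=col_x)
    ax_o, _ = conv2d_same(x, w.w_xo, col=col_x)
    ah_i, col_h = conv2d_same(h_prev, w.w_hi)
    ah_f, _ = conv2d_same(h_prev, w.w_hf, col=col_h)
    ah_c, _ = conv2d_same(h_prev, w.w_hc, col=col_h)
    ah_o, _ = conv2d_same(h_prev, w.w_ho, col=col_h)
    i = _sigmoid(ax_i + ah_i + c_prev * w.w_ci + w.b_i)
    f = _sigmoid(ax_f + ah_f + c_prev * w.w_cf + w.b_f)
    g = np.tanh(ax_c + ah_c + w.b_c)
    c = f * c_prev + i * g
    c_peep = c_prev if output_peephole == "prev" else c
    o = _sigmoid(ax_o + ah_o + c_peep * w.w_co + w.b_o)
    tc = np.tanh(c)
    h = o * tc
    cache = (x, h_prev, c_prev, i, f, g, c, o, tc, col_x, col_h)
    return h, c, cache


def convlstm_step(x, h_prev, c_prev, w: ConvLSTMWeights,
                  output_peephole: str = "prev"):
    """One ConvLSTM step on (rows, cols, channels) tensors (or batches of
    them); returns ``(H, C)``."""
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x, h_prev, c_prev = x[None], np.asarray(h_prev)[None], np.asarray(c_prev)[None]
    h, c, _ = _convlstm_step_full(x, np.asarray(h_prev, dtype=np.float32),
                                  np.asarray(c_prev, dtype=np.float32),
                                  w, output_peephole)
    return (h[0], c[0]) if single else (h, c)


# ---------------------------------------------------------------------------
# sequence layers with BPTT
# ---------------------------------------------------------------------------

class LSTMLayer(Layer):
    """Runs the peephole LSTM over (B, T, D) inputs, zero initial state."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 output_peephole: str = "prev"):
        super().__init__()
        self.units = units
        self.output_peephole = output_peephole
        w = LSTMWeights.init(input_dim, units, rng)
        self.params = {f.name: getattr(w, f.name)
                       for f in dataclasses.fields(w)}

    @property
    def weights(self) -> LSTMWeights:
        return LSTMWeights(**self.params)

    def forward(self, x, train=False, rng=None, initial_state=None):
        b, t, _ = x.shape
        w = self.weights
        if initial_state is None:
            h = np.zeros((b, self.units), dtype=np.float32)
            c = np.zeros((b, self.units), dtype=np.float32)
        else:
            h, c = initial_state
        self._caches, hs = [], np.empty((b, t, self.units), dtype=np.float32)
        for step in range(t):
            h, c, cache = _lstm_step_full(x[:, step], h, c, w,
                                          self.output_peephole)
            self._caches.append(cache)
            hs[:, step] = h
        self.final_state = (np.asarray(h, dtype=np.float32).copy(),
                            np.asarray(c, dtype=np.float32).copy())
        return hs

    def backward(self, dy):
        w = self.weights
        b, t, u = dy.shape
        grads = {k: np.zeros_like(v, dtype=np.float64)
                 for k, v in self.params.items()}
        dx = np.empty((b, t, w.w_xi.shape[0]), dtype=np.float32)
        dh_next = np.zeros((b, u))
        dc_next = np.zeros((b, u))
        peep_prev = self.output_peephole == "prev"
        for step in reversed(range(t)):
            x, h_prev, c_prev, i, f, g, c, o, tc = self._caches[step]
            dh = dy[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            da_o = do * o * (1.0 - o)
            if peep_prev:
                dc_prev_peep = da_o * w.w_co
            else:
                dc = dc + da_o * w.w_co
                dc_prev_peep = 0.0
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_prev = dc * f + dc_prev_peep
            da_i = di * i * (1.0 - i)
            da_f = df * f * (1.0 - f)
            da_c = dg * (1.0 - g ** 2)
            dc_prev = dc_prev + da_i * w.w_ci + da_f * w.w_cf
            grads["w_ci"] += (da_i * c_prev).sum(0)
            grads["w_cf"] += (da_f * c_prev).sum(0)
            grads["w_co"] += (da_o * (c_prev if peep_prev else c)).sum(0)
            for name, da in zip(_GATES, (da_i, da_f, da_c, da_o)):
                grads[f"w_x{name}"] += x.T @ da
                grads[f"w_h{name}"] += h_prev.T @ da
                grads[f"b_{name}"] += da.sum(0)
            dx[:, step] = (da_i @ w.w_xi.T + da_f @ w.w_xf.T
                           + da_c @ w.w_xc.T + da_o @ w.w_xo.T)
            dh_next = (da_i @ w.w_hi.T + da_f @ w.w_hf.T
                       + da_c @ w.w_hc.T + da_o @ w.w_ho.T)
            dc_next = dc_prev
        self.grads = {k: v.astype(np.float32) for k, v in grads.items()}
        self._caches = None
        return dx


class ConvLSTMLayer(Layer):
    """Runs the ConvLSTM over (B, T, H, W, C) inputs, zero initial state."""

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator, output_peephole: str = "prev"):
        super().__init__()
        self.filters = filters
        self.kernel = kernel
        self.output_peephole = output_peephole
        w = ConvLSTMWeights.init(c_in, filters, kernel, rng)
        self.params = {f.name: getattr(w, f.name)
                       for f in dataclasses.fields(w)}

    @property
    def weights(self) -> ConvLSTMWeights:
        return ConvLSTMWeights(**self.params)

    def forward(self, x, train=False, rng=None, initial_state=None):
        b, t, hh, ww, _ = x.shape
        w = self.weights
        if initial_state is None:
            h = np.zeros((b, hh, ww, self.filters), dtype=np.float32)
            c = np.zeros_like(h)
        else:
            h, c = initial_state
        self._caches = []
        hs = np.empty((b, t, hh, ww, self.filters), dtype=np.float32)
        for step in range(t):
            h, c, cache = _convlstm_step_full(
                np.asarray(x[:, step], dtype=np.float32), h, c, w,
                self.output_peephole)
            self._caches.append(cache)
            hs[:, step] = h
        self.final_state = (h.copy(), c.copy())
        return hs

    def backward(self, dy):
        w = self.weights
        b, t = dy.shape[:2]
        grads = {k: np.zeros_like(v, dtype=np.float64)
                 for k, v in self.params.items()}
        dx = None
        dh_next = np.zeros(dy.shape[0:1] + dy.shape[2:], dtype=np.float32)
        dc_next = np.zeros_like(dh_next)
        peep_prev = self.output_peephole == "prev"
        sum_sp = (0, 1, 2)
        for step in reversed(range(t)):
            x, h_prev, c_prev, i, f, g, c, o, tc, col_x, col_h = \
                self._caches[step]
            if dx is None:
                dx = np.empty((b, t) + x.shape[1:], dtype=np.float32)
            dh = dy[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            da_o = do * o * (1.0 - o)
            if peep_prev:
                dc_prev_peep = da_o * w.w_co
            else:
                dc = dc + da_o * w.w_co
                dc_prev_peep = 0.0
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_prev = dc * f + dc_prev_peep
            da_i = (di * i * (1.0 - i)).astype(np.float32)
            da_f = (df * f * (1.0 - f)).astype(np.float32)
            da_c = (dg * (1.0 - g ** 2)).astype(np.float32)
            da_o = da_o.astype(np.float32)
            dc_prev = dc_prev + da_i * w.w_ci + da_f * w.w_cf
            grads["w_ci"] += (da_i * c_prev).sum(sum_sp)
            grads["w_cf"] += (da_f * c_prev).sum(sum_sp)
            grads["w_co"] += (da_o * (c_prev if peep_prev else c)).sum(sum_sp)
            dxs = np.zeros(x.shape, dtype=np.float32)
            dhs = np.zeros(h_prev.shape, dtype=np.float32)
            for name, da in zip(_GATES, (da_i, da_f, da_c, da_o)):
                dxi, dwx = conv2d_same_backward(da, col_x,
                                                self.params[f"w_x{name}"],
                                                x.shape)
                dxs += dxi
                grads[f"w_x{name}"] += dwx
                dhi, dwh = conv2d_same_backward(da, col_h,
                                                self.params[f"w_h{name}"],
                                                h_prev.shape)
                dhs += dhi
                grads[f"w_h{name}"] += dwh
                grads[f"b_{name}"] += da.sum(sum_sp)
            dx[:, step] = dxs
            dh_next = dhs
            dc_next = dc_prev.astype(np.float32)
        self.grads = {k: v.astype(np.float32) for k, v in grads.items()}
        self._caches = None
        return dx
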