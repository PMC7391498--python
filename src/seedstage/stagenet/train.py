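"""Training: softmax cross-entropy minimised with Adam.

The empirical risk over labelled frames (or frame sequences) is the mean
cross-entropy between the softmax output and the annotated stage; it is
minimised with the Adam adaptive-moment optimiser at learning rate 0.001 by
default.  Temporal models are trained by truncated backpropagation through
time on fixed-length chunks (default 32 frames): the recurrent state is zero
at each sequence start and carried forward across the chunks of a sequence
(gradients truncated at chunk boundaries), so full-sequence inference sees
the same state statistics as training.  Memoryless models see shuffled
individual frames.  Everything stochastic
(shuffling, dropout) is driven by ``TrainingConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from ..errors import ConfigurationError
from .network import Model

__all__ = ["TrainingConfig", "Adam", "softmax_cross_entropy", "train_model"]


@dataclasses.dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    epochs: int = 5
    batch_size: int = 32          # frames (memoryless) or sequences (temporal)
    sequence_chunk_len: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 0 or self.batch_size < 1 or self.sequence_chunk_len < 1:
            raise ConfigurationError("invalid training configuration")


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: Model, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[key])
                  for name, layer, key in model.parameters()}
        self.v = {name: np.zeros_like(layer.params[key])
                  for name, layer, key in model.parameters()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, layer, key in self.model.parameters():
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            layer.params[key] -= (self.lr * (m / bc1)
                                  / (np.sqrt(v / bc2) + self.eps))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    flat = logits.reshape(-1, logits.shape[-1]).astype(np.float64)
    y = labels.reshape(-1)
    z = flat - flat.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = flat.shape[0]
    loss = -logp[np.arange(n), y].mean()
    dlogits = np.exp(logp)
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    return loss, dlogits.reshape(logits.shape).astype(np.float32)


def train_model(model: Model, x: np.ndarray, y: np.ndarray,
                config: TrainingConfig):
    """Fit ``model`` in place; returns ``(model, loss_history)``.

    ``x``/``y`` are ``(N, H, W, C)`` / ``(N,)`` for memoryless models and
    ``(S, T, H, W, C)`` / ``(S, T)`` for temporal ones.  ``loss_history`` is
    the mean per-epoch training loss.  ``epochs=0`` is a no-op.  Raises on
    NaN loss; warns when a class is absent from the labels.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0:
        raise ValueError("empty training set")
    present = np.unique(y)
    missing = sorted(set(range(model.spec.n_classes)) - set(present.tolist()))
    if missing:
        warnings.warn(f"classes absent from training labels: {missing}",
                      stacklevel=2)
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0

    rng = np.random.default_rng([config.seed, 13])
    model.rng = np.random.default_rng([config.seed, 17])  # dropout stream
    opt = Adam(model, config.learning_rate)
    history: list[float] = []

    def _step(xb, yb, initial_state=None):
        logits = model.forward(xb, train=True, initial_state=initial_state)
        loss, dlogits = softmax_cross_entropy(logits, yb)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"NaN/inf loss at epoch {len(history)}; lower the "
                f"learning rate")
        model.backward(dlogits)
        opt.step()
        return loss

    if model.is_temporal:
        # truncated BPTT: chunks of each sequence are processed in temporal
        # order with the recurrent state carried across chunk boundaries
        # (gradients truncated there); state is zero at sequence start, so
        # training matches full-sequence inference statistics.
        s, t = x.shape[:2]
        cl = min(config.sequence_chunk_len, t)
        bounds = [(i * cl, min((i + 1) * cl, t))
                  for i in range((t + cl - 1) // cl)]
        for _ in range(config.epochs):
            order = rng.permutation(s)
            losses, weights = [], []
            for start in range(0, s, config.batch_size):
                idx = order[start:start + config.batch_size]
                state = None
                for lo, hi in bounds:
                    loss = _step(x[idx, lo:hi], y[idx, lo:hi], state)
                    state = model.temporal_layer.final_state
                    losses.append(loss)
                    weights.append(len(idx) * (hi - lo))
            history.append(float(np.average(losses, weights=weights)))
    else:
        n = x.shape[0]
        for _ in range(config.epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                losses.append(_step(x[idx], y[idx]))
                weights.append(len(idx))
            history.append(float(np.average(losses, weights=weights)))
    return model, history
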