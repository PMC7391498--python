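"""Network specification and assembly.

The baseline stage classifier is a small AlexNet-like stack: four 3x3
convolutions with 64, 128, 256 and 256 filters, each followed by ReLU and
2x2 max-pooling; then a 512-unit fully connected layer with ReLU and dropout
(p = 0.5) and a softmax output layer.  The temporal variants keep the same
feature extractor and insert either a 128-unit peephole LSTM on the
flattened feature vectors (CNN-LSTM) or a ConvLSTM on the feature maps,
between feature extraction and the classification head.

A ``small`` preset (two conv layers, 32x32 inputs) exists for experiments
where dozens of models must be trained quickly; it is the same code path at
a fraction of the cost.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..errors import ConfigurationError
from .layers import (Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2, ReLU)
from .recurrent import ConvLSTMLayer, LSTMLayer

__all__ = ["NetworkSpec", "Model", "build_network"]


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    ``temporal`` selects the sequence block: ``"none"`` (memoryless CNN),
    ``"lstm"`` (CNN-LSTM) or ``"convlstm"``.  For binary chained models set
    ``n_classes=2`` and ``class_pair`` to the two global stage codes the
    model discriminates.
    """

    conv_filters: tuple[int, ...] = (64, 128, 256, 256)
    kernel_size: int = 3
    dense_units: int = 512
    dropout: float = 0.5
    temporal: str = "none"
    lstm_units: int = 128
    convlstm_filters: int = 64
    convlstm_kernel: int = 3
    n_classes: int = 4
    input_shape: tuple[int, int, int] = (89, 89, 3)
    class_pair: tuple[int, int] | None = None
    output_peephole: str = "prev"

    def __post_init__(self):
        if self.temporal not in ("none", "lstm", "convlstm"):
            raise ConfigurationError(f"unknown temporal block {self.temporal!r}")
        if self.n_classes not in (2, 4):
            raise ConfigurationError("n_classes must be 2 or 4")
        h, w, _ = self.input_shape
        for _ in self.conv_filters:
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ConfigurationError(
                f"input {self.input_shape} too small for "
                f"{len(self.conv_filters)} pooling stages")
        if self.n_classes == 2 and self.class_pair is not None:
            a, b = self.class_pair
            if b != a + 1:
                raise ConfigurationError(
                    "class_pair must be two consecutive stages")

    @property
    def feature_map_shape(self) -> tuple[int, int, int]:
        h, w, _ = self.input_shape
        for _ in self.conv_filters:
            h, w = h // 2, w // 2
        return (h, w, self.conv_filters[-1])

    @classmethod
    def baseline(cls, temporal: str = "none", n_classes: int = 4,
                       class_pair=None) -> "NetworkSpec":
        return cls(temporal=temporal, n_classes=n_classes,
                   class_pair=class_pair)

    @classmethod
    def small(cls, temporal: str = "none", n_classes: int = 4,
              class_pair=None, input_size: int = 32) -> "NetworkSpec":
        return cls(conv_filters=(8, 16), dense_units=64, lstm_units=32,
                   convlstm_filters=8, temporal=temporal, n_classes=n_classes,
                   input_shape=(input_size, input_size, 3),
                   class_pair=class_pair)


class Model:
    """A stage classifier: conv feature extractor, optional temporal block,
    dense classification head.

    Memoryless models take ``(N, H, W, C)`` batches; temporal models take
    ``(B, T, H, W, C)`` sequence batches with the recurrent state zeroed at
    each sequence start.  ``forward`` returns logits; softmax lives in the
    loss / ``predict_proba``.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.rng = np.random.default_rng([seed, 7])
        init_rng = np.random.default_rng([seed, 11])
        c_in = spec.input_shape[2]
        self.feature_layers: list[Layer] = []
        for f in spec.conv_filters:
            self.feature_layers += [Conv2D(c_in, f, spec.kernel_size, init_rng),
                                    ReLU(), MaxPool2()]
            c_in = f
        fh, fw, fc = spec.feature_map_shape
        self.temporal_layer: Layer | None = None
        if spec.temporal == "lstm":
            self.feature_layers.append(Flatten())
            self.temporal_layer = LSTMLayer(fh * fw * fc, spec.lstm_units,
                                            init_rng, spec.output_peephole)
            head_in = spec.lstm_units
        elif spec.temporal == "convlstm":
            self.temporal_layer = ConvLSTMLayer(fc, spec.convlstm_filters,
                                                spec.convlstm_kernel,
                                                init_rng, spec.output_peephole)
            head_in = fh * fw * spec.convlstm_filters
        else:
            self.feature_layers.append(Flatten())
            head_in = fh * fw * fc
        self.head_layers: list[Layer] = [
            Dense(head_in, spec.dense_units, init_rng), ReLU(),
            Dropout(spec.dropout),
            Dense(spec.dense_units, spec.n_classes, init_rng, glorot=True)]

    # -- plumbing ---------------------------------------------------------
    @property
    def is_temporal(self) -> bool:
        return self.temporal_layer is not None

    def layers(self) -> list[Layer]:
        mid = [self.temporal_layer] if self.temporal_layer else []
        return self.feature_layers + mid + self.head_layers

    def parameters(self):
        """(name, layer, key) triples for every trainable array."""
        out = []
        for li, layer in enumerate(self.layers()):
            for key in layer.params:
                out.append((f"layer{li}.{key}", layer, key))
        return out

    def param_count(self) -> int:
        return sum(layer.params[k].size for _, layer, k in self.parameters())

    def conv_filter_counts(self) -> tuple[int, ...]:
        return tuple(l.params["weight"].shape[-1]
                     for l in self.feature_layers if isinstance(l, Conv2D))

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                initial_state=None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if self.is_temporal:
            if x.ndim != 5:
                raise ValueError("temporal model expects (B, T, H, W, C)")
            b, t = x.shape[:2]
            z = x.reshape((b * t,) + x.shape[2:])
            for layer in self.feature_layers:
                z = layer.forward(z, train, self.rng)
            z = z.reshape((b, t) + z.shape[1:])
            z = self.temporal_layer.forward(z, train, self.rng,
                                            initial_state=initial_state)
            self._bt = (b, t)
            z = z.reshape((b * t,) + z.shape[2:])
            if z.ndim > 2:
                self._head_in_shape = z.shape
                z = z.reshape(z.shape[0], -1)
            else:
                self._head_in_shape = None
            for layer in self.head_layers:
                z = layer.forward(z, train, self.rng)
            return z.reshape(b, t, -1)
        if x.ndim != 4:
            raise ValueError("memoryless model expects (N, H, W, C)")
        z = x
        for layer in self.feature_layers:
            z = layer.forward(z, train, self.rng)
        for layer in self.head_layers:
            z = layer.forward(z, train, self.rng)
        return z

    def backward(self, dlogits: np.ndarray) -> None:
        if self.is_temporal:
            b, t = self._bt
            dz = dlogits.reshape(b * t, -1)
            for layer in reversed(self.head_layers):
                dz = layer.backward(dz)
            if self._head_in_shape is not None:
                dz = dz.reshape(self._head_in_shape)
            dz = dz.reshape((b, t) + dz.shape[1:])
            dz = self.temporal_layer.backward(dz)
            dz = dz.reshape((b * t,) + dz.shape[2:])
            for layer in reversed(self.feature_layers):
                dz = layer.backward(dz)
            return
        dz = dlogits
        for layer in reversed(self.head_layers):
            dz = layer.backward(dz)
        for layer in reversed(self.feature_layers):
            dz = layer.backward(dz)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (inference mode, no dropout)."""
        logits = self.forward(x, train=False)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: layer.params[key].copy()
                for name, layer, key in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.parameters():
            layer.params[key][...] = state[name]

    def save(self, path) -> None:
        meta = dataclasses.asdict(self.spec)
        meta = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in meta.items()}
        np.savez(path, __spec__=np.array([repr(meta)], dtype=object),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "Model":
        import ast
        data = np.load(path, allow_pickle=True)
        meta = ast.literal_eval(str(data["__spec__"][0]))
        for k in ("conv_filters", "input_shape", "class_pair"):
            if meta.get(k) is not None:
                meta[k] = tuple(meta[k])
        model = cls(NetworkSpec(**meta), seed=0)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__spec__"})
        return model


def build_network(spec: NetworkSpec, seed: int = 0) -> Model:
    """Initialise a model for ``spec``; weights are uniform fan-in draws
    fully determined by ``seed``."""
    return Model(spec, seed)
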