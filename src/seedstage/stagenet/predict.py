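"""Inference on pot sequences.

``predict_frames`` scores one pot's time-lapse: memoryless CNNs score each
frame independently, temporal models consume the sequence in order with the
recurrent state zeroed at the start.  ``chained_predict`` implements the
ontology-chained binary scheme: three 2-class models M1(Soil, FA),
M2(FA, OC), M3(OC, FL); M1 scans from the start, and at the first frame a
model reports its later stage the scan switches permanently to the next
model (the switch frame itself is re-scored by the new model).  After M3
first reports FL, every remaining frame is FL.  The emitted sequence is
non-decreasing by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..stages import N_STAGES, STAGE_NAMES
from .network import Model

__all__ = ["PredictionTrace", "predict_frames", "chained_predict"]


@dataclasses.dataclass
class PredictionTrace:
    """Per-frame class probabilities and hard labels for one pot sequence."""

    probs: np.ndarray          # (T, 4), rows sum to 1
    labels: np.ndarray         # (T,) stage codes
    frame_indices: np.ndarray  # (T,)
    pot: tuple[int, int, int] | None = None  # (tray, row, col)

    def __post_init__(self):
        if len(self.probs) != len(self.labels) != len(self.frame_indices):
            raise ValueError("trace arrays must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def replace_labels(self, labels: np.ndarray) -> "PredictionTrace":
        return dataclasses.replace(self, labels=np.asarray(labels).copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs,
                          columns=[f"p_{n.lower()}" for n in STAGE_NAMES])
        df.insert(0, "frame", self.frame_indices)
        df["label"] = self.labels
        return df


def _normalise(crops: np.ndarray) -> np.ndarray:
    x = np.asarray(crops)
    if x.size == 0:
        raise ValueError("empty sequence")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32, copy=False)


def predict_frames(model: Model, crops: np.ndarray,
                   frame_indices=None, pot=None) -> PredictionTrace:
    """Score a (T, H, W, C) pot sequence with a 4-class model."""
    x = _normalise(crops)
    if model.is_temporal:
        probs = model.predict_proba(x[None])[0]
    else:
        probs = model.predict_proba(x)
    labels = probs.argmax(axis=1).astype(np.int64)
    t = len(probs)
    idx = np.arange(t) if frame_indices is None else np.asarray(frame_indices)
    return PredictionTrace(probs=probs, labels=labels, frame_indices=idx,
                           pot=pot)


def _embed_binary(p2: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
    out = np.zeros(N_STAGES, dtype=np.float64)
    out[pair[0]], out[pair[1]] = p2[0], p2[1]
    return out


def chained_predict(m1: Model, m2: Model, m3: Model, crops: np.ndarray,
                    frame_indices=None, pot=None) -> PredictionTrace:
    """Ontology-chained prediction with three binary CNNs."""
    models = (m1, m2, m3)
    expected = ((0, 1), (1, 2), (2, 3))
    for m, pair in zip(models, expected):
        if m.spec.n_classes != 2 or m.spec.class_pair != pair:
            raise ConfigurationError(
                f"chained models must have class pairs {expected}, got "
                f"{m.spec.class_pair}")
        if m.is_temporal:
            raise ConfigurationError("chained models must be memoryless CNNs")
    x = _normalise(crops)
    t = len(x)
    probs = np.zeros((t, N_STAGES))
    labels = np.zeros(t, dtype=np.int64)
    active = 0          # index of the current binary model; 3 means locked FL
    # lazy segment scoring: a model is only ever evaluated on the frames of
    # its own tenure (models after the current one are not consulted at all)
    seg_probs: np.ndarray | None = None
    seg_start = 0
    for f in range(t):
        while True:
            if active == 3:
                probs[f] = _embed_binary(np.array([0.0, 1.0]), (2, 3))
                labels[f] = 3
                break
            if seg_probs is None:
                seg_probs = models[active].predict_proba(x[f:])
                seg_start = f
            pair = expected[active]
            p2 = seg_probs[f - seg_start]
            probs[f] = _embed_binary(p2, pair)
            stage = pair[int(p2.argmax())]
            if stage == pair[1]:        # later class detected -> switch
                active += 1
                seg_probs = None        # next model scores from this frame on
                if active < 3:
                    continue            # re-score this frame with next model
                labels[f] = stage       # FL just detected
                break
            labels[f] = stage
            break
    idx = np.arange(t) if frame_indices is None else np.asarray(frame_indices)
    return PredictionTrace(probs=probs, labels=labels, frame_indices=idx,
                           pot=pot)
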