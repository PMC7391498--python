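"""Ontology-aware temporal smoothing of predicted stage sequences.

Frame-level classifiers flicker near stage boundaries (tiny morphological
differences, circadian lobe movement).  Two corrections exploit the fact
that stages are ordinal and irreversible:

1. **Median smoothing** — a sliding window of ``n`` consecutive labels is
   sorted ordinally and the ``floor((n+1)/2)``-th smallest (the lower
   median) replaces the current label; this is majority voting that cannot
   invent a class absent from the window.  The shipped window is 4 frames —
   one hour of observation at the 15-minute cadence.
2. **Monotone (ontology) clamping** — the running maximum of the ordinal
   codes, which removes regressions such as the late FL -> OC flips that
   occur when the first leaf grows out of the crop and only cotyledons
   remain visible: once FL has been reached the stage stays FL.

Window alignment: the default ``"centered"`` window covers
``[t - floor((n-1)/2), t + ceil((n-1)/2)]`` with edge replication at the
sequence boundaries; with the lower-median order statistic this makes the
full post-processing step exactly idempotent.  A ``"trailing"`` window
(ending at the current frame, truncated at the start) is available but
delays every transition by ``n - floor((n+1)/2)`` frames per application
and is therefore not the default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stagenet.predict import PredictionTrace

__all__ = ["SmoothingConfig", "median_smooth", "enforce_monotone",
           "postprocess", "sweep_window_size"]


@dataclasses.dataclass(frozen=True)
class SmoothingConfig:
    window_n: int = 4
    enforce_ontology: bool = True
    alignment: str = "centered"

    def __post_init__(self):
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if self.alignment not in ("centered", "trailing"):
            raise ValueError("alignment must be 'centered' or 'trailing'")


def median_smooth(labels, n: int, alignment: str = "centered") -> np.ndarray:
    """Sliding-window ordinal median (lower median for even ``n``).

    Each output label is the ``floor((n+1)/2)``-th smallest of the window's
    labels.  ``centered`` windows use edge replication; ``trailing`` windows
    end at the current position and are truncated at the sequence start
    (order statistic recomputed for the truncated size).
    """
    if n < 1:
        raise ValueError("window size must be >= 1")
    lab = np.asarray(labels, dtype=np.int64)
    if lab.size == 0:
        raise ValueError("empty label sequence")
    t = lab.size
    out = np.empty(t, dtype=np.int64)
    if alignment == "centered":
        back = (n - 1) // 2
        fwd = n - 1 - back
        padded = np.concatenate([np.full(back, lab[0]), lab,
                                 np.full(fwd, lab[-1])])
        k = (n + 1) // 2            # 1-based rank of the lower median
        win = np.lib.stride_tricks.sliding_window_view(padded, n)
        out[:] = np.sort(win, axis=1)[:, k - 1]
    elif alignment == "trailing":
        for i in range(t):
            m = min(n, i + 1)
            window = np.sort(lab[i - m + 1:i + 1])
            out[i] = window[(m + 1) // 2 - 1]
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    return out


def enforce_monotone(labels) -> np.ndarray:
    """Running maximum of the ordinal codes: forbids developmental
    regressions, keeping e.g. a pot at FL once FL has been reached."""
    lab = np.asarray(labels, dtype=np.int64)
    if lab.size == 0:
        raise ValueError("empty label sequence")
    return np.maximum.accumulate(lab)


def postprocess(trace: PredictionTrace,
                config: SmoothingConfig = SmoothingConfig()) -> PredictionTrace:
    """Median smoothing then (optionally) ontology clamping.

    Probabilities are carried through unchanged; only the hard labels are
    replaced.  Idempotent with the default centered alignment.
    """
    labels = median_smooth(trace.labels, config.window_n, config.alignment)
    if config.enforce_ontology:
        labels = enforce_monotone(labels)
    return trace.replace_labels(labels)


def sweep_window_size(traces: list[PredictionTrace], truth: list[np.ndarray],
                      n_range=range(1, 11),
                      enforce_ontology: bool = True,
                      alignment: str = "centered"):
    """Frame accuracy after post-processing as a function of window size.

    Returns ``(n_star, curve)`` where ``curve`` maps each ``n`` to the
    pooled frame accuracy over all traces and ``n_star`` is the smallest
    ``n`` attaining the maximum.
    """
    if len(traces) != len(truth):
        raise ValueError("traces and truth are misaligned")
    for tr, y in zip(traces, truth):
        if len(tr) != len(np.asarray(y)):
            raise ValueError("trace/truth length mismatch")
    curve: dict[int, float] = {}
    for n in n_range:
        cfg = SmoothingConfig(window_n=n, enforce_ontology=enforce_ontology,
                              alignment=alignment)
        correct = total = 0
        for tr, y in zip(traces, truth):
            sm = postprocess(tr, cfg)
            correct += int((sm.labels == np.asarray(y)).sum())
            total += len(sm)
        curve[n] = correct / total
    best = max(curve.values())
    n_star = min(n for n, a in curve.items() if a == best)
    return n_star, curve
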