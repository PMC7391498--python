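"""Shared fixtures: small synthetic scenes and preprocessed crop tensors.

Everything is generated programmatically; the expensive artifacts (rendered
and background-filtered crop sequences) are session-scoped so several test
modules can share one rendering pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedstage import preprocess as pp
from seedstage import synthgen

#: Transition-delay windows (fractions of the sequence) used by the short
#: training scenes: every germinated pot traverses all four stages.
SHORT_DELAYS = {"t_fa_range": (0.15, 0.3), "fa_dur_range": (0.2, 0.3),
                "oc_dur_range": (0.25, 0.35)}


def preprocess_scene(cfg: synthgen.SceneConfig,
                     schedule: synthgen.StageSchedule,
                     remove_bg: bool = True) -> np.ndarray:
    """Crop every pot of every frame directly from the unrotated canvas.

    Returns (n_trays, rows, cols, T, s, s, 3) uint8.  Bypasses
    rectification on purpose: these fixtures feed classifier tests, and the
    geometric path has its own tests.
    """
    s, m = cfg.pot_size_px, cfg.margin_px
    out = np.empty((cfg.n_trays, cfg.grid_rows, cfg.grid_cols,
                    cfg.frames_total, s, s, 3), dtype=np.uint8)
    for t in range(cfg.n_trays):
        for f in range(cfg.frames_total):
            img = synthgen.render_tray_frame(cfg, schedule, f, tray=t)
            for r in range(cfg.grid_rows):
                for c in range(cfg.grid_cols):
                    crop = img[m + r * s:m + (r + 1) * s,
                               m + c * s:m + (c + 1) * s]
                    out[t, r, c, f] = (pp.remove_background(crop)
                                       if remove_bg else crop)
    return out


@pytest.fixture(scope="session")
def easy_scene():
    """1 tray, 3x4 pots, 48 frames, easy difficulty, full germination."""
    cfg = synthgen.SceneConfig(n_trays=1, grid_rows=3, grid_cols=4,
                               pot_size_px=32, frames_total=48, seed=2,
                               margin_px=30, difficulty="easy")
    schedule = synthgen.sample_stage_schedule(cfg, 1.0, SHORT_DELAYS)
    return cfg, schedule


@pytest.fixture(scope="session")
def easy_crops(easy_scene):
    """Background-filtered crop sequences (12, 48, 32, 32, 3) + labels."""
    cfg, schedule = easy_scene
    crops = preprocess_scene(cfg, schedule)
    n_pots = cfg.grid_rows * cfg.grid_cols
    x = crops.reshape(n_pots, cfg.frames_total, 32, 32, 3)
    y = schedule.label_array(cfg.frames_total).reshape(n_pots,
                                                       cfg.frames_total)
    return x, y


@pytest.fixture(scope="session")
def trained_small_lstm(easy_crops):
    """A small CNN-LSTM fitted on the easy scene (shared across tests)."""
    from seedstage.stagenet import (NetworkSpec, TrainingConfig,
                                    build_network, train_model)

    x, y = easy_crops
    model = build_network(NetworkSpec.small(temporal="lstm"), seed=0)
    _, history = train_model(
        model, x, y,
        TrainingConfig(epochs=15, batch_size=4, sequence_chunk_len=16,
                       seed=0))
    return model, history
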