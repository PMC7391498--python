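"""Ordinal developmental stages of a seedling.

Early seedling development passes through a fixed sequence of stages: bare
soil, first appearance of the cotyledon above the soil surface (FA, the
emergence event), opening of the cotyledons (OC), and appearance of the first
true leaf (FL).  The order is ontological — a pot can never regress to an
earlier stage — and every component of this package (chained classifiers,
label smoothing, event timing) leans on that total order.
"""

from __future__ import annotations

import enum


class StageLabel(enum.IntEnum):
    """Developmental stage, totally ordered Soil < FA < OC < FL."""

    SOIL = 0
    FA = 1
    OC = 2
    FL = 3

    @property
    def display_name(self) -> str:
        return _DISPLAY[self]


_DISPLAY = {
    StageLabel.SOIL: "Soil",
    StageLabel.FA: "FA",
    StageLabel.OC: "OC",
    StageLabel.FL: "FL",
}

#: Class order used everywhere a 4-vector or 4x4 matrix is indexed by stage.
STAGE_NAMES = ("Soil", "FA", "OC", "FL")
N_STAGES = 4
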