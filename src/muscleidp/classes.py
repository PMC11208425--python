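"""Fixed integer coding of the 12 segmented muscle classes.

Six paired muscle groups, left/right separated; 0 is background. The coding
is part of the on-disk contract (label NIfTIs, IDP table columns) and never
changes.
"""

from __future__ import annotations

N_CLASSES = 12  # muscle classes; channel/label 0 is background
N_CHANNELS = N_CLASSES + 1

MUSCLE_GROUPS = (
    "psoas",
    "quadratus_lumborum",
    "erector_spinae",
    "gluteus_medius",
    "rectus_abdominis",
    "lateral_abdominals",
)

#: class id -> (muscle group, side)
CLASS_TABLE: dict[int, tuple[str, str]] = {
    1: ("psoas", "left"),
    2: ("psoas", "right"),
    3: ("quadratus_lumborum", "left"),
    4: ("quadratus_lumborum", "right"),
    5: ("erector_spinae", "left"),
    6: ("erector_spinae", "right"),
    7: ("gluteus_medius", "left"),
    8: ("gluteus_medius", "right"),
    9: ("rectus_abdominis", "left"),
    10: ("rectus_abdominis", "right"),
    11: ("lateral_abdominals", "left"),
    12: ("lateral_abdominals", "right"),
}

#: (group, side) -> class id
CLASS_IDS: dict[tuple[str, str], int] = {v: k for k, v in CLASS_TABLE.items()}


def class_name(class_id: int) -> str:
    group, side = CLASS_TABLE[class_id]
    return f"{group}_{side}"
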