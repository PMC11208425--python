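"""Imaging-derived phenotypes: cavity-slab restriction, volumes, masses.

The "abdominal" region is the axial slab between the most inferior lung slice
and the inferior aspect of L5, both boundary slices included. Per-class
volume is voxel counting times voxel volume (no partial-volume modelling);
mass converts volume at a fixed muscle density of 1.06 kg/L = 1.06 g/mL.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import CLASS_TABLE, MUSCLE_GROUPS, N_CLASSES, class_name
from .phantom import Landmarks

__all__ = [
    "MUSCLE_DENSITY_G_PER_ML",
    "CavitySlab",
    "MuscleIDP",
    "delineate_cavity",
    "compute_volumes",
    "volume_to_mass",
    "extract_idp",
    "idp_table",
]

#: Skeletal-muscle density, 1.06 kg/L ≡ 1.06 g/mL.
MUSCLE_DENSITY_G_PER_ML = 1.06


@dataclass(frozen=True)
class CavitySlab:
    """Inclusive axial slice interval [top_slice, bottom_slice]."""

    top_slice: int
    bottom_slice: int

    def __post_init__(self) -> None:
        if not (0 <= self.top_slice < self.bottom_slice):
            raise ValueError(
                f"need 0 <= top_slice < bottom_slice, got [{self.top_slice}, {self.bottom_slice}]"
            )

    @property
    def n_slices(self) -> int:
        return self.bottom_slice - self.top_slice + 1


@dataclass
class MuscleIDP:
    """Per-class cavity-slab volumes (mL) and masses (g) for one subject."""

    subject_id: str
    volume_ml: dict[int, float]
    mass_g: dict[int, float] = field(default_factory=dict)
    density_g_per_ml: float = MUSCLE_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        if not self.mass_g:
            self.mass_g = {c: volume_to_mass(v, self.density_g_per_ml) for c, v in self.volume_ml.items()}

    def group_mass_g(self, group: str) -> float:
        return sum(
            self.mass_g[c] for c, (g, _s) in CLASS_TABLE.items() if g == group
        )

    @property
    def total_volume_ml(self) -> float:
        return sum(self.volume_ml.values())

    @property
    def total_mass_g(self) -> float:
        return sum(self.mass_g.values())


def delineate_cavity(landmarks: Landmarks | dict, n_slices: int | None = None) -> CavitySlab:
    """Cavity slab from the lung-inferior and L5-inferior landmarks.

    Accepts a :class:`~muscleidp.phantom.Landmarks` or a mapping with keys
    ``lung_inferior_slice`` / ``l5_inferior_slice``. Missing or inverted
    landmarks are errors.
    """
    if isinstance(landmarks, dict):
        try:
            top = landmarks["lung_inferior_slice"]
            bottom = landmarks["l5_inferior_slice"]
        except KeyError as e:
            raise ValueError(f"missing landmark {e.args[0]!r}") from None
    else:
        top, bottom = landmarks.lung_inferior_slice, landmarks.l5_inferior_slice
    if top is None or bottom is None:
        raise ValueError("landmarks must both be provided")
    top, bottom = int(top), int(bottom)
    if top >= bottom:
        raise ValueError(
            f"inverted landmarks: lung_inferior={top} must lie above l5_inferior={bottom}"
        )
    if n_slices is not None and bottom >= n_slices:
        raise ValueError(f"l5_inferior={bottom} outside volume with {n_slices} slices")
    return CavitySlab(top_slice=top, bottom_slice=bottom)


def compute_volumes(
    labels: np.ndarray,
    slab: CavitySlab,
    spacing_mm: tuple[float, float, float],
) -> dict[int, float]:
    """Per-class volume (mL) of labeled voxels inside the cavity slab.

    ``volume_ml[c] = (# voxels labeled c in slices top..bottom) x voxel
    volume``, with 1 mL = 1000 mm³. Voxels outside the slab contribute
    nothing.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be a 3D volume")
    if spacing_mm is None or len(spacing_mm) != 3 or any(s <= 0 for s in spacing_mm):
        raise ValueError(f"need positive 3-axis voxel spacing, got {spacing_mm}")
    if slab.bottom_slice >= labels.shape[0]:
        raise ValueError(
            f"slab [{slab.top_slice}, {slab.bottom_slice}] exceeds {labels.shape[0]} slices"
        )
    vox_ml = float(np.prod(spacing_mm)) / 1000.0
    sub = labels[slab.top_slice : slab.bottom_slice + 1]
    counts = np.bincount(sub.ravel().astype(np.int64), minlength=N_CLASSES + 1)
    return {c: float(counts[c]) * vox_ml for c in range(1, N_CLASSES + 1)}


def volume_to_mass(volume_ml: float, density_g_per_ml: float = MUSCLE_DENSITY_G_PER_ML) -> float:
    """Mass in grams from volume in mL at muscle density (default 1.06 g/mL)."""
    if volume_ml < 0:
        raise ValueError(f"volume must be >= 0, got {volume_ml}")
    return density_g_per_ml * volume_ml


def extract_idp(
    subject_id: str,
    labels: np.ndarray,
    landmarks: Landmarks | dict,
    spacing_mm: tuple[float, float, float],
) -> MuscleIDP:
    """Full IDP extraction for one subject: slab -> volumes -> masses."""
    slab = delineate_cavity(landmarks, n_slices=np.asarray(labels).shape[0])
    volumes = compute_volumes(labels, slab, spacing_mm)
    return MuscleIDP(subject_id=subject_id, volume_ml=volumes)


def idp_table(idps: list[MuscleIDP]) -> pd.DataFrame:
    """One row per subject: per-class volume/mass, group totals, overall total.

    Columns: ``{group}_{side}_volume_ml``, ``{group}_{side}_mass_g``,
    ``{group}_mass_g`` (L+R), ``total_mass_g``.
    """
    rows = []
    for idp in idps:
        row: dict = {"subject_id": idp.subject_id}
        for c in range(1, N_CLASSES + 1):
            row[f"{class_name(c)}_volume_ml"] = idp.volume_ml[c]
            row[f"{class_name(c)}_mass_g"] = idp.mass_g[c]
        for group in MUSCLE_GROUPS:
            row[f"{group}_mass_g"] = idp.group_mass_g(group)
        row["total_mass_g"] = idp.total_mass_g
        rows.append(row)
    return pd.DataFrame(rows)


def write_idp_table(idps: list[MuscleIDP], path: str | os.PathLike) -> pd.DataFrame:
    df = idp_table(idps)
    df.to_csv(os.fspath(path), sep="\t", index=False)
    return df
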