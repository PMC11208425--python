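"""Volume I/O, orientation handling, and CT preprocessing.

Volumes are carried as :class:`CTVolume`: a 3D array of Hounsfield units (HU)
with axial slices along the first axis, per-axis voxel spacing in millimetres,
and the NIfTI voxel-to-world affine. On disk everything is NIfTI-1.

Preprocessing follows the conventions of CT body-composition pipelines:

* series selection keeps axial, soft-kernel series with slice thickness
  >= 2 mm (thin slices are too noisy for muscle segmentation);
* model input is intensity-windowed (window 400 HU, level 40 HU) onto [0, 1];
* skeletal muscle attenuation is taken as -29..150 HU inclusive.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Literal, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "SeriesMeta",
    "read_volume",
    "write_volume",
    "select_series",
    "window_intensity",
    "muscle_attenuation_mask",
    "HU_MUSCLE_MIN",
    "HU_MUSCLE_MAX",
    "MIN_SLICE_THICKNESS_MM",
    "DEFAULT_WINDOW",
    "DEFAULT_LEVEL",
]

#: Skeletal-muscle attenuation range in HU, bounds inclusive.
HU_MUSCLE_MIN = -29.0
HU_MUSCLE_MAX = 150.0

#: Axial series thinner than this are excluded as too noisy.
MIN_SLICE_THICKNESS_MM = 2.0

DEFAULT_WINDOW = 400.0
DEFAULT_LEVEL = 40.0


@dataclass
class CTVolume:
    """A 3D HU-valued image in canonical (axial-first) orientation.

    ``voxels[k]`` is the k-th axial slice; ``spacing_mm`` is (z, y, x) voxel
    spacing. ``affine`` maps voxel indices (in the canonical axis order used
    by the on-disk representation, x-y-z) to world millimetres.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray
    orientation: str = "zyx-canonical"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"CTVolume requires a 3D array, got {self.voxels.ndim}D"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing_mm
        ):
            raise ValueError(f"spacing must be 3 finite positive values, got {self.spacing_mm}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm³)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return dataclasses.replace(self, voxels=voxels)


@dataclass
class SeriesMeta:
    """Acquisition metadata used for series selection."""

    orientation_label: Literal["axial", "sagittal", "coronal", "other"]
    slice_thickness_mm: float
    kernel_class: Literal["soft", "high_pass"] = "soft"
    contrast_phase: Literal["enhanced", "unenhanced", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")


def _to_canonical_zyx(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Reorient to RAS canonical, returning (zyx voxels, zyx spacing, affine).

    nibabel's canonical arrays are indexed (x, y, z); axial slices must sit on
    the first axis, so the array is transposed to (z, y, x). The stored affine
    is the canonical x-y-z affine (used to write back and for world-coordinate
    queries).
    """
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    vox = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return vox, spacing, np.asarray(img.affine, dtype=float)


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI-1 volume and canonicalize its orientation.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    non-3D images or non-finite/zero spacing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D image, got shape {img.shape} in {path}")
    vox, spacing, affine = _to_canonical_zyx(img)
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"non-finite or non-positive voxel spacing {spacing} in {path}")
    return CTVolume(voxels=vox, spacing_mm=spacing, affine=affine)


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a :class:`CTVolume` (or aligned label volume) as NIfTI-1."""
    data = np.transpose(vol.voxels, (2, 1, 0))
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms((vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0]))
    nib.save(img, os.fspath(path))


def voxel_to_world(vol: CTVolume, zyx_index: Sequence[float]) -> np.ndarray:
    """World (mm) coordinates of a voxel given by its (z, y, x) index."""
    z, y, x = zyx_index
    hom = np.array([x, y, z, 1.0], dtype=float)
    return (vol.affine @ hom)[:3]


def select_series(metas: Sequence[SeriesMeta]) -> list[int]:
    """Indices of series usable for muscle segmentation, order preserved.

    A series is excluded if it is not axial, uses a high-pass reconstruction
    kernel, or is an axial series with slice thickness below 2 mm.
    """
    keep = []
    for i, m in enumerate(metas):
        if m.orientation_label != "axial":
            continue
        if m.kernel_class == "high_pass":
            continue
        if m.slice_thickness_mm < MIN_SLICE_THICKNESS_MM:
            continue
        keep.append(i)
    return keep


def window_intensity(
    voxels: np.ndarray | CTVolume,
    window: float = DEFAULT_WINDOW,
    level: float = DEFAULT_LEVEL,
) -> np.ndarray:
    """Linear window/level mapping of HU onto [0, 1], clipped outside.

    HU values in [level - window/2, level + window/2] map linearly onto
    [0, 1]; values outside clip to the endpoints. With the defaults
    (window 400, level 40) the passband is [-160, 240] HU.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    hu = voxels.voxels if isinstance(voxels, CTVolume) else np.asarray(voxels)
    lo = level - window / 2.0
    out = (hu.astype(np.float64) - lo) / window
    return np.clip(out, 0.0, 1.0)


def muscle_attenuation_mask(
    voxels: np.ndarray | CTVolume,
    hu_min: float = HU_MUSCLE_MIN,
    hu_max: float = HU_MUSCLE_MAX,
) -> np.ndarray:
    """Boolean mask of voxels inside the muscle attenuation range, inclusive."""
    hu = voxels.voxels if isinstance(voxels, CTVolume) else np.asarray(voxels)
    return (hu >= hu_min) & (hu <= hu_max)
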