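"""Synthetic abdominal CT phantoms and simulated demographic cohorts.

Real abdominal CT with expert muscle labels is controlled-access, so every
downstream stage of the pipeline is exercised on phantoms generated here:

* :func:`generate_phantom` renders an HU-valued volume containing a fat body
  outline, a lung region superior to the lung-inferior landmark, a vertebral
  bone column, and 12 disjoint muscle structures (six paired groups), together
  with a voxel-exact ground-truth label map and the two cavity landmarks.
* :func:`generate_cohort` simulates a demographic table whose total muscle
  mass declines linearly with age at sex-specific rates, split across the 12
  classes by fixed per-sex proportions — the statistical structure the cohort
  analyses are validated against.

Both generators are deterministic given their spec's seed.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classes import CLASS_TABLE, N_CLASSES, class_name
from .imaging_io import CTVolume, write_volume

__all__ = [
    "MuscleStructure",
    "PhantomSpec",
    "CohortSimSpec",
    "Landmarks",
    "generate_phantom",
    "generate_cohort",
    "make_phantom_set",
    "write_phantom_dataset",
    "DEFAULT_HU_MEANS",
]

#: Plausible per-tissue mean attenuations (HU). Muscle sits inside the
#: skeletal-muscle attenuation window [-29, 150]; fat and bone sit outside it.
DEFAULT_HU_MEANS = {
    "air": -1000.0,
    "lung": -800.0,
    "fat": -100.0,
    "muscle": 50.0,
    "bone": 700.0,
}


@dataclass
class MuscleStructure:
    """One labeled structure: an elliptic tube or an ellipsoid, in voxels.

    ``tube``: elliptic cylinder with cross-section radii ``radii_yx`` centred
    at ``center_yx``, spanning axial slices ``z_min..z_max`` inclusive.
    ``ellipsoid``: axis-aligned ellipsoid with ``center_zyx`` / ``radii_zyx``.
    """

    class_id: int
    shape: str = "tube"  # "tube" | "ellipsoid"
    center_yx: tuple[float, float] = (0.0, 0.0)
    radii_yx: tuple[float, float] = (1.0, 1.0)
    z_min: int = 0
    z_max: int = 0
    center_zyx: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_zyx: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        nz, ny, nx = grid_shape
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        if self.shape == "tube":
            cy, cx = self.center_yx
            ry, rx = self.radii_yx
            inplane = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            return inplane & (zz >= self.z_min) & (zz <= self.z_max)
        if self.shape == "ellipsoid":
            cz, cy, cx = self.center_zyx
            rz, ry, rx = self.radii_zyx
            return (
                ((zz - cz) / rz) ** 2
                + ((yy - cy) / ry) ** 2
                + ((xx - cx) / rx) ** 2
                <= 1.0
            )
        raise ValueError(f"unknown structure shape {self.shape!r}")


def _default_geometry(grid_shape: tuple[int, int, int]) -> list[MuscleStructure]:
    """Gross-anatomy-like default layout, scaled to the grid.

    Paired paraspinal tubes (psoas, quadratus lumborum, erector spinae),
    anterior wall slabs (rectus abdominis), lateral wall ellipses, and
    gluteal ellipsoids low in the volume. Positions are configuration — this
    is only a reviewable default.
    """
    nz, ny, nx = grid_shape
    sy, sx = ny / 64.0, nx / 64.0
    z_lo, z_hi = int(round(0.25 * nz)), int(round(0.85 * nz))

    def tube(cid, cy, cx, ry, rx, z0=z_lo, z1=z_hi):
        return MuscleStructure(
            class_id=cid,
            shape="tube",
            center_yx=(cy * sy, cx * sx),
            radii_yx=(ry * sy, rx * sx),
            z_min=z0,
            z_max=z1,
        )

    gz = int(round(0.8 * nz))
    structures = [
        # psoas: paraspinal, anterior to quadratus lumborum
        tube(1, 35, 24, 3.5, 3.5),
        tube(2, 35, 40, 3.5, 3.5),
        # quadratus lumborum: small, posterior-lateral to psoas
        tube(3, 43, 19, 2.5, 2.5),
        tube(4, 43, 45, 2.5, 2.5),
        # erector spinae: large posterior columns
        tube(5, 50, 25, 3.5, 4.5),
        tube(6, 50, 39, 3.5, 4.5),
        # gluteus medius: inferior lateral ellipsoids
        MuscleStructure(
            class_id=7,
            shape="ellipsoid",
            center_zyx=(gz, 38 * sy, 13 * sx),
            radii_zyx=(0.12 * nz, 5 * sy, 4 * sx),
        ),
        MuscleStructure(
            class_id=8,
            shape="ellipsoid",
            center_zyx=(gz, 38 * sy, 51 * sx),
            radii_zyx=(0.12 * nz, 5 * sy, 4 * sx),
        ),
        # rectus abdominis: anterior wall slabs
        tube(9, 12, 26, 2.5, 5.0),
        tube(10, 12, 38, 2.5, 5.0),
        # lateral abdominals: thin lateral wall ellipses
        tube(11, 28, 7, 9.0, 3.0),
        tube(12, 28, 57, 9.0, 3.0),
    ]
    return structures


@dataclass
class PhantomSpec:
    """Parameters of one synthetic abdominal CT volume."""

    grid_shape: tuple[int, int, int] = (40, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (5.0, 2.0, 2.0)
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_noise_sd: float = 10.0
    muscle_geometry: list[MuscleStructure] | None = None
    landmark_lung_inferior: int = 8
    landmark_l5_inferior: int = 34
    contrast_shift_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz = self.grid_shape[0]
        if not (0 <= self.landmark_lung_inferior < self.landmark_l5_inferior < nz):
            raise ValueError(
                "landmarks must satisfy 0 <= lung_inferior < l5_inferior < n_slices; "
                f"got lung={self.landmark_lung_inferior}, l5={self.landmark_l5_inferior}, "
                f"n_slices={nz}"
            )
        hu = self.hu_means
        if not (hu["air"] < hu["lung"] < hu["fat"] < hu["muscle"] < hu["bone"]):
            raise ValueError("tissue HU means must be ordered air < lung < fat < muscle < bone")
        if not (-29.0 <= hu["muscle"] <= 150.0):
            raise ValueError(
                f"muscle HU mean {hu['muscle']} outside the attenuation range [-29, 150]"
            )
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be >= 0")
        if self.muscle_geometry is None:
            self.muscle_geometry = _default_geometry(self.grid_shape)
        ids = sorted(s.class_id for s in self.muscle_geometry)
        if ids != list(range(1, N_CLASSES + 1)):
            raise ValueError(f"muscle_geometry must define classes 1..{N_CLASSES} exactly, got {ids}")


@dataclass
class Landmarks:
    """Axial slice indices of the cavity boundaries."""

    lung_inferior_slice: int
    l5_inferior_slice: int


def _body_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    nz, ny, nx = grid_shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    body2d = ((yy - cy) / (0.44 * ny)) ** 2 + ((xx - cx) / (0.47 * nx)) ** 2 <= 1.0
    return np.broadcast_to(body2d, (nz, ny, nx)).copy()


def _lung_mask(grid_shape, body2d_any: np.ndarray, lung_inferior: int) -> np.ndarray:
    nz, ny, nx = grid_shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    lungs2d = np.zeros((ny, nx), dtype=bool)
    for side in (-1.0, 1.0):
        lungs2d |= ((yy - (cy - 0.08 * ny)) / (0.22 * ny)) ** 2 + (
            (xx - (cx + side * 0.2 * nx)) / (0.16 * nx)
        ) ** 2 <= 1.0
    mask = np.zeros(grid_shape, dtype=bool)
    mask[: lung_inferior + 1] = lungs2d & body2d_any
    return mask


def _bone_mask(grid_shape) -> np.ndarray:
    nz, ny, nx = grid_shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = 0.66 * ny, (nx - 1) / 2.0
    bone2d = ((yy - cy) / (0.055 * ny)) ** 2 + ((xx - cx) / (0.055 * nx)) ** 2 <= 1.0
    return np.broadcast_to(bone2d, (nz, ny, nx)).copy()


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, np.ndarray, Landmarks]:
    """Render a phantom volume, its ground-truth label map, and landmarks.

    The label map assigns class k exactly to structure k's voxels; muscle
    structures must be pairwise disjoint (a hard error names the first
    offending pair otherwise). Identical spec + seed gives bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    hu = spec.hu_means

    body = _body_mask(shape)
    lung = _lung_mask(shape, body[0], spec.landmark_lung_inferior)
    bone = _bone_mask(shape) & body

    vol = np.full(shape, hu["air"], dtype=np.float64)
    vol[body] = hu["fat"] + spec.contrast_shift_hu
    vol[lung & body] = hu["lung"]
    vol[bone] = hu["bone"]

    labels = np.zeros(shape, dtype=np.int16)
    owner = {}
    for s in sorted(spec.muscle_geometry, key=lambda s: s.class_id):
        m = s.mask(shape)
        clash = m & (labels > 0)
        if clash.any():
            other = int(labels[clash][0])
            raise ValueError(
                f"muscle structures overlap: class {other} "
                f"({class_name(other)}) and class {s.class_id} ({class_name(s.class_id)})"
            )
        labels[m] = s.class_id
        owner[s.class_id] = m
    vol[labels > 0] = hu["muscle"] + spec.contrast_shift_hu

    if spec.hu_noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.hu_noise_sd, size=shape)

    sz, sy, sx = spec.voxel_spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    ct = CTVolume(voxels=vol, spacing_mm=spec.voxel_spacing_mm, affine=affine)
    lm = Landmarks(
        lung_inferior_slice=spec.landmark_lung_inferior,
        l5_inferior_slice=spec.landmark_l5_inferior,
    )
    return ct, labels, lm


def make_phantom_set(
    n: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    jitter_vox: float = 2.0,
    jitter_scale: float = 0.12,
) -> list[tuple[CTVolume, np.ndarray, Landmarks]]:
    """Generate ``n`` phantoms with per-phantom geometry jitter.

    Structure centres are shifted by up to ``jitter_vox`` voxels and radii
    rescaled by up to ``jitter_scale`` (uniform), emulating anatomical
    variation across subjects so that held-out phantoms differ from training
    phantoms. Retries placement a few times if a jitter draw causes overlap.
    """
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec()
    out = []
    for i in range(n):
        for _attempt in range(20):
            geom = copy.deepcopy(base.muscle_geometry)
            for s in geom:
                if s.shape == "tube":
                    dy, dx = rng.uniform(-jitter_vox, jitter_vox, 2)
                    f = 1.0 + rng.uniform(-jitter_scale, jitter_scale)
                    s.center_yx = (s.center_yx[0] + dy, s.center_yx[1] + dx)
                    s.radii_yx = (s.radii_yx[0] * f, s.radii_yx[1] * f)
                else:
                    dz, dy, dx = rng.uniform(-jitter_vox, jitter_vox, 3)
                    f = 1.0 + rng.uniform(-jitter_scale, jitter_scale)
                    s.center_zyx = (
                        s.center_zyx[0] + dz,
                        s.center_zyx[1] + dy,
                        s.center_zyx[2] + dx,
                    )
                    s.radii_zyx = tuple(r * f for r in s.radii_zyx)
            spec = copy.deepcopy(base)
            spec.muscle_geometry = geom
            spec.seed = int(rng.integers(0, 2**31 - 1))
            try:
                out.append(generate_phantom(spec))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(f"could not place disjoint structures for phantom {i}")
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

# Per-sex mean group masses (g) used for default split proportions; the split
# is L/R symmetric. Magnitudes follow published abdominal-CT cohort tables
# (female total ~2041 g, male ~3086 g).
_FEMALE_GROUP_G = {
    "erector_spinae": 704.0,
    "gluteus_medius": 82.0,
    "lateral_abdominals": 745.0,
    "psoas": 224.0,
    "quadratus_lumborum": 84.0,
    "rectus_abdominis": 205.0,
}
_MALE_GROUP_G = {
    "erector_spinae": 954.0,
    "gluteus_medius": 154.0,
    "lateral_abdominals": 1171.0,
    "psoas": 367.0,
    "quadratus_lumborum": 131.0,
    "rectus_abdominis": 309.0,
}


def _proportions(group_g: dict) -> dict[int, float]:
    total = sum(group_g.values())
    props = {}
    for cid, (group, _side) in CLASS_TABLE.items():
        props[cid] = group_g[group] / total / 2.0  # L/R symmetric
    return props


@dataclass
class CohortSimSpec:
    """Parameters of a simulated demographic cohort.

    Total abdominal muscle mass is linear in age per sex:
    ``mass = intercept_g[sex] + slope_g_per_year[sex] * age + N(0, noise_sd_g)``,
    then split across the 12 classes by ``group_proportions[sex]`` (sums to 1).
    Default intercepts are calibrated so the age-60 mean matches published
    sex-specific totals (female 2041 g, male 3086 g) at the default slopes of
    -0.96 (female) and -1.73 (male) g/year. ``height_coupling_exp`` optionally
    multiplies mass by (height / 1.7 m)^exp to induce a mass-height
    correlation (0 = off); used to validate height-squared adjustment.
    """

    n_subjects: int = 500
    sex_fraction_male: float = 0.45
    age_range_years: tuple[float, float] = (18.0, 95.0)
    intercept_g: dict = field(
        default_factory=lambda: {"female": 2041.0 + 0.96 * 60.0, "male": 3086.0 + 1.73 * 60.0}
    )
    slope_g_per_year: dict = field(default_factory=lambda: {"female": -0.96, "male": -1.73})
    group_proportions: dict = field(
        default_factory=lambda: {
            "female": _proportions(_FEMALE_GROUP_G),
            "male": _proportions(_MALE_GROUP_G),
        }
    )
    noise_sd_g: float = 450.0
    height_model: dict = field(
        default_factory=lambda: {"female": (1.62, 0.07), "male": (1.76, 0.08)}
    )
    bmi_model: dict = field(default_factory=lambda: {"female": (27.5, 5.5), "male": (28.0, 5.0)})
    height_coupling_exp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3 (downstream statistics undefined)")
        if not (0.0 <= self.sex_fraction_male <= 1.0):
            raise ValueError("sex_fraction_male must be in [0, 1]")
        for sex in ("female", "male"):
            total = sum(self.group_proportions[sex].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"group_proportions for {sex} sum to {total}, expected 1 +- 1e-9"
                )


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a per-subject demographics + muscle-mass table.

    Columns: subject_id, age_years, sex, height_m, bmi, one mass column per
    class (``{group}_{side}_mass_g``), per-group totals (``{group}_mass_g``)
    and ``total_mass_g``. Masses are strictly positive (violating draws are
    resampled). Reproducible under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sexes = np.where(rng.random(n) < spec.sex_fraction_male, "male", "female")
    ages = rng.uniform(*spec.age_range_years, size=n)

    heights = np.empty(n)
    bmis = np.empty(n)
    totals = np.empty(n)
    for i in range(n):
        sex = sexes[i]
        hm, hs = spec.height_model[sex]
        bm, bs = spec.bmi_model[sex]
        h = rng.normal(hm, hs)
        while h <= 0.5 or h >= 2.5:
            h = rng.normal(hm, hs)
        b = rng.normal(bm, bs)
        while b <= 10.0:
            b = rng.normal(bm, bs)
        mu = spec.intercept_g[sex] + spec.slope_g_per_year[sex] * ages[i]
        if spec.height_coupling_exp != 0.0:
            mu = mu * (h / 1.7) ** spec.height_coupling_exp
        m = mu + (rng.normal(0.0, spec.noise_sd_g) if spec.noise_sd_g > 0 else 0.0)
        while m <= 0:
            m = mu + rng.normal(0.0, spec.noise_sd_g)
        heights[i], bmis[i], totals[i] = h, b, m

    rows = {
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "age_years": ages,
        "sex": sexes,
        "height_m": heights,
        "bmi": bmis,
    }
    per_class = np.zeros((n, N_CLASSES))
    for i in range(n):
        props = spec.group_proportions[sexes[i]]
        for cid in range(1, N_CLASSES + 1):
            per_class[i, cid - 1] = totals[i] * props[cid]
    for cid in range(1, N_CLASSES + 1):
        rows[f"{class_name(cid)}_mass_g"] = per_class[:, cid - 1]
    for group in sorted({g for g, _ in CLASS_TABLE.values()}):
        left = rows[f"{group}_left_mass_g"]
        right = rows[f"{group}_right_mass_g"]
        rows[f"{group}_mass_g"] = np.asarray(left) + np.asarray(right)
    rows["total_mass_g"] = totals
    return pd.DataFrame(rows)


def write_phantom_dataset(
    out_dir: str | os.PathLike,
    phantoms: Sequence[tuple[CTVolume, np.ndarray, Landmarks]],
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write image/label NIfTI pairs plus the landmark/demographics sidecar.

    Files: ``subNNN_ct.nii.gz``, ``subNNN_labels.nii.gz``, ``subjects.tsv``
    with columns subject_id, lung_inferior_slice, l5_inferior_slice and, when
    a cohort table is supplied, its demographic columns joined row-by-row.
    Returns the sidecar table.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    recs = []
    for i, (vol, labels, lm) in enumerate(phantoms):
        sid = f"sub{i:03d}"
        write_volume(vol, os.path.join(out_dir, f"{sid}_ct.nii.gz"))
        lab_vol = CTVolume(
            voxels=labels.astype(np.int16),
            spacing_mm=vol.spacing_mm,
            affine=vol.affine,
        )
        write_volume(lab_vol, os.path.join(out_dir, f"{sid}_labels.nii.gz"))
        recs.append(
            {
                "subject_id": sid,
                "lung_inferior_slice": lm.lung_inferior_slice,
                "l5_inferior_slice": lm.l5_inferior_slice,
            }
        )
    table = pd.DataFrame(recs)
    if cohort is not None:
        demo = cohort.iloc[: len(table)].reset_index(drop=True)
        demo = demo[["age_years", "sex", "height_m", "bmi"]]
        table = pd.concat([table, demo], axis=1)
    table.to_csv(os.path.join(out_dir, "subjects.tsv"), sep="\t", index=False)
    return table
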