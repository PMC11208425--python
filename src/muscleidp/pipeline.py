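"""End-to-end orchestration: volumes in, IDP table and statistics out.

:func:`run_pipeline` processes a dataset directory (NIfTI volumes plus a
``subjects.tsv`` sidecar with landmarks and optional demographics) through
windowing, slice-wise segmentation, argmax + hole-fill postprocessing,
attenuation masking, cavity-slab restriction and IDP extraction. Per-study
failures (unreadable volumes, implausible segmentations) are logged and
skipped with a count, not fatal. Every run writes a manifest recording the
seed, inputs, outputs and exclusions so artifacts are reproducible.
"""

from __future__ import annotations

import datetime
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .classes import N_CLASSES
from .idp import MuscleIDP, delineate_cavity, extract_idp, idp_table
from .imaging_io import CTVolume, muscle_attenuation_mask, read_volume, window_intensity
from .postprocess import argmax_labels, fill_label_holes
from .segmenter import ResUNet

logger = logging.getLogger("muscleidp")

__all__ = ["RunConfig", "segment_volume", "run_pipeline", "sanity_check_idp"]


@dataclass
class RunConfig:
    """Pipeline run parameters."""

    data_dir: str
    out_dir: str
    seed: int = 0
    apply_attenuation_mask: bool = True
    fill_mode: str = "2d"
    overwrite: bool = False
    profile: str = "desk"  # "desk" | "full" (slice size / width presets)


def segment_volume(
    model: ResUNet,
    vol: CTVolume,
    apply_attenuation_mask: bool = True,
    fill_mode: str = "2d",
    batch_size: int = 8,
) -> np.ndarray:
    """Segment every axial slice of a volume into a 3D label map.

    Windows intensities, runs the model slice-wise, decodes with argmax,
    fills label holes, and (by default) intersects predicted muscle labels
    with the raw-HU attenuation mask [-29, 150].
    """
    x = window_intensity(vol).astype(np.float32)
    labels = np.zeros(vol.voxels.shape, dtype=np.int16)
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        probs = model.predict_proba(xb)
        labels[start : start + xb.shape[0]] = argmax_labels(probs)
    labels = fill_label_holes(labels, mode=fill_mode)
    if apply_attenuation_mask:
        keep = muscle_attenuation_mask(vol)
        n_dropped = int(((labels > 0) & ~keep).sum())
        if n_dropped:
            logger.info("attenuation mask removed %d labeled voxels", n_dropped)
        labels[~keep] = 0
    return labels


def sanity_check_idp(idp: MuscleIDP, slab_volume_ml: float) -> str | None:
    """Automated exclusion rule replacing manual review of segmentations.

    Returns a reason string if the segmentation is implausible (zero
    foreground anywhere, or any single class claiming more volume than the
    whole cavity slab), else None.
    """
    if idp.total_volume_ml == 0:
        return "zero foreground in cavity slab"
    for c in range(1, N_CLASSES + 1):
        if idp.volume_ml[c] > slab_volume_ml:
            return f"class {c} volume {idp.volume_ml[c]:.1f} mL exceeds slab volume"
    return None


def run_pipeline(cfg: RunConfig, model: ResUNet) -> dict:
    """Run the full extraction over a dataset directory; return the manifest.

    Expects ``subjects.tsv`` in ``cfg.data_dir`` with columns subject_id,
    lung_inferior_slice, l5_inferior_slice (plus optional demographics) and
    one ``{subject_id}_ct.nii.gz`` per row. Writes ``idps.tsv`` and
    ``manifest.json`` to ``cfg.out_dir``; refuses to overwrite existing
    outputs unless ``cfg.overwrite``.
    """
    table_path = os.path.join(cfg.data_dir, "subjects.tsv")
    if not os.path.exists(table_path):
        raise FileNotFoundError(table_path)
    subjects = pd.read_csv(table_path, sep="\t")

    os.makedirs(cfg.out_dir, exist_ok=True)
    idps_path = os.path.join(cfg.out_dir, "idps.tsv")
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    for p in (idps_path, manifest_path):
        if os.path.exists(p) and not cfg.overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite to replace it")

    idps: list[MuscleIDP] = []
    exclusions: list[dict] = []
    inputs: list[str] = []
    for _, row in subjects.iterrows():
        sid = str(row["subject_id"])
        ct_path = os.path.join(cfg.data_dir, f"{sid}_ct.nii.gz")
        inputs.append(ct_path)
        try:
            vol = read_volume(ct_path)
            slab = delineate_cavity(
                {
                    "lung_inferior_slice": row["lung_inferior_slice"],
                    "l5_inferior_slice": row["l5_inferior_slice"],
                },
                n_slices=vol.n_slices,
            )
            labels = segment_volume(
                model,
                vol,
                apply_attenuation_mask=cfg.apply_attenuation_mask,
                fill_mode=cfg.fill_mode,
            )
            idp = extract_idp(sid, labels, {
                "lung_inferior_slice": slab.top_slice,
                "l5_inferior_slice": slab.bottom_slice,
            }, vol.spacing_mm)
            slab_ml = slab.n_slices * vol.voxels.shape[1] * vol.voxels.shape[2] * vol.voxel_volume_ml
            reason = sanity_check_idp(idp, slab_ml)
            if reason is not None:
                raise RuntimeError(f"segmentation sanity check failed: {reason}")
            idps.append(idp)
        except Exception as exc:  # noqa: BLE001 - per-study fault tolerance
            logger.warning("excluding study %s: %s", sid, exc)
            exclusions.append({"subject_id": sid, "reason": str(exc)})

    df = idp_table(idps) if idps else pd.DataFrame(columns=["subject_id"])
    df.to_csv(idps_path, sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": cfg.seed,
        "data_dir": os.path.abspath(cfg.data_dir),
        "inputs": inputs,
        "outputs": [idps_path],
        "n_processed": len(idps),
        "n_excluded": len(exclusions),
        "exclusions": exclusions,
        "apply_attenuation_mask": cfg.apply_attenuation_mask,
        "fill_mode": cfg.fill_mode,
    }
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1)
    logger.info(
        "pipeline complete: %d processed, %d excluded", len(idps), len(exclusions)
    )
    return manifest
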