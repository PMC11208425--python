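"""Dataset assembly: phantom directories / in-memory phantoms -> studies.

A :class:`~muscleidp.segmenter.Study` holds all axial slices of one subject;
slices are windowed to [0, 1] and restricted to the cavity slab (the region
the segmenter is trained and evaluated on).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .idp import delineate_cavity
from .imaging_io import read_volume, window_intensity
from .phantom import Landmarks
from .segmenter import Study

__all__ = ["studies_from_phantoms", "load_study_dataset"]


def studies_from_phantoms(
    phantoms: Sequence[tuple],
    ids: Sequence[str] | None = None,
    restrict_to_slab: bool = True,
) -> list[Study]:
    """Build studies from in-memory (volume, labels, landmarks) triples."""
    studies = []
    for i, (vol, labels, lm) in enumerate(phantoms):
        sid = ids[i] if ids is not None else f"sub{i:03d}"
        imgs = window_intensity(vol).astype(np.float32)
        labs = np.asarray(labels, dtype=np.int16)
        if restrict_to_slab:
            slab = delineate_cavity(lm, n_slices=imgs.shape[0])
            imgs = imgs[slab.top_slice : slab.bottom_slice + 1]
            labs = labs[slab.top_slice : slab.bottom_slice + 1]
        studies.append(Study(study_id=sid, images=imgs, labels=labs))
    return studies


def load_study_dataset(data_dir: str | os.PathLike, restrict_to_slab: bool = True) -> list[Study]:
    """Load a phantom dataset directory (written by ``write_phantom_dataset``)."""
    data_dir = os.fspath(data_dir)
    table = pd.read_csv(os.path.join(data_dir, "subjects.tsv"), sep="\t")
    phantoms = []
    ids = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        vol = read_volume(os.path.join(data_dir, f"{sid}_ct.nii.gz"))
        lab = read_volume(os.path.join(data_dir, f"{sid}_labels.nii.gz"))
        lm = Landmarks(
            lung_inferior_slice=int(row["lung_inferior_slice"]),
            l5_inferior_slice=int(row["l5_inferior_slice"]),
        )
        phantoms.append((vol, np.rint(lab.voxels).astype(np.int16), lm))
        ids.append(sid)
    return studies_from_phantoms(phantoms, ids=ids, restrict_to_slab=restrict_to_slab)
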