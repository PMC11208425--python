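"""Label-map postprocessing: argmax decoding and per-class hole filling."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .classes import N_CLASSES

__all__ = ["argmax_labels", "fill_label_holes"]


def argmax_labels(prob_map: np.ndarray) -> np.ndarray:
    """Per-pixel label with maximal probability; ties go to the lowest index.

    Accepts a channel-first probability map: (C, H, W) for one slice or
    (N, C, H, W) for a batch. Non-finite probabilities are rejected.
    """
    p = np.asarray(prob_map)
    if not np.isfinite(p).all():
        raise ValueError("probability map contains non-finite values")
    axis = 0 if p.ndim == 3 else 1
    return p.argmax(axis=axis).astype(np.int16)


def fill_label_holes(labels: np.ndarray, mode: str = "2d") -> np.ndarray:
    """Fill background cavities fully enclosed by each muscle class.

    For each class 1..12 independently, background pixels that are not
    reachable from the image border through the class's complement (i.e. the
    holes of that class's binary mask) are reassigned to the class.
    Connectivity is the filter's default: 4-connected in 2D, 6-connected in
    3D. Pixels already holding a nonzero label are never overwritten; when
    two classes would claim the same hole pixel the lowest class id wins.
    The operation is idempotent.

    ``mode='2d'`` fills slice-wise on a 3D volume (matching a 2D slice-wise
    segmentation pipeline); ``mode='3d'`` fills volumetrically.
    """
    lm = np.asarray(labels)
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if lm.ndim == 2:
        return _fill_once(lm)
    if mode == "2d":
        out = lm.copy()
        for k in range(lm.shape[0]):
            out[k] = _fill_once(lm[k])
        return out
    return _fill_once(lm)


def _fill_once(lm: np.ndarray) -> np.ndarray:
    out = lm.copy()
    for c in range(1, N_CLASSES + 1):
        mask = lm == c
        if not mask.any():
            continue
        holes = ndimage.binary_fill_holes(mask) & ~mask
        out[holes & (out == 0)] = c
    return out
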