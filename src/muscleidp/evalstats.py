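"""Segmentation agreement statistics.

Sørensen–Dice overlap with the slice-wise aggregation conventions of CT
body-composition studies (a slice where both masks are empty is scored N/A
and excluded, not 1), intraclass correlation for method agreement, and OLS
regression of automatic on manual cross-sectional areas.

The ICC variant is ICC(2,1): two-way random effects, absolute agreement,
single measurement — the conventional choice when two measurement methods
are compared on the same subjects. It is computed directly from the mean
squares of the two-way (targets x raters) ANOVA layout:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with n targets, k = 2 raters, MSR the between-target, MSC the between-rater
and MSE the residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "DiceRecord",
    "AgreementResult",
    "dice",
    "aggregate_dice",
    "icc",
    "area_agreement",
]


@dataclass
class DiceRecord:
    """One Dice evaluation: a (study, slice, class) triple; dice=None is N/A."""

    study_id: str
    slice_index: int
    class_id: int
    dice: float | None


@dataclass
class AgreementResult:
    class_id: int | None
    icc: float
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float | None:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|).

    Returns None (not applicable) when both masks are empty; 0.0 when exactly
    one is empty.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(truth_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa = int(a.sum())
    sb = int(b.sum())
    if sa == 0 and sb == 0:
        return None
    inter = int((a & b).sum())
    return 2.0 * inter / (sa + sb)


def aggregate_dice(
    records: Iterable[DiceRecord],
    mode: str = "slices",
    pool_sides: bool = False,
) -> dict:
    """Per-class (or per-group) mean ± SD of Dice records.

    ``mode='slices'`` aggregates across 2D-slice records (test-set
    convention); ``mode='folds'`` expects one record per fold (its
    ``slice_index`` is the fold index) and aggregates across fold averages
    (cross-validation convention). With ``pool_sides=True`` the left/right
    records of each muscle group are pooled and keys are group names. N/A
    records are excluded; a key with no applicable record maps to None,
    never to 0.
    """
    if mode not in ("slices", "folds"):
        raise ValueError("mode must be 'slices' or 'folds'")
    from .classes import CLASS_TABLE

    buckets: dict = {}
    for r in records:
        key = CLASS_TABLE[r.class_id][0] if pool_sides else r.class_id
        buckets.setdefault(key, [])
        if r.dice is not None:
            buckets[key].append(float(r.dice))
    out: dict = {}
    for key, vals in sorted(buckets.items(), key=lambda kv: str(kv[0])):
        if not vals:
            out[key] = None
        else:
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            out[key] = (float(arr.mean()), sd)
    return out


def icc(measure_a: Sequence[float], measure_b: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    a = np.asarray(measure_a, dtype=float)
    b = np.asarray(measure_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("measure_a and measure_b must be 1D and paired")
    n = len(a)
    if n < 3:
        raise ValueError("ICC requires at least 3 paired measurements")
    data = np.column_stack([a, b])
    if np.ptp(data) == 0:
        raise ValueError("ICC is undefined for constant measurements")
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    )


def area_agreement(
    auto_areas: Sequence[float],
    manual_areas: Sequence[float],
    class_id: int | None = None,
) -> AgreementResult:
    """OLS regression of automatic on manual areas plus ICC(2,1).

    Returns slope, intercept, r² and the two-sided p-value of the slope;
    significance is conventionally read at p < 0.05.
    """
    auto = np.asarray(auto_areas, dtype=float)
    manual = np.asarray(manual_areas, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("area series must be 1D and paired")
    if len(auto) < 3:
        raise ValueError("need at least 3 paired areas")
    if np.ptp(manual) == 0:
        raise ValueError("manual areas are constant; regression undefined")
    x = sm.add_constant(manual)
    fit = sm.OLS(auto, x).fit()
    return AgreementResult(
        class_id=class_id,
        icc=icc(auto, manual),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
    )
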