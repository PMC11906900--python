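"""Evaluation metrics: Sørensen–Dice coefficient and 95th-percentile
Hausdorff distance in physical units.

DSC compares per-class binary masks: ``2|X ∩ Y| / (|X| + |Y|)``.  Two empty
masks score 1 (nothing to find, nothing found); one empty mask scores 0.

HD95 extracts boundary voxels (a mask voxel with any 6-neighbour outside the
mask), measures Euclidean distances between the two boundary point sets
scaled by the voxel spacing, and reports the maximum of the two directed 95th
percentiles — the convention prevailing in segmentation benchmarks.  A pooled
variant (95th percentile of both directed distance sets concatenated) is
available under ``direction="pooled"``.  Results are in millimetres; spacing
is given in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelMap, CORTICAL, TRABECULAR

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)   # 6-connectivity


def dice_score(pred: LabelMap, gt: LabelMap, cls: int) -> float:
    """Hard Dice on the class-`cls` binary masks."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    x = pred.class_mask(cls)
    y = gt.class_mask(cls)
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbour outside the mask (array
    borders count as outside)."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return mask & ~eroded


def hd95(pred: LabelMap, gt: LabelMap, cls: int, spacing=None,
         direction: str = "max") -> float:
    """95th-percentile Hausdorff distance for class `cls`, in mm."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    spacing = tuple(spacing) if spacing is not None else pred.spacing
    x = pred.class_mask(cls)
    y = gt.class_mask(cls)
    if not x.any() or not y.any():
        raise ValueError(f"HD95 undefined: empty mask for class {cls}")
    bx = boundary_voxels(x)
    by = boundary_voxels(y)
    # distance_transform_edt gives, at every voxel, the distance to the
    # nearest boundary voxel of the other set (spacing-scaled)
    dt_y = ndimage.distance_transform_edt(~by, sampling=spacing)
    dt_x = ndimage.distance_transform_edt(~bx, sampling=spacing)
    d_xy = dt_y[bx]
    d_yx = dt_x[by]
    if direction == "max":
        val = max(np.percentile(d_xy, 95), np.percentile(d_yx, 95))
    elif direction == "pooled":
        val = np.percentile(np.concatenate([d_xy, d_yx]), 95)
    else:
        raise ValueError(f"unknown direction '{direction}'")
    return float(val) / 1000.0   # µm -> mm


@dataclass
class EvalRecord:
    """One row of the per-subset evaluation table."""

    scan_id: str
    subset: int
    dsc_cortical: float
    dsc_trabecular: float
    avg_dsc: float
    hd95_cortical: float
    hd95_trabecular: float
    avg_hd95: float

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_pair(pred: LabelMap, gt: LabelMap, spacing=None,
                  scan_id: str = "", subset: int = 0) -> EvalRecord:
    """DSC and HD95 for the cortical and trabecular classes plus their means.

    HD95 is NaN for a class whose mask is empty in either input (undefined,
    deliberately not reported as 0).
    """
    dsc_c = dice_score(pred, gt, CORTICAL)
    dsc_t = dice_score(pred, gt, TRABECULAR)

    def _hd(cls):
        try:
            return hd95(pred, gt, cls, spacing)
        except ValueError:
            return float("nan")

    hd_c, hd_t = _hd(CORTICAL), _hd(TRABECULAR)
    return EvalRecord(
        scan_id=scan_id, subset=subset,
        dsc_cortical=dsc_c, dsc_trabecular=dsc_t,
        avg_dsc=(dsc_c + dsc_t) / 2.0,
        hd95_cortical=hd_c, hd95_trabecular=hd_t,
        avg_hd95=(hd_c + hd_t) / 2.0,
    )


def records_to_table(records) -> pd.DataFrame:
    """Per-subset rows plus aggregate rows (class-mean per subset, then
    subset-mean; the pooled-over-subsets order is exported alongside)."""
    df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        return df
    agg = df.drop(columns=["scan_id", "subset"]).mean(numeric_only=True)
    pooled = {
        "avg_dsc": (agg["dsc_cortical"] + agg["dsc_trabecular"]) / 2.0,
        "avg_hd95": (agg["hd95_cortical"] + agg["hd95_trabecular"]) / 2.0,
    }
    rows = [dict(scan_id="MEAN(subset-first)", subset=-1, **agg.to_dict()),
            dict(scan_id="MEAN(class-first)", subset=-1, **{**agg.to_dict(), **pooled})]
    return pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
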