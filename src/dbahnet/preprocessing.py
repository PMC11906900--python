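"""Raw-scan preprocessing: threshold, keep the bone, delete the fibula,
crop, and z-score.

The stages run in a fixed order:

1. Otsu thresholding with a safety margin ``M`` (grey levels) subtracted so
   faint trabecular voxels stay connected to the foreground;
2. retention of the largest 3D connected component (the bone), which removes
   the sample holder, resin artefacts and any free-floating structures;
3. per-slice removal of the second-largest 2D component (the fibula) along
   the bone axis;
4. auto-cropping to the bone bounding box and background suppression;
5. z-score normalisation of the cropped intensities.

Otsu operates on an 8-bit min-max rescaled copy over a 256-bin histogram so
the margin has the fixed meaning of grey levels.  The threshold convention is
pinned: candidate ``t`` splits classes ``[0, t)`` versus ``[t, 255]`` and the
mask keeps voxels ``>= t* - M``; ties in the variance argmax take the
smallest ``t``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PreprocessConfig
from .volumes import IntensityVolume, LabelMap

log = logging.getLogger(__name__)

_STRUCT_3D = np.ones((3, 3, 3), bool)   # 26-connectivity
_STRUCT_2D = np.ones((3, 3), bool)      # 8-connectivity


@dataclass
class BinaryMask:
    """Binary foreground mask sharing geometry with its source volume."""

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


def rescale_to_8bit(vol: IntensityVolume) -> np.ndarray:
    """Min-max rescale intensities to integers in [0, 255]."""
    v = vol.voxels.astype(np.float64)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant volume: no threshold exists")
    return np.rint((v - lo) / (hi - lo) * 255.0).astype(np.uint8)


def otsu_threshold_value(vol8: np.ndarray) -> int:
    """Exhaustive Otsu threshold over the 256-bin histogram of an 8-bit volume.

    Returns the ``t`` in 1..255 maximising the between-class variance of the
    partition ``[0, t) | [t, 255]``; the smallest maximiser wins ties.
    """
    hist = np.bincount(vol8.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    omega0 = np.cumsum(p)[:-1]                  # weight of class [0, t) at t-1
    mu_cum = np.cumsum(p * levels)[:-1]
    mu_total = (p * levels).sum()
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    if not valid.any():
        raise ValueError("volume has fewer than 2 distinct grey levels")
    return int(np.argmax(sigma_b)) + 1          # split below t vs >= t


def otsu_threshold_with_margin(vol: IntensityVolume,
                               cfg: PreprocessConfig) -> BinaryMask:
    """Bone/background mask at the Otsu threshold minus the margin ``M``."""
    vol8 = rescale_to_8bit(vol)
    t = otsu_threshold_value(vol8)
    mask = vol8 >= max(t - cfg.margin, 0)
    log.info("otsu threshold t*=%d, applied t*-M=%d, foreground %d voxels",
             t, t - cfg.margin, int(mask.sum()))
    return BinaryMask(mask, vol.spacing)


def keep_largest_component_3d(mask: BinaryMask) -> BinaryMask:
    """Largest 26-connected component; size ties break on the component whose
    smallest linear voxel index is smallest."""
    if not mask.voxels.any():
        raise ValueError("empty mask: no components to keep")
    lab, n = ndimage.label(mask.voxels, structure=_STRUCT_3D)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = sizes.max()
    winners = np.flatnonzero(sizes == best)
    if winners.size > 1:
        flat = lab.ravel()
        first = {w: np.argmax(flat == w) for w in winners}
        keep = min(winners, key=lambda w: first[w])
    else:
        keep = winners[0]
    return BinaryMask(lab == keep, mask.spacing)


def remove_fibula_per_slice(mask: BinaryMask) -> BinaryMask:
    """In every z-slice with >= 2 8-connected components, remove the
    second-largest one (the fibula cross-section)."""
    out = mask.voxels.copy()
    for z in range(out.shape[2]):
        sl = out[:, :, z]
        lab, n = ndimage.label(sl, structure=_STRUCT_2D)
        if n < 2:
            continue
        sizes = np.bincount(lab.ravel())[1:]    # component 1..n
        flat = lab.ravel()
        firsts = np.full(n + 1, flat.size)
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        pos = np.searchsorted(sorted_labels, np.arange(1, n + 1))
        firsts[1:] = order[pos]
        ranked = sorted(range(1, n + 1), key=lambda c: (-sizes[c - 1], firsts[c]))
        second = ranked[1]
        out[:, :, z] = sl & (lab != second)
    return BinaryMask(out, mask.spacing)


def autocrop_to_bone(vol: IntensityVolume, mask: BinaryMask,
                     cfg: PreprocessConfig, labels: LabelMap | None = None):
    """Crop volume and mask to the mask's bounding box plus ``crop_margin``
    voxels, suppressing off-mask intensities to the volume minimum."""
    if not mask.voxels.any():
        raise ValueError("empty mask: nothing to crop to")
    coords = np.argwhere(mask.voxels)
    lo = np.maximum(coords.min(axis=0) - cfg.crop_margin, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + cfg.crop_margin, vol.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    fill = float(vol.voxels.min())
    sub = vol.voxels[sl].copy()
    sub_mask = mask.voxels[sl]
    sub[~sub_mask] = fill
    out_vol = IntensityVolume(sub, vol.spacing, vol.intensity_units)
    out_mask = BinaryMask(sub_mask, mask.spacing)
    if labels is not None:
        return out_vol, out_mask, LabelMap(labels.voxels[sl], labels.spacing)
    return out_vol, out_mask


def zscore_normalize(vol: IntensityVolume) -> IntensityVolume:
    """Zero-mean, unit-variance normalisation over all voxels (population σ)."""
    v = vol.voxels.astype(np.float64)
    sigma = v.std()
    if sigma == 0:
        raise ValueError("zero-variance volume cannot be z-scored")
    out = ((v - v.mean()) / sigma).astype(np.float32)
    return IntensityVolume(out, vol.spacing, "z-scored")


def preprocess_pipeline(vol: IntensityVolume, cfg: PreprocessConfig,
                        labels: LabelMap | None = None):
    """Full preprocessing chain; returns ``(volume, mask[, labels])`` with
    the volume z-scored and everything cropped to the bone."""
    mask = otsu_threshold_with_margin(vol, cfg)
    log.info("threshold stage: %d foreground voxels", mask.count())
    mask = keep_largest_component_3d(mask)
    log.info("largest-component stage: %d voxels", mask.count())
    mask = remove_fibula_per_slice(mask)
    log.info("fibula-removal stage: %d voxels", mask.count())
    cropped = autocrop_to_bone(vol, mask, cfg, labels)
    out_vol, out_mask = cropped[0], cropped[1]
    out_vol = zscore_normalize(out_vol)
    if labels is not None:
        return out_vol, out_mask, cropped[2]
    return out_vol, out_mask
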