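"""Label-map refinement after prediction.

Three stages, in the fixed order:

1. noise removal — the union of the foreground classes is reduced to its
   largest 26-connected component (satellites and speckle disappear);
2. endosteal smoothing — morphological opening of the cortical mask with a
   spherical structuring element of radius ``K_o`` (default 3 voxels);
   voxels the opening removes are *reassigned to trabecular bone*, so the
   total bone voxel count is exactly conserved while the endosteal surface
   loses its small openings;
3. trabecular reconnection — morphological closing of the trabecular mask
   with a sphere of radius ``R_c`` (default 1 voxel) merges components whose
   gap is within reach; bridge voxels are taken from background only, never
   from cortical bone.

Structuring elements are discrete Euclidean balls.  Each stage can be
switched off via :class:`~dbahnet.config.PostprocessConfig`.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .config import PostprocessConfig
from .volumes import LabelMap, CORTICAL, TRABECULAR

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), bool)


def remove_noise_components(labels: LabelMap) -> LabelMap:
    """Keep only the largest 26-connected component of the foreground union,
    preserving class identities inside it."""
    fg = labels.voxels > 0
    if not fg.any():
        raise ValueError("empty foreground: nothing to denoise")
    lab, n = ndimage.label(fg, structure=_STRUCT_26)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    out = labels.voxels.copy()
    out[lab != keep] = 0
    return LabelMap(out, labels.spacing)


def smooth_endosteal_transition(labels: LabelMap,
                                cfg: PostprocessConfig) -> LabelMap:
    """Open the cortical mask with a radius-``K_o`` ball; voxels removed by
    the opening become trabecular, conserving total bone voxel count."""
    cort = labels.class_mask(CORTICAL)
    # erosion treats out-of-volume as bone: the cortical tube continues past
    # the ROI, so the clipped rim at the volume boundary must not be eroded
    b = ball(cfg.opening_radius)
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(cort, structure=b, border_value=1), structure=b)
    removed = cort & ~opened
    out = labels.voxels.copy()
    out[removed] = TRABECULAR
    return LabelMap(out, labels.spacing)


def connect_trabeculae(labels: LabelMap, cfg: PostprocessConfig) -> LabelMap:
    """Close the trabecular mask with a radius-``R_c`` ball; bridge voxels
    come exclusively from background (cortical voxels are never altered)."""
    trab = labels.class_mask(TRABECULAR)
    if not trab.any():
        return labels.copy()
    closed = ndimage.binary_closing(trab, structure=ball(cfg.closing_radius))
    bridges = closed & ~trab & (labels.voxels == 0)
    out = labels.voxels.copy()
    out[bridges] = TRABECULAR
    return LabelMap(out, labels.spacing)


def postprocess_pipeline(labels: LabelMap, cfg: PostprocessConfig) -> LabelMap:
    """Noise removal, endosteal smoothing, trabecular reconnection."""
    before = np.bincount(labels.voxels.ravel(), minlength=3)
    out = remove_noise_components(labels)
    if cfg.smooth_endosteum:
        out = smooth_endosteal_transition(out, cfg)
    if cfg.connect_trabeculae:
        out = connect_trabeculae(out, cfg)
    after = np.bincount(out.voxels.ravel(), minlength=3)
    log.info("postprocess voxel deltas: cortical %+d, trabecular %+d",
             int(after[1] - before[1]), int(after[2] - before[2]))
    return out
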