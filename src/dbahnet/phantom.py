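"""Synthetic µCT-like mouse tibia phantoms with exact ground-truth labels.

A phantom emulates the morphology the segmentation pipeline must handle:

* a hollow, roughly cylindrical cortical shell (label 1), optionally tapered;
* a sparse, connected trabecular lattice inside the medullary cavity
  (label 2), built by thresholding a Gaussian random field and keeping only
  struts whose in-slice component touches the endosteal surface — so every
  trabecula is anchored to the shell, as real trabeculae are;
* a small fibula cross-section rendered at bone intensity but *labelled
  background*, spatially disconnected from the tibia, so that preprocessing
  (not the generator) must remove it;
* low-intensity resin background, a sample-holder bar, and surrounding air;
* additive Gaussian noise.

Intensity means are laid out on an 8-bit-like scale with the contrast
ordering cortical > trabecular > marrow > resin > air that µCT scans of
resin-embedded bone show.  Identical seeds produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelMap, CORTICAL, TRABECULAR

_BALL1 = ndimage.generate_binary_structure(3, 1)   # radius-1 Euclidean ball


@dataclass
class PhantomParams:
    shape: tuple = (96, 96, 48)
    spacing: tuple = (5.0, 5.0, 5.0)          # µm, the control-scan resolution
    outer_radius: float = 0.38                # fractions of min(H, W)
    inner_radius: float = 0.26
    taper: float = 0.05                       # relative radius change over depth
    trabecular_fraction: float = 0.25         # target volume fraction in cavity
    trabecular_scale: float = 1.5             # Gaussian field smoothing (voxels)
    fibula_radius: float = 0.07
    fibula_gap: float = 4.0                   # voxels between fibula and shell
    holder: bool = True
    intensity_means: dict = field(default_factory=lambda: {
        "cortical": 200.0, "trabecular": 160.0, "marrow": 60.0,
        "holder": 70.0, "resin": 40.0, "air": 10.0})
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        h, w, _ = self.shape
        r_out = self.outer_radius * min(h, w)
        r_in = self.inner_radius * min(h, w)
        if not (0 < r_in < r_out < min(h, w) / 2):
            raise ValueError("need 0 < inner radius < outer radius < min(H,W)/2")
        if not 0.0 <= self.trabecular_fraction < 1.0:
            raise ValueError("trabecular fraction must lie in [0, 1)")


def _radial_grid(shape, center):
    h, w, d = shape
    x = np.arange(h)[:, None, None] - center[0]
    y = np.arange(w)[None, :, None] - center[1]
    return np.sqrt(x * x + y * y) * np.ones((1, 1, d))


def _anchored_trabeculae(field, cavity, shell, fraction, ring):
    """Threshold `field` inside the cavity at `fraction`, add the endosteal
    lining ring, then keep only in-slice (8-connected) components touching
    the cortical shell."""
    if fraction <= 0 or not cavity.any():
        return np.zeros_like(cavity)
    vals = field[cavity]
    thr = np.quantile(vals, 1.0 - fraction)
    lattice = (cavity & (field >= thr)) | ring
    # connecting step: close 1-voxel gaps so the lattice is a fused network
    # (and stable under the same closing used by postprocessing)
    lattice = ndimage.binary_closing(lattice, structure=_BALL1) & cavity
    out = np.zeros_like(lattice)
    struct = np.ones((3, 3), bool)
    for z in range(lattice.shape[2]):
        sl = lattice[:, :, z]
        if not sl.any():
            continue
        lab, n = ndimage.label(sl, structure=struct)
        # a component is anchored if its dilation overlaps the shell slice
        grown = ndimage.grey_dilation(lab, footprint=struct)
        anchored = np.unique(grown[shell[:, :, z] & (grown > 0)])
        out[:, :, z] = np.isin(lab, anchored[anchored > 0]) & sl
    return out


def generate_phantom(params: PhantomParams):
    """Render a phantom; returns ``(IntensityVolume, LabelMap)``."""
    h, w, d = params.shape
    rng = np.random.default_rng(params.seed)
    cx, cy = (h - 1) / 2.0, (w - 1) / 2.0
    r = _radial_grid(params.shape, (cx, cy))
    z_frac = np.linspace(0.0, 1.0, d)[None, None, :]
    scale = 1.0 - params.taper * z_frac
    r_out = params.outer_radius * min(h, w) * scale
    r_in = params.inner_radius * min(h, w) * scale

    shell = (r >= r_in) & (r <= r_out)
    cavity = r < r_in

    field = ndimage.gaussian_filter(
        rng.standard_normal(params.shape), params.trabecular_scale)
    # anchor filtering removes some voxels; re-aim the threshold a few times
    # so the realised fraction lands near the target
    # a thin trabecularised lining along the endosteum anchors the lattice to
    # the shell in every slice and makes it one connected 3D structure
    ring = cavity & (r >= r_in - 1.6)
    want = params.trabecular_fraction
    aim = want
    trab = _anchored_trabeculae(field, cavity, shell, aim, ring)
    if want > 0:
        for _ in range(8):
            realised = trab.sum() / max(cavity.sum(), 1)
            if abs(realised - want) < 0.01:
                break
            aim = float(np.clip(aim * want / max(realised, 1e-6), 0.005, 0.95))
            trab = _anchored_trabeculae(field, cavity, shell, aim, ring)
    else:
        trab = np.zeros_like(cavity)

    means = params.intensity_means
    intensity = np.full(params.shape, means["air"], dtype=np.float32)
    resin_zone = r < (min(h, w) / 2.0 - 1.0)
    intensity[resin_zone] = means["resin"]
    intensity[cavity] = means["marrow"]
    intensity[shell] = means["cortical"]
    intensity[trab] = means["trabecular"]

    # fibula: bone-bright cylinder, labelled background, disconnected from
    # the tibia (the proximal ROI lies above the tibio-fibular junction)
    fib_r = params.fibula_radius * min(h, w)
    fib_dist = params.outer_radius * min(h, w) + params.fibula_gap + fib_r
    fx, fy = cx + fib_dist / np.sqrt(2.0), cy + fib_dist / np.sqrt(2.0)
    fib = _radial_grid(params.shape, (fx, fy)) <= fib_r
    fib &= ~shell & ~cavity
    intensity[fib] = means["cortical"]

    holder_mask = np.zeros(params.shape, bool)
    if params.holder:
        holder_mask[: max(2, h // 24), :, :] = True
        holder_mask &= ~(shell | cavity | fib)
        intensity[holder_mask] = means["holder"]

    if params.noise_sigma > 0:
        intensity = intensity + rng.normal(
            0.0, params.noise_sigma, params.shape).astype(np.float32)

    labels = np.zeros(params.shape, np.uint8)
    labels[shell] = CORTICAL
    labels[trab] = TRABECULAR
    vol = IntensityVolume(intensity.astype(np.float32), params.spacing, "raw-scanner")
    return vol, LabelMap(labels, params.spacing)


def phantom_foreign_masks(params: PhantomParams):
    """Recompute the fibula and holder masks of a phantom (for tests that
    check those structures are removed by preprocessing)."""
    h, w, d = params.shape
    cx, cy = (h - 1) / 2.0, (w - 1) / 2.0
    r = _radial_grid(params.shape, (cx, cy))
    z_frac = np.linspace(0.0, 1.0, d)[None, None, :]
    scale = 1.0 - params.taper * z_frac
    shell_or_cavity = r <= params.outer_radius * min(h, w) * scale
    fib_r = params.fibula_radius * min(h, w)
    fib_dist = params.outer_radius * min(h, w) + params.fibula_gap + fib_r
    fx, fy = cx + fib_dist / np.sqrt(2.0), cy + fib_dist / np.sqrt(2.0)
    fib = (_radial_grid(params.shape, (fx, fy)) <= fib_r) & ~shell_or_cavity
    holder = np.zeros(params.shape, bool)
    if params.holder:
        holder[: max(2, h // 24), :, :] = True
        holder &= ~shell_or_cavity & ~fib
    return fib, holder


DEGRADE_MODES = ("identity", "porosity", "thin_cortex", "sparsify", "densify")


def degrade_phantom(vol: IntensityVolume, labels: LabelMap, mode: str,
                    amount: float = 0.05, seed: int = 0):
    """Emulate treatment-driven morphology changes on a phantom.

    Modes: ``porosity`` removes `amount` of cortical voxels (random holes),
    ``thin_cortex`` erodes the cortical shell, ``sparsify`` removes `amount`
    of trabecular voxels, ``densify`` dilates trabeculae into the cavity,
    ``identity`` returns copies unchanged.  Labels and intensities are
    updated consistently (removed bone becomes marrow-like).
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"unknown degradation mode '{mode}'")
    rng = np.random.default_rng(seed)
    v, lab = vol.voxels.copy(), labels.voxels.copy()
    marrow = 60.0

    def _remove(mask_cls, frac):
        idx = np.flatnonzero(lab == mask_cls)
        k = int(round(frac * idx.size))
        chosen = rng.choice(idx, size=k, replace=False)
        lab.flat[chosen] = 0
        v.flat[chosen] = marrow + rng.normal(0, 4.0, k)

    if mode == "porosity":
        _remove(CORTICAL, amount)
    elif mode == "sparsify":
        _remove(TRABECULAR, amount)
    elif mode == "thin_cortex":
        cort = lab == CORTICAL
        eroded = ndimage.binary_erosion(cort, np.ones((3, 3, 1), bool))
        gone = cort & ~eroded
        lab[gone] = 0
        v[gone] = marrow + rng.normal(0, 4.0, int(gone.sum()))
    elif mode == "densify":
        trab = lab == TRABECULAR
        grown = ndimage.binary_dilation(trab, np.ones((3, 3, 3), bool))
        # only grow inside the medullary cavity (never into cortical/outside)
        cavity_like = ndimage.binary_fill_holes(lab > 0) & (lab == 0)
        new = grown & cavity_like
        lab[new] = TRABECULAR
        v[new] = 160.0 + rng.normal(0, 4.0, int(new.sum()))
    return (IntensityVolume(v, vol.spacing, vol.intensity_units),
            LabelMap(lab, labels.spacing))
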