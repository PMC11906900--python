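"""Live training-time augmentation: five transform families applied to each
sample with a small per-transform probability.

The families and parameter ranges:

* random affine — rotation about the bone axis, angle ~ U[0, π], with
  isotropic scaling ~ U[0.85, 1.25], about the volume centre;
* elastic deformation — ``x' = x + α·G(σ)`` with a per-axis Gaussian random
  displacement field smoothed at σ ~ U[9, 13] voxels and magnitude
  α ~ U[0, 900];
* additive Gaussian noise with variance 0.1;
* intensity scaling ``x' = x·(1 + f)``, f ~ U[−0.1, 0.1];
* gamma contrast ``x' = x^γ``, γ ~ U[0.5, 4.5], computed on a min–max
  [0, 1]-rescaled copy and mapped back to the original range (the power map
  is undefined for the negative values of z-scored data).

Geometric transforms act on image and labels with one shared deformation:
trilinear resampling for intensities, nearest-neighbour for labels.
Out-of-bounds voxels are filled with the image minimum / background label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AugmentConfig
from .volumes import IntensityVolume, LabelMap


@dataclass
class Sample:
    """An (image, labels) training pair with matching geometry."""

    image: IntensityVolume
    labels: LabelMap

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError(f"sample geometry mismatch: "
                             f"{self.image.shape} vs {self.labels.shape}")

    def copy(self) -> "Sample":
        return Sample(self.image.copy(), self.labels.copy())


def _resample_pair(sample: Sample, img_fn, lab_fn) -> Sample:
    img = img_fn(sample.image.voxels.astype(np.float32))
    lab = lab_fn(sample.labels.voxels)
    return Sample(
        IntensityVolume(img, sample.image.spacing, sample.image.intensity_units),
        LabelMap(lab, sample.labels.spacing))


def random_affine(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator,
                  angle: float | None = None, scale: float | None = None) -> Sample:
    """Rotation about z and isotropic scaling about the volume centre."""
    if angle is None:
        angle = rng.uniform(*cfg.rot_range)
    if scale is None:
        scale = rng.uniform(*cfg.scale_range)
    if angle == 0.0 and scale == 1.0:
        return sample.copy()
    c, s = np.cos(angle), np.sin(angle)
    # output -> input mapping: rotate by -angle, divide by scale
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]]) / scale
    center = (np.asarray(sample.image.shape) - 1) / 2.0
    offset = center - rot @ center
    fill = float(sample.image.voxels.min())
    return _resample_pair(
        sample,
        lambda v: ndimage.affine_transform(v, rot, offset=offset, order=1,
                                           mode="constant", cval=fill),
        lambda l: ndimage.affine_transform(l, rot, offset=offset, order=0,
                                           mode="constant", cval=0,
                                           output=np.uint8))


def elastic_deform(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator,
                   sigma: float | None = None, alpha: float | None = None) -> Sample:
    """Smooth random displacement field: x' = x + alpha * G(sigma)."""
    if sigma is None:
        sigma = rng.uniform(*cfg.elastic_sigma)
    if alpha is None:
        alpha = rng.uniform(*cfg.elastic_alpha)
    if alpha == 0.0:
        return sample.copy()
    shape = sample.image.shape
    disp = [alpha * ndimage.gaussian_filter(
        rng.standard_normal(shape).astype(np.float32), sigma)
        for _ in range(3)]
    grid = np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape],
                       indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    fill = float(sample.image.voxels.min())
    return _resample_pair(
        sample,
        lambda v: ndimage.map_coordinates(v, coords, order=1,
                                          mode="constant", cval=fill),
        lambda l: ndimage.map_coordinates(l, coords, order=0,
                                          mode="constant", cval=0).astype(np.uint8))


def add_gaussian_noise(sample: Sample, cfg: AugmentConfig,
                       rng: np.random.Generator) -> Sample:
    """Additive zero-mean Gaussian noise on the image; labels untouched."""
    if cfg.noise_variance <= 0:
        return sample.copy()
    noise = rng.normal(0.0, np.sqrt(cfg.noise_variance),
                       sample.image.shape).astype(np.float32)
    out = sample.copy()
    out.image.voxels = out.image.voxels + noise
    return out


def scale_intensity(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator,
                    f: float | None = None) -> Sample:
    if f is None:
        f = rng.uniform(*cfg.intensity_range)
    out = sample.copy()
    out.image.voxels = out.image.voxels * np.float32(1.0 + f)
    return out


def adjust_contrast(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator,
                    gamma: float | None = None) -> Sample:
    """Gamma map on a [0, 1]-rescaled copy, restored to the original range.

    Monotone in input intensity for any gamma > 0.
    """
    if gamma is None:
        gamma = rng.uniform(*cfg.gamma_range)
    v = sample.image.voxels.astype(np.float64)
    lo, hi = v.min(), v.max()
    out = sample.copy()
    if hi > lo:
        unit = (v - lo) / (hi - lo)
        out.image.voxels = (unit ** gamma * (hi - lo) + lo).astype(np.float32)
    return out


_PIPELINE = (random_affine, elastic_deform, add_gaussian_noise,
             scale_intensity, adjust_contrast)


def apply_augmentations(sample: Sample, cfg: AugmentConfig,
                        rng: np.random.Generator) -> Sample:
    """Apply the five transforms in fixed order, each independently with
    probability ``cfg.p``; fully reproducible from the generator state."""
    out = sample
    for fn in _PIPELINE:
        if rng.uniform() < cfg.p:
            out = fn(out, cfg, rng)
    return out.copy() if out is sample else out
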