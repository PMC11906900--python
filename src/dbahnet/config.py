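"""Configuration records for the network and the surrounding pipeline.

Defaults reproduce the published training protocol for the full-size model:
embedding width C = 96 with per-axis patch reduction E = [4, 4, 2], attention
heads (6, 12, 24, 48) across the three hierarchy levels plus the bottleneck,
SGD with momentum 0.99 at batch size 4 under a cosine-annealed learning rate
starting at 1e-4, random (320, 320, 32) crops, a 70/10/20 scan-level split,
Dice/cross-entropy weights alpha = beta = 0.5, an Otsu margin of 5 grey
levels, morphological radii K_o = 3 and R_c = 1, and per-transform
augmentation probability p = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


def _err(key, msg):
    raise ValueError(f"config key '{key}': {msg}")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    C : embedding channels at the first hierarchy level.
    E : per-axis reduction factors of the patch embedding (each 2 or 4).
    heads : attention heads at levels 0..2 and the bottleneck.
    depths : Swin block pairs per level.
    window : local-volume (window) extents for windowed attention.
    """

    C: int = 96
    E: tuple = (4, 4, 2)
    heads: tuple = (6, 12, 24, 48)
    depths: tuple = (1, 1, 1)
    window: tuple = (4, 4, 2)
    mlp_ratio: float = 4.0
    n_classes: int = 3
    # initialisation scheme (see docs/methods.md): backbone convolutions are
    # followed by normalisation layers, so the network function is invariant
    # to their weight scale while their effective SGD learning rate grows as
    # 1/||w||^2; starting them small lets the published small-learning-rate
    # protocol train them at a useful rate.  The output convolution carries a
    # fixed logit gain for the same reason.
    conv_init_shrink: float = 30.0
    logit_gain: float = 200.0

    def __post_init__(self):
        self.E = tuple(int(e) for e in self.E)
        self.heads = tuple(int(h) for h in self.heads)
        self.depths = tuple(int(d) for d in self.depths)
        self.window = tuple(int(w) for w in self.window)
        if any(e not in (2, 4) for e in self.E) or len(self.E) != 3:
            _err("E", f"every component must be 2 or 4, got {self.E}")
        if len(self.heads) != 4:
            _err("heads", "need 4 head counts (3 levels + bottleneck)")
        for s in range(4):
            ch = self.C * 2 ** s
            if ch % self.heads[s] != 0:
                _err("heads", f"stage channels {ch} not divisible by {self.heads[s]}")
        if self.n_classes < 2:
            _err("n_classes", "need at least 2 classes")

    def stage_channels(self, s: int) -> int:
        return self.C * 2 ** s

    def stage_shapes(self, input_shape):
        """Spatial extents of the feature hierarchy for a given input crop."""
        h, w, d = input_shape
        ex, ey, ez = self.E
        shapes = []
        for s in range(4):
            shapes.append((h // (ex * 2 ** s), w // (ey * 2 ** s), d // (ez * 2 ** s)))
        return shapes


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    momentum: float = 0.99
    batch_size: int = 4
    crop: tuple = (320, 320, 32)
    split: tuple = (0.7, 0.1, 0.2)
    max_steps: int = 1000
    steps_per_epoch: int = 250
    seed: int = 0
    loss_alpha: float = 0.5
    loss_beta: float = 0.5
    n_subsets: int = 10
    patience: int = 10

    def __post_init__(self):
        self.crop = tuple(int(c) for c in self.crop)
        self.split = tuple(float(s) for s in self.split)
        if abs(sum(self.split) - 1.0) > 1e-8:
            _err("split", f"fractions must sum to 1, got {self.split}")
        if abs(self.loss_alpha + self.loss_beta - 1.0) > 1e-8:
            _err("loss_alpha/loss_beta", "must sum to 1")
        if self.n_subsets < 1:
            _err("n_subsets", "must be >= 1")

    def validate_against(self, model: ModelConfig):
        for c, e in zip(self.crop, model.E):
            if c % (e * 8) != 0:
                _err("crop", f"extent {c} not divisible by E*8 = {e * 8}")


@dataclass
class PreprocessConfig:
    margin: int = 5          # grey levels subtracted from the Otsu threshold
    histogram_bins: int = 256
    crop_margin: int = 8     # voxels retained around the bone bounding box

    def __post_init__(self):
        if self.margin < 0:
            _err("margin", "must be >= 0")
        if self.histogram_bins < 2:
            _err("histogram_bins", "must be >= 2")
        if self.crop_margin < 0:
            _err("crop_margin", "must be >= 0")


@dataclass
class PostprocessConfig:
    opening_radius: int = 3   # K_o, endosteal smoothing sphere radius (voxels)
    closing_radius: int = 1   # R_c, trabecular reconnection sphere radius
    smooth_endosteum: bool = True
    connect_trabeculae: bool = True

    def __post_init__(self):
        if self.opening_radius < 1 or self.closing_radius < 1:
            _err("opening_radius/closing_radius", "must be >= 1")


@dataclass
class AugmentConfig:
    p: float = 0.1
    rot_range: tuple = (0.0, 3.141592653589793)
    scale_range: tuple = (0.85, 1.25)
    elastic_sigma: tuple = (9.0, 13.0)
    elastic_alpha: tuple = (0.0, 900.0)
    noise_variance: float = 0.1
    intensity_range: tuple = (-0.1, 0.1)
    gamma_range: tuple = (0.5, 4.5)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            _err("p", "must lie in [0, 1]")
        for key in ("rot_range", "scale_range", "elastic_sigma",
                    "elastic_alpha", "intensity_range", "gamma_range"):
            lo, hi = getattr(self, key)
            if lo > hi:
                _err(key, f"range not ordered: ({lo}, {hi})")


_SECTIONS = {
    "model": ModelConfig,
    "train": TrainConfig,
    "preprocess": PreprocessConfig,
    "postprocess": PostprocessConfig,
    "augment": AugmentConfig,
}


def load_config(path=None, overrides: dict | None = None):
    """Load a flat or sectioned YAML config; unset keys use the defaults above.

    Returns ``(ModelConfig, TrainConfig, PreprocessConfig, PostprocessConfig,
    AugmentConfig)``.  Keys may be given flat (``C: 48``) or grouped under the
    section names ``model/train/preprocess/postprocess/augment``.  Unknown
    keys and invariant violations raise with the offending key named.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a mapping of keys to values")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    flat = {}
    sectioned = {name: {} for name in _SECTIONS}
    for key, val in raw.items():
        if key in _SECTIONS and isinstance(val, dict):
            sectioned[key].update(val)
        else:
            flat[key] = val

    field_owner = {}
    for name, cls in _SECTIONS.items():
        for f in fields(cls):
            field_owner.setdefault(f.name, name)
    for key, val in flat.items():
        if key not in field_owner:
            raise ValueError(f"unknown config key '{key}'")
        sectioned[field_owner[key]][key] = val

    out = []
    for name, cls in _SECTIONS.items():
        try:
            out.append(cls(**sectioned[name]))
        except TypeError as exc:
            raise ValueError(f"bad key in section '{name}': {exc}") from exc
    model, train, pre, post, aug = out
    train.validate_against(model)
    return model, train, pre, post, aug
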