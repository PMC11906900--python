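"""Training protocol and checkpointing.

Training follows the published recipe: SGD with momentum 0.99, batch size 4
(configurable down for CPU-scale runs), random subvolume crops, live
augmentation, the combined Dice/cross-entropy loss, and a cosine-annealed
learning rate starting at 1e-4.  "Until convergence" is operationalised as
early stopping on the validation mean Dice score.  Runs are bit-reproducible
from the seed in single-threaded mode.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .augmentation import Sample, apply_augmentations
from .config import AugmentConfig, ModelConfig, TrainConfig
from .losses import combined_loss, softmax_probs
from .metrics import dice_score
from .model import DBAHNet
from .nn import Tensor, no_grad
from .volumes import IntensityVolume, LabelMap, CORTICAL, TRABECULAR

log = logging.getLogger(__name__)


def make_splits(scan_ids, ratios=(0.7, 0.1, 0.2), seed: int = 0):
    """Scan-level train/val/test split with sizes round(N*ratio), adjusted on
    the training set so they sum to N; deterministic under the seed."""
    ids = list(scan_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 scans to split")
    sizes = [int(round(n * r)) for r in ratios]
    sizes[0] += n - sum(sizes)
    if min(sizes) < 0:
        raise ValueError(f"degenerate split sizes {sizes}")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    train = shuffled[:sizes[0]]
    val = shuffled[sizes[0]:sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return train, val, test


def sample_crop(sample: Sample, crop, rng: np.random.Generator) -> Sample:
    """Uniformly random subvolume of exactly `crop` shape; volumes smaller
    than the crop are first padded symmetrically with background."""
    crop = tuple(int(c) for c in crop)
    img = sample.image.voxels
    lab = sample.labels.voxels
    pads = []
    for s, c in zip(img.shape, crop):
        short = max(c - s, 0)
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        img = np.pad(img, pads, constant_values=float(img.min()))
        lab = np.pad(lab, pads, constant_values=0)
    corner = [rng.integers(0, s - c + 1) for s, c in zip(img.shape, crop)]
    sl = tuple(slice(o, o + c) for o, c in zip(corner, crop))
    return Sample(
        IntensityVolume(img[sl].copy(), sample.image.spacing,
                        sample.image.intensity_units),
        LabelMap(lab[sl].copy(), sample.labels.spacing))


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine annealing: lr0 at step 0 down to lr_min at `total_steps`."""
    t = min(max(step, 0), total_steps) / total_steps
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * t))


class SGD:
    """Stochastic gradient descent with classical (non-Nesterov) momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.99):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainingState:
    step: int = 0
    lr: float = 0.0
    loss_history: list = field(default_factory=list)   # (step, lr, loss)
    val_history: list = field(default_factory=list)    # (step, mean fg DSC)
    best_val_dsc: float = -1.0
    best_step: int = -1
    seed: int = 0


def foreground_mean_dsc(pred: LabelMap, gt: LabelMap) -> float:
    return 0.5 * (dice_score(pred, gt, CORTICAL) + dice_score(pred, gt, TRABECULAR))


def predict_labels(model: DBAHNet, image: np.ndarray) -> LabelMap:
    """Single-tile argmax prediction for a crop-sized input."""
    with no_grad():
        logits = model(Tensor(image[None, None]))
    pred = np.argmax(logits.data[0], axis=0).astype(np.uint8)
    return LabelMap(pred)


def train(model: DBAHNet, train_samples, val_samples, cfg: TrainConfig,
          aug: AugmentConfig | None = None, log_rows: list | None = None,
          validate_fn=None):
    """Run the training loop; returns ``(best_state_dict, TrainingState)``.

    `validate_fn(model) -> float` overrides the default validation (mean
    foreground DSC over crop-sized validation samples); validation runs once
    per epoch (``cfg.steps_per_epoch`` steps).  A NaN loss aborts with a
    diagnostic.  With ``aug=None`` no augmentation is applied.
    """
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum)
    state = TrainingState(seed=cfg.seed)
    best_weights = model.state_dict()
    bad_epochs = 0

    def _validate():
        if validate_fn is not None:
            return float(validate_fn(model))
        if not val_samples:
            return float("nan")
        scores = []
        for s in val_samples:
            pred = predict_labels(model, s.image.voxels)
            scores.append(foreground_mean_dsc(pred, s.labels))
        return float(np.mean(scores))

    for step in range(cfg.max_steps):
        lr = cosine_lr(step, cfg.max_steps, cfg.lr0)
        opt.lr = lr
        batch_imgs, batch_labs = [], []
        for _ in range(cfg.batch_size):
            s = train_samples[rng.integers(len(train_samples))]
            s = sample_crop(s, cfg.crop, rng)
            if aug is not None:
                s = apply_augmentations(s, aug, rng)
            batch_imgs.append(s.image.voxels)
            batch_labs.append(s.labels.voxels)
        x = Tensor(np.stack(batch_imgs)[:, None])
        g = np.stack(batch_labs)
        logits = model(x)
        p = softmax_probs(logits, class_axis=1)
        loss = combined_loss(p, g, cfg.loss_alpha, cfg.loss_beta, class_axis=1)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"training diverged: loss={loss_val} at step {step} (lr={lr:g})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.step = step + 1
        state.lr = lr
        state.loss_history.append((step, lr, loss_val))
        if log_rows is not None:
            log_rows.append({"step": step, "lr": lr, "train_loss": loss_val})
        if (step + 1) % cfg.steps_per_epoch == 0 or step + 1 == cfg.max_steps:
            val_dsc = _validate()
            state.val_history.append((step + 1, val_dsc))
            log.info("step %d: loss=%.4f val_dsc=%.4f", step + 1, loss_val, val_dsc)
            if np.isnan(val_dsc) or val_dsc > state.best_val_dsc:
                state.best_val_dsc = val_dsc
                state.best_step = step + 1
                best_weights = model.state_dict()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    log.info("early stop at step %d", step + 1)
                    break
    return best_weights, state


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path, model: DBAHNet, model_cfg: ModelConfig,
                    extra: dict | None = None):
    meta = {"C": model_cfg.C, "E": list(model_cfg.E),
            "heads": list(model_cfg.heads), "depths": list(model_cfg.depths),
            "window": list(model_cfg.window), "mlp_ratio": model_cfg.mlp_ratio,
            "n_classes": model_cfg.n_classes,
            "conv_init_shrink": model_cfg.conv_init_shrink,
            "logit_gain": model_cfg.logit_gain}
    if extra:
        meta = {**meta, "extra": extra}
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __config__=json.dumps(meta), **arrays)


def load_checkpoint(path, expected_cfg: ModelConfig | None = None):
    """Rebuild a model from a checkpoint; refuses a checkpoint whose stored
    config disagrees with `expected_cfg`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        weights = {k[len("param::"):]: data[k] for k in data.files
                   if k.startswith("param::")}
    meta.pop("extra", None)
    cfg = ModelConfig(C=meta["C"], E=tuple(meta["E"]), heads=tuple(meta["heads"]),
                      depths=tuple(meta["depths"]), window=tuple(meta["window"]),
                      mlp_ratio=meta["mlp_ratio"], n_classes=meta["n_classes"],
                      conv_init_shrink=meta["conv_init_shrink"],
                      logit_gain=meta["logit_gain"])
    if expected_cfg is not None and cfg != expected_cfg:
        raise ValueError(f"checkpoint config {cfg} disagrees with requested "
                         f"{expected_cfg}")
    model = DBAHNet(cfg)
    model.load_state_dict(weights)
    return model, cfg
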