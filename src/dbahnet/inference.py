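"""Whole-volume prediction by sliding-window tiling.

Crops of the training window size are run through the network with a default
50% overlap; softmax maps are blended with a separable Hann (cosine-squared)
importance weight so tile seams do not imprint on the argmax.  Volumes
smaller than the window are padded with their minimum intensity and the
padded region is discarded from the output.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, no_grad
from .volumes import IntensityVolume, LabelMap


def _tile_starts(extent: int, window: int, stride: int):
    if extent <= window:
        return [0]
    starts = list(range(0, extent - window, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def _hann(n: int) -> np.ndarray:
    i = np.arange(n)
    w = np.sin(np.pi * (i + 0.5) / n) ** 2
    return np.maximum(w, 1e-3).astype(np.float32)


def sliding_window_predict(model, vol, window, overlap: float = 0.5,
                           return_probs: bool = False):
    """Predict a label map for `vol` (IntensityVolume or 3D array)."""
    voxels = vol.voxels if isinstance(vol, IntensityVolume) else np.asarray(vol)
    spacing = vol.spacing if isinstance(vol, IntensityVolume) else (1.0, 1.0, 1.0)
    window = tuple(int(w) for w in window)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    pads = [(0, max(w - s, 0)) for s, w in zip(voxels.shape, window)]
    padded = np.pad(voxels, pads, constant_values=float(voxels.min())) \
        if any(p[1] for p in pads) else voxels
    strides = [max(int(round(w * (1.0 - overlap))), 1) for w in window]
    weight = (_hann(window[0])[:, None, None] *
              _hann(window[1])[None, :, None] *
              _hann(window[2])[None, None, :])

    prob_acc = None
    weight_acc = np.zeros(padded.shape, np.float32)
    with no_grad():
        for x0 in _tile_starts(padded.shape[0], window[0], strides[0]):
            for y0 in _tile_starts(padded.shape[1], window[1], strides[1]):
                for z0 in _tile_starts(padded.shape[2], window[2], strides[2]):
                    sl = (slice(x0, x0 + window[0]),
                          slice(y0, y0 + window[1]),
                          slice(z0, z0 + window[2]))
                    tile = padded[sl]
                    logits = model(Tensor(tile[None, None])).data[0]
                    z = logits - logits.max(axis=0, keepdims=True)
                    e = np.exp(z)
                    probs = e / e.sum(axis=0, keepdims=True)
                    if prob_acc is None:
                        prob_acc = np.zeros((probs.shape[0], *padded.shape),
                                            np.float32)
                    prob_acc[(slice(None),) + sl] += probs * weight
                    weight_acc[sl] += weight
    prob_acc /= weight_acc
    crop = tuple(slice(0, s) for s in voxels.shape)
    prob_acc = prob_acc[(slice(None),) + crop]
    labels = LabelMap(np.argmax(prob_acc, axis=0).astype(np.uint8), spacing)
    if return_probs:
        return labels, prob_acc
    return labels
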