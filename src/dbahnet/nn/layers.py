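"""Neural-network building blocks over the autodiff core.

Modules follow the familiar container pattern: parameters are discovered by
recursing over attributes, and ``state_dict``/``load_state_dict`` exchange
plain dicts of NumPy arrays so checkpoints serialise with ``np.savez``.

Initialisation is deterministic: every module draws its weights from the
``numpy.random.Generator`` passed to its constructor.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, conv3d, conv_transpose3d, layer_norm


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable even under no_grad


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +/- 2 std, the common transformer init."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(trunc_normal(rng, (d_in, d_out), std))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Conv3d(Module):
    """He-initialised 3D convolution, layout (B, C, X, Y, Z)."""

    def __init__(self, c_in: int, c_out: int, kernel, rng: np.random.Generator,
                 stride=1, padding=0, bias: bool = True):
        k = kernel if isinstance(kernel, (tuple, list)) else (kernel,) * 3
        fan_in = c_in * int(np.prod(k))
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_out, c_in, *k)).astype(np.float32))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel, rng: np.random.Generator,
                 stride=1, padding=0, bias: bool = True):
        k = kernel if isinstance(kernel, (tuple, list)) else (kernel,) * 3
        fan_in = c_in * int(np.prod(k))
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_in, c_out, *k)).astype(np.float32))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, self.stride,
                                self.padding)


class ChannelNorm(Module):
    """Layer norm over the channel axis of a (B, C, X, Y, Z) feature map."""

    def __init__(self, channels: int):
        self.norm = LayerNorm(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = x.transpose(0, 2, 3, 4, 1)
        y = self.norm(y)
        return y.transpose(0, 4, 1, 2, 3)


class InstanceNorm3d(Module):
    """Per-channel normalisation over the spatial axes of (B, C, X, Y, Z).

    Unlike a cross-channel layer norm it preserves per-position intensity
    contrasts within each channel map — the behaviour segmentation networks
    rely on for voxel-level discrimination.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class MLP(Module):
    """Two-layer GELU feed-forward block used inside transformer layers."""

    def __init__(self, dim: int, ratio: float, rng: np.random.Generator):
        hidden = int(dim * ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())
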