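"""DBAHNet: dual-branch attention-based hybrid encoder–decoder for 3D
cortical/trabecular bone segmentation.

The network projects a one-channel volume into a C-channel embedding via
strided convolutions (per-axis reduction E), then runs three hierarchical
levels, each holding two parallel branches:

* a transformer branch — a pair of 3D shifted-window (Swin) attention blocks
  (regular partitioning, then shifted partitioning) followed by a stride-2
  convolution;
* a convolution branch — a channel-wise attention convolution module (CACM)
  in the encoder / spatial-wise attention module (SACM) in the decoder, each
  ending in a stride-2 (transposed, in the decoder) convolution.

The branches are merged at every level by a transformer–convolution feature
fusion module (TCFFM): per-branch channel gating by sigmoid masks, a 1x1x1
fusion convolution, and one local-window transformer block.  The bottleneck
applies four global (un-windowed) transformer blocks to the 8C feature map.
Decoder levels mirror the encoder; skip connections are filtered by
cross-attention gates in which encoder features provide keys/values and
decoder features the queries.  A cascade of transposed convolutions restores
the input resolution and a 1x1x1 convolution emits the class logits.

Windowed attention uses learned per-head relative position bias and cyclic
shift with masking for the shifted variant (shift = half the window per
axis).  Feature maps are laid out ``(B, C, X, Y, Z)``.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ModelConfig
from .nn import (Tensor, Module, Linear, LayerNorm, Conv3d, ConvTranspose3d,
                 InstanceNorm3d, MLP, Parameter, trunc_normal, concat, softmax)

_NEG = -1.0e4


# ---------------------------------------------------------------------------
# window bookkeeping (pure NumPy; no gradients flow through these tables)

def _pad_extents(spatial, window):
    return tuple(int(math.ceil(s / w)) * w for s, w in zip(spatial, window))


def window_partition(x: Tensor, window):
    """(B, C, X, Y, Z) -> (B * n_windows, T, C) with zero padding to window
    multiples.  Returns the token tensor and the padded extents."""
    b, c, sx, sy, sz = x.shape
    px, py, pz = _pad_extents((sx, sy, sz), window)
    if (px, py, pz) != (sx, sy, sz):
        x = x.pad(((0, 0), (0, 0), (0, px - sx), (0, py - sy), (0, pz - sz)))
    wx, wy, wz = window
    nx, ny, nz = px // wx, py // wy, pz // wz
    x = x.reshape(b, c, nx, wx, ny, wy, nz, wz)
    x = x.transpose(0, 2, 4, 6, 3, 5, 7, 1)
    return x.reshape(b * nx * ny * nz, wx * wy * wz, c), (px, py, pz)


def window_reverse(tokens: Tensor, window, padded, spatial, batch: int, channels: int):
    """Inverse of :func:`window_partition` (crops the padding back off)."""
    wx, wy, wz = window
    px, py, pz = padded
    nx, ny, nz = px // wx, py // wy, pz // wz
    x = tokens.reshape(batch, nx, ny, nz, wx, wy, wz, channels)
    x = x.transpose(0, 7, 1, 4, 2, 5, 3, 6)
    x = x.reshape(batch, channels, px, py, pz)
    sx, sy, sz = spatial
    if (px, py, pz) != (sx, sy, sz):
        x = x[:, :, :sx, :sy, :sz]
    return x


def _stride_offsets(stride):
    """Voxel offsets of a stride cell, in a fixed axis-major order."""
    import itertools
    return list(itertools.product(*(range(s) for s in stride)))


def relative_position_index(window) -> np.ndarray:
    """(T, T) index into the (2wx-1)(2wy-1)(2wz-1) relative-bias table."""
    wx, wy, wz = window
    coords = np.stack(np.meshgrid(np.arange(wx), np.arange(wy), np.arange(wz),
                                  indexing="ij"), axis=0).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]
    rel = rel + np.array([wx - 1, wy - 1, wz - 1])[:, None, None]
    return (rel[0] * (2 * wy - 1) + rel[1]) * (2 * wz - 1) + rel[2]


def shifted_window_mask(padded, window, shift) -> np.ndarray:
    """(n_windows, T, T) additive mask enforcing that tokens brought together
    by the cyclic shift do not attend across original region boundaries."""
    img = np.zeros(padded, dtype=np.int64)
    region = 0
    segs = []
    for p, w, s in zip(padded, window, shift):
        if s == 0:
            segs.append([slice(0, p)])
        else:
            segs.append([slice(0, p - w), slice(p - w, p - s), slice(p - s, p)])
    for sx in segs[0]:
        for sy in segs[1]:
            for sz in segs[2]:
                img[sx, sy, sz] = region
                region += 1
    wx, wy, wz = window
    nx, ny, nz = padded[0] // wx, padded[1] // wy, padded[2] // wz
    img = img.reshape(nx, wx, ny, wy, nz, wz).transpose(0, 2, 4, 1, 3, 5)
    ids = img.reshape(nx * ny * nz, wx * wy * wz)
    mask = np.where(ids[:, :, None] == ids[:, None, :], 0.0, _NEG)
    return mask.astype(np.float32)


# ---------------------------------------------------------------------------
# attention blocks

class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention over token sequences.

    Computes ``Softmax(Q K^T / sqrt(d_k)) V`` per head, with an optional
    additive logit bias (relative position bias and/or shift mask).
    """

    def __init__(self, dim: int, heads: int, rng, kv_dim: int | None = None):
        if dim % heads:
            raise ValueError(f"{heads} heads do not divide {dim} channels")
        self.heads = heads
        self.d_k = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(kv_dim or dim, dim, rng)
        self.v = Linear(kv_dim or dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, q_tokens: Tensor, kv_tokens: Tensor,
                bias=None) -> Tensor:
        b, tq, dim = q_tokens.shape
        tk = kv_tokens.shape[1]
        h, dk = self.heads, self.d_k

        def split(t, n_tok):
            return t.reshape(b, n_tok, h, dk).transpose(0, 2, 1, 3)

        q = split(self.q(q_tokens), tq)
        k = split(self.k(kv_tokens), tk)
        v = split(self.v(kv_tokens), tk)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))
        if bias is not None:
            logits = logits + (bias if isinstance(bias, Tensor) else Tensor(bias))
        attn = softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, tq, dim)
        return self.proj(out)


class WindowAttentionBlock(Module):
    """One pre-norm transformer layer with (optionally shifted) windowed
    multi-head self-attention and a GELU MLP, both with residual paths."""

    def __init__(self, dim: int, heads: int, window, rng,
                 shifted: bool = False, mlp_ratio: float = 4.0):
        self.window = tuple(window)
        self.shift = tuple(w // 2 for w in window) if shifted else (0, 0, 0)
        self.shifted = shifted
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.rel_bias = Parameter(trunc_normal(
            rng, (int(np.prod([2 * w - 1 for w in window])), heads)))
        self._rel_index = relative_position_index(self.window)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_ratio, rng)
        self._mask_cache: dict = {}

    def _bias(self, padded, batch_windows: int, batch: int) -> Tensor:
        # (T, T, heads) -> (1, heads, T, T); gradient flows into the table
        tbl = self.rel_bias[self._rel_index]
        bias = tbl.transpose(2, 0, 1).reshape(
            1, self.attn.heads, self._rel_index.shape[0], self._rel_index.shape[1])
        if self.shifted and any(self.shift):
            key = padded
            if key not in self._mask_cache:
                self._mask_cache[key] = shifted_window_mask(
                    padded, self.window, self.shift)
            m = self._mask_cache[key]                     # (nw, T, T)
            nw = m.shape[0]
            m = np.broadcast_to(m[None, :, None], (batch, nw, 1, *m.shape[1:]))
            m = m.reshape(batch * nw, 1, *m.shape[3:])
            bias = bias + Tensor(m)
        return bias

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        h = x.transpose(0, 2, 3, 4, 1)                    # (B, X, Y, Z, C)
        h = self.norm1(h).transpose(0, 4, 1, 2, 3)
        if self.shifted and any(self.shift):
            h = h.roll(tuple(-s for s in self.shift), axis=(2, 3, 4))
        tokens, padded = window_partition(h, self.window)
        bias = self._bias(padded, tokens.shape[0], b)
        out_tokens = self.attn(tokens, tokens, bias=bias)
        h = window_reverse(out_tokens, self.window, padded, spatial, b, c)
        if self.shifted and any(self.shift):
            h = h.roll(self.shift, axis=(2, 3, 4))
        x = x + h
        h = x.transpose(0, 2, 3, 4, 1)
        h = self.mlp(self.norm2(h))
        return x + h.transpose(0, 4, 1, 2, 3)


class SwinBlockPair(Module):
    """Regular-partition block followed by a shifted-partition block."""

    def __init__(self, dim: int, heads: int, window, rng, mlp_ratio: float = 4.0):
        self.block1 = WindowAttentionBlock(dim, heads, window, rng,
                                           shifted=False, mlp_ratio=mlp_ratio)
        self.block2 = WindowAttentionBlock(dim, heads, window, rng,
                                           shifted=True, mlp_ratio=mlp_ratio)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class GlobalTransformerBlock(Module):
    """ViT-style pre-norm transformer layer with global (un-windowed)
    attention over every spatial position."""

    def __init__(self, dim: int, heads: int, rng, mlp_ratio: float = 4.0):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        t = int(np.prod(spatial))
        tok = x.reshape(b, c, t).transpose(0, 2, 1)
        n = self.norm1(tok)
        tok = tok + self.attn(n, n)
        tok = tok + self.mlp(self.norm2(tok))
        return tok.transpose(0, 2, 1).reshape(b, c, *spatial)


class AttentionGate(Module):
    """Cross-attention skip filter: encoder features (keys/values) gate the
    decoder features (queries) through one transformer layer.

    Like every transformer block outside the bottleneck, the layer operates
    on local volumes: query and skip are partitioned into the same window
    grid and cross-attention runs within each window pair.  With ``window``
    None (or a window covering the whole map) the attention is global.
    """

    def __init__(self, dim: int, heads: int, rng, window=None,
                 mlp_ratio: float = 4.0):
        self.window = tuple(window) if window is not None else None
        self.norm_q = LayerNorm(dim)
        self.norm_kv = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_ratio, rng)

    def forward(self, query: Tensor, skip: Tensor) -> Tensor:
        if query.shape[2:] != skip.shape[2:]:
            raise ValueError(f"gate spatial mismatch: {query.shape} vs {skip.shape}")
        b, c = query.shape[0], query.shape[1]
        spatial = query.shape[2:]
        if self.window is None:
            t = int(np.prod(spatial))
            q = query.reshape(b, c, t).transpose(0, 2, 1)
            kv = skip.reshape(b, c, t).transpose(0, 2, 1)
            x = q + self.attn(self.norm_q(q), self.norm_kv(kv))
            x = x + self.mlp(self.norm2(x))
            return x.transpose(0, 2, 1).reshape(b, c, *spatial)
        q, padded = window_partition(query, self.window)
        kv, _ = window_partition(skip, self.window)
        x = q + self.attn(self.norm_q(q), self.norm_kv(kv))
        x = x + self.mlp(self.norm2(x))
        return window_reverse(x, self.window, padded, spatial, b, c)


# ---------------------------------------------------------------------------
# convolution branches and fusion

class CACM(Module):
    """Channel-wise attention convolution module (encoder branch).

    Global average- and max-pooled channel descriptors are concatenated,
    squeezed to C/2 and re-expanded by 1x1x1 convolutions (GELU between),
    passed through a sigmoid to a channel attention map that modulates the
    input, and a final stride-2 convolution doubles the channels while
    halving every spatial extent.
    """

    def __init__(self, channels: int, rng):
        if channels % 2:
            raise ValueError("CACM needs an even channel count")
        self.squeeze = Conv3d(2 * channels, channels // 2, 1, rng)
        self.expand = Conv3d(channels // 2, channels, 1, rng)
        self.down = Conv3d(channels, 2 * channels, 3, rng, stride=2, padding=1)

    def attention_map(self, x: Tensor) -> Tensor:
        gap = x.mean(axis=(2, 3, 4), keepdims=True)
        gmp = x.max(axis=(2, 3, 4), keepdims=True)
        d = concat([gap, gmp], axis=1)
        return self.expand(self.squeeze(d).gelu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"CACM needs even spatial extents, got {x.shape[2:]}")
        return self.down(x * self.attention_map(x))


class SACM(Module):
    """Spatial-wise attention convolution module (decoder branch).

    Channel-wise max and mean maps are concatenated and reduced by a 1x1x1
    convolution to a single-channel sigmoid attention map that modulates the
    input; a stride-2 transposed convolution then halves the channels while
    doubling every spatial extent.
    """

    def __init__(self, channels: int, rng):
        if channels % 2:
            raise ValueError("SACM needs an even channel count")
        self.mix = Conv3d(2, 1, 1, rng)
        self.up = ConvTranspose3d(channels, channels // 2, 2, rng, stride=2)

    def attention_map(self, x: Tensor) -> Tensor:
        mx = x.max(axis=1, keepdims=True)
        av = x.mean(axis=1, keepdims=True)
        return self.mix(concat([mx, av], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return self.up(x * self.attention_map(x))


class TCFFM(Module):
    """Transformer–convolution feature fusion.

    Each branch is reweighted by a sigmoid mask of its channel-averaged
    descriptor, the branches are concatenated, a 1x1x1 convolution fuses them
    back to the branch width, and one local-window transformer block mixes
    the result spatially.
    """

    def __init__(self, channels: int, heads: int, window, rng,
                 mlp_ratio: float = 4.0):
        self.fuse = Conv3d(2 * channels, channels, 1, rng)
        self.block = WindowAttentionBlock(channels, heads, window, rng,
                                          shifted=False, mlp_ratio=mlp_ratio)

    def forward(self, x_tr: Tensor, x_c: Tensor) -> Tensor:
        if x_tr.shape != x_c.shape:
            raise ValueError(f"TCFFM shape mismatch: {x_tr.shape} vs {x_c.shape}")
        m_tr = x_tr.mean(axis=(2, 3, 4), keepdims=True).sigmoid()
        m_c = x_c.mean(axis=(2, 3, 4), keepdims=True).sigmoid()
        fused = self.fuse(concat([x_tr * m_tr, x_c * m_c], axis=1))
        return self.block(fused)


# ---------------------------------------------------------------------------
# embedding, head, levels

class PatchEmbed(Module):
    """Cascade of strided 3x3x3 convolutions whose per-axis stride product
    equals E, each followed by channel layer-norm and GELU.

    The first convolution is initialised as a space-to-depth rearrangement:
    channel ``i`` samples voxel offset ``i`` of its stride cell, so the
    embedding starts as an invertible rearrangement of the raw intensities
    (remaining channels keep their random init).  Together with the matching
    head initialisation this makes the freshly built network an
    identity-preserving map of the input — a strong starting point for the
    segmentation objective.
    """

    def __init__(self, cfg: ModelConfig, rng):
        remaining = list(cfg.E)
        n_steps = max(int(math.log2(e)) for e in remaining)
        chans = [1] + [cfg.C] * n_steps
        self.convs, self.norms = [], []
        for i in range(n_steps):
            stride = tuple(2 if remaining[a] > 1 else 1 for a in range(3))
            remaining = [r // s for r, s in zip(remaining, stride)]
            self.convs.append(Conv3d(chans[i], chans[i + 1], 3, rng,
                                     stride=stride, padding=1))
            self.norms.append(InstanceNorm3d(chans[i + 1]))
        self.E = cfg.E
        first = self.convs[0]
        for i, (dx, dy, dz) in enumerate(_stride_offsets(first.stride)):
            if i >= first.weight.shape[0]:
                break
            w = np.zeros(first.weight.shape[1:], np.float32)
            # kernel index sampling input voxel (stride*out + offset), pad 1
            w[0, dx + 1, dy + 1, dz + 1] = 1.0
            first.weight.data[i] = w

    def forward(self, x: Tensor) -> Tensor:
        for a, (s, e) in enumerate(zip(x.shape[2:], self.E)):
            if s % (e * 8):
                raise ValueError(
                    f"input extent {s} on axis {a} not divisible by E*8={e * 8}")
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).gelu()
        return x


class SegmentationHead(Module):
    """Transposed convolutions undoing the patch embedding reduction, then a
    1x1x1 convolution to the class logits.

    The first transposed convolution is initialised with a depth-to-space
    channel: output channel 0 reassembles the stride cell from the channels
    the patch embedding's space-to-depth init produced, so at construction
    time the head sees a (monotonically transformed) copy of the input
    intensity at full resolution.  The 1x1x1 output convolution carries a
    fixed logit gain (see ``ModelConfig``).
    """

    def __init__(self, cfg: ModelConfig, rng):
        remaining = list(cfg.E)
        n_steps = max(int(math.log2(e)) for e in remaining)
        self.ups, self.norms = [], []
        ch = cfg.C
        wide = 2 * cfg.C                 # decoding width at fine resolution
        for i in range(n_steps):
            stride = tuple(2 if remaining[a] > 1 else 1 for a in range(3))
            remaining = [r // s for r, s in zip(remaining, stride)]
            # kernel 2x the stride (with cropping) so neighbouring coarse
            # cells overlap and fine structure can be reconstructed
            kernel = tuple(2 * s if s > 1 else 1 for s in stride)
            padding = tuple(s // 2 if s > 1 else 0 for s in stride)
            self.ups.append(ConvTranspose3d(ch, wide, kernel, rng,
                                            stride=stride, padding=padding))
            self.norms.append(InstanceNorm3d(wide))
            ch = wide
        self.out = Conv3d(ch, cfg.n_classes, 1, rng)
        first = self.ups[0]
        first.weight.data[:, 0] = 0.0          # reserve channel 0
        for i, (dx, dy, dz) in enumerate(_stride_offsets(first.stride)):
            if i >= first.weight.shape[0]:
                break
            # transposed kernel index writing output voxel stride*in + offset
            kx = dx + (1 if first.stride[0] > 1 else 0)
            ky = dy + (1 if first.stride[1] > 1 else 0)
            kz = dz + (1 if first.stride[2] > 1 else 0)
            first.weight.data[i, 0, kx, ky, kz] = 1.0
        self.logit_gain = float(cfg.logit_gain)
        # keep initial logits O(1) despite the gain
        self.out.weight.data = rng.normal(
            0.0, 0.5 / max(self.logit_gain, 1.0),
            size=self.out.weight.shape).astype(np.float32)

    def forward(self, x: Tensor) -> Tensor:
        for up, norm in zip(self.ups, self.norms):
            x = norm(up(x)).gelu()
        return self.out(x) * self.logit_gain


class EncoderLevel(Module):
    """Swin pair + stride-2 conv (transformer branch) in parallel with CACM
    (convolution branch), fused by a TCFFM: channels double, extents halve."""

    def __init__(self, channels: int, heads: int, heads_next: int, window,
                 rng, mlp_ratio: float = 4.0):
        self.swin = SwinBlockPair(channels, heads, window, rng, mlp_ratio)
        self.tr_down = Conv3d(channels, 2 * channels, 3, rng, stride=2, padding=1)
        self.cacm = CACM(channels, rng)
        self.tcffm = TCFFM(2 * channels, heads_next, window, rng, mlp_ratio)

    def forward(self, x: Tensor) -> Tensor:
        x_tr = self.tr_down(self.swin(x))
        x_c = self.cacm(x)
        return self.tcffm(x_tr, x_c)


class DecoderLevel(Module):
    """Mirror of :class:`EncoderLevel` with SACM and transposed convolutions:
    channels halve, extents double; the result is gated against the encoder
    skip of matching scale."""

    def __init__(self, channels: int, heads: int, heads_out: int, window,
                 rng, mlp_ratio: float = 4.0):
        self.swin = SwinBlockPair(channels, heads, window, rng, mlp_ratio)
        self.tr_up = ConvTranspose3d(channels, channels // 2, 2, rng, stride=2)
        self.sacm = SACM(channels, rng)
        self.tcffm = TCFFM(channels // 2, heads_out, window, rng, mlp_ratio)
        self.gate = AttentionGate(channels // 2, heads_out, rng, window,
                                  mlp_ratio)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x_tr = self.tr_up(self.swin(x))
        x_c = self.sacm(x)
        fused = self.tcffm(x_tr, x_c)
        # attention-gated skip plus the encoder residual skip connection
        return self.gate(fused, skip) + skip


class DBAHNet(Module):
    """The full dual-branch attention-based hybrid network."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        C, W, r = cfg.C, cfg.window, cfg.mlp_ratio
        h = cfg.heads
        self.embed = PatchEmbed(cfg, rng)
        self.enc_levels = [
            EncoderLevel(C * 2 ** s, h[s], h[min(s + 1, 3)], W, rng, r)
            for s in range(3)]
        self.bottleneck = [GlobalTransformerBlock(8 * C, h[3], rng, r)
                           for _ in range(4)]
        self.dec_levels = [
            DecoderLevel(C * 2 ** (s + 1), h[min(s + 1, 3)], h[s], W, rng, r)
            for s in reversed(range(3))]            # deepest level first
        self.head = SegmentationHead(cfg, rng)
        if cfg.conv_init_shrink != 1.0:
            shrink = np.float32(cfg.conv_init_shrink)
            out_w = self.head.out.weight
            for name, p in self.named_parameters():
                # convolution kernels only — never normalisation gains
                if (p.data.ndim == 5 and name.endswith(".weight")
                        and p is not out_w):
                    p.data /= shrink

    def encode(self, x: Tensor):
        """Returns (embedding, [level outputs F1..F3]); F3 is the 8C map that
        enters the bottleneck."""
        f0 = self.embed(x)
        feats = [f0]
        h = f0
        for level in self.enc_levels:
            h = level(h)
            feats.append(h)
        return f0, feats

    def forward(self, x: Tensor) -> Tensor:
        _, feats = self.encode(x)
        h = feats[-1]
        for blk in self.bottleneck:
            h = blk(h)
        skips = feats[:-1]                          # scales 8C/2 ... C
        for level, skip in zip(self.dec_levels, reversed(skips)):
            h = level(h, skip)
        return self.head(h)
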