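"""PIDSAN4: parallel inverted dual self-attention network.

A lightweight hybrid classifier for blood-smear images.  The convolutional
trunk (a stem plus four stages of parallel inverted-bottleneck blocks with
max-pool downsampling) extracts local morphology; the resulting feature map
is resampled to an 8x8 grid, embedded into 16 patch tokens, and refined by a
pair of self-attentions — one over the spatial token axis, one over the
channel axis — fused back into the embedding with learnable weights
(initialised at 0.5 each).  A global average pool over tokens, dropout, a
fully connected layer and a softmax produce the class probabilities.

The class imbalance of the training data is handled by weighting the
categorical cross-entropy with weights inversely proportional to class
occurrence, w_c = T / (C * n_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    BatchNorm2d, Conv2d, Dropout, Linear, Module, Tensor,
    get_activation, maxpool2x2, swish,
)

__all__ = [
    "Pidsan4Config", "InvertedBottleneck", "Pidsan4",
    "class_weights", "weighted_cross_entropy", "downsample_stage",
]


@dataclass
class Pidsan4Config:
    """Architecture hyperparameters.

    ``stem_channels`` are the widths of the two stem convolutions; the second
    one is the trunk width at which every inverted-bottleneck block operates.
    ``section_depth`` repeats each bottleneck stage (the searched
    "section depth" hyperparameter).  ``activation`` is the searched stem /
    intermediate activation; the bottleneck branches always use swish.
    """

    input_size: int = 224
    in_channels: int = 3
    stem_channels: tuple = (32, 64)
    n_stages: int = 4
    n_patches: int = 16
    embed_dim: int = 64
    n_classes: int = 2
    fusion_init: float = 0.5
    section_depth: int = 1
    dropout_rate: float = 0.5
    activation: str = "relu"
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        grid = math.isqrt(self.n_patches)
        if grid * grid != self.n_patches:
            raise ValueError(f"n_patches must be a perfect square, got {self.n_patches}")
        if self.section_depth < 1:
            raise ValueError(f"section_depth must be >= 1, got {self.section_depth}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.input_size < 32:
            raise ValueError(f"input_size must be >= 32, got {self.input_size}")

    @property
    def trunk_width(self) -> int:
        return self.stem_channels[1]

    @classmethod
    def reduced(cls, input_size: int = 64, seed: int = 0, **kw) -> "Pidsan4Config":
        """Narrow configuration used for CPU-scale experiments and tests."""
        kw.setdefault("stem_channels", (8, 16))
        kw.setdefault("embed_dim", 16)
        kw.setdefault("dropout_rate", 0.1)
        kw.setdefault("dtype", "float32")
        return cls(input_size=input_size, seed=seed, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stem_channels"] = list(self.stem_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Pidsan4Config":
        d = dict(d)
        d["stem_channels"] = tuple(d["stem_channels"])
        return cls(**d)


def _np_dtype(name: str):
    return {"float32": np.float32, "float64": np.float64}[name]


class InvertedBottleneck(Module):
    """Two parallel expand -> depthwise -> project branches plus a skip.

    Each branch: 1x1 expansion conv + batch norm + swish, 3x3 depthwise conv
    (groups == channels) + batch norm + swish, 1x1 projection conv.  The two
    branch outputs are summed elementwise and added to the block input.
    Spatial dimensions and channel depth are preserved.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float64,
                 n_branches: int = 2):
        super().__init__()
        self.branches = []
        for _ in range(n_branches):
            self.branches.append([
                Conv2d(channels, channels, 1, rng, dtype=dtype),
                BatchNorm2d(channels, dtype=dtype),
                Conv2d(channels, channels, 3, rng, padding=1, groups=channels, dtype=dtype),
                BatchNorm2d(channels, dtype=dtype),
                Conv2d(channels, channels, 1, rng, dtype=dtype),
            ])

    def _submodules(self):
        for branch in self.branches:
            yield from branch

    def named_parameters(self, prefix: str = ""):
        for bi, branch in enumerate(self.branches):
            for li, layer in enumerate(branch):
                yield from layer.named_parameters(f"{prefix}branches.{bi}.{li}.")

    def named_buffers(self, prefix: str = ""):
        for bi, branch in enumerate(self.branches):
            for li, layer in enumerate(branch):
                yield from layer.named_buffers(f"{prefix}branches.{bi}.{li}.")

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for expand, bn1, depthwise, bn2, project in self.branches:
            h = swish(bn1(expand(x)))
            h = swish(bn2(depthwise(h)))
            out = out + project(h)
        return out


def downsample_stage(x: Tensor, activation=swish) -> Tensor:
    """2x2 max pooling (stride 2) followed by an activation (swish default)."""
    return activation(maxpool2x2(x))


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Bilinear (align-corners) 1-D interpolation matrix, shape (n_out, n_in)."""
    R = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        R[:, 0] = 1.0
        return R
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    for i in range(n_out):
        R[i, lo[i]] += 1.0 - frac[i]
        R[i, hi[i]] += frac[i]
    return R


class PatchEmbed(Module):
    """Resample a feature map to an 8x8 grid and embed 16 2x2 patches.

    The trunk output (7x7 for a 224 input) cannot tile into 16 square
    patches, so it is bilinearly resampled to 8x8 first; a 4x4 grid of 2x2
    patches is then flattened and affinely projected to ``embed_dim``.
    """

    GRID = 8
    PATCH = 2

    def __init__(self, channels: int, embed_dim: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        self.channels = channels
        self.proj = Linear(self.PATCH * self.PATCH * channels, embed_dim, rng, dtype=dtype)
        self.dtype = dtype

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        if (H, W) != (self.GRID, self.GRID):
            Rh = Tensor(_resize_matrix(H, self.GRID, self.dtype))
            Rw = Tensor(_resize_matrix(W, self.GRID, self.dtype).T)
            x = Rh @ x @ Rw
        g = self.GRID // self.PATCH                       # 4x4 grid of patches
        x = x.reshape(B, C, g, self.PATCH, g, self.PATCH)
        x = x.transpose((0, 2, 4, 3, 5, 1))               # (B, g, g, 2, 2, C)
        tokens = x.reshape(B, g * g, self.PATCH * self.PATCH * C)
        return self.proj(tokens)                          # (B, 16, D)


class TokenSelfAttention(Module):
    """Scaled dot-product self-attention over tokens or over channels.

    ``axis="spatial"`` attends across the N tokens (each row of the softmax
    sums to 1 over tokens); ``axis="channel"`` transposes the sequence first
    so attention runs across the D feature channels.
    """

    def __init__(self, n_tokens: int, dim: int, axis: str, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        if axis not in ("spatial", "channel"):
            raise ValueError(f"axis must be 'spatial' or 'channel', got {axis!r}")
        self.axis = axis
        width = dim if axis == "spatial" else n_tokens
        if width < 1:
            raise ValueError("attention head dimension must be positive")
        self.d_k = width
        self.q = Linear(width, width, rng, dtype=dtype)
        self.k = Linear(width, width, rng, dtype=dtype)
        self.v = Linear(width, width, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.axis == "channel":
            x = x.swapaxes(-1, -2)
        q, k, v = self.q(x), self.k(x), self.v(x)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        out = scores.softmax(axis=-1) @ v
        if self.axis == "channel":
            out = out.swapaxes(-1, -2)
        return out

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Attention matrix rows (each sums to 1); for inspection/tests."""
        if self.axis == "channel":
            x = x.swapaxes(-1, -2)
        q, k = self.q(x), self.k(x)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        return scores.softmax(axis=-1).data


def dual_attention_fuse(phi_e: Tensor, spatial: Tensor, channel: Tensor,
                        alpha, beta) -> Tensor:
    """phi_E + alpha * spatial + beta * channel (alpha, beta trainable scalars)."""
    if phi_e.shape != spatial.shape or phi_e.shape != channel.shape:
        raise ValueError(
            f"shape mismatch: {phi_e.shape}, {spatial.shape}, {channel.shape}")
    return phi_e + alpha * spatial + beta * channel


class Pidsan4(Module):
    """Full PIDSAN4 classifier; ``forward`` maps (B, 3, S, S) to (B, n_classes)."""

    def __init__(self, cfg: Pidsan4Config | None = None):
        super().__init__()
        cfg = cfg or Pidsan4Config()
        self.cfg = cfg
        dtype = _np_dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.act = get_activation(cfg.activation)
        c1, c2 = cfg.stem_channels
        self.stem_conv1 = Conv2d(cfg.in_channels, c1, 3, rng, stride=2, padding=1, dtype=dtype)
        self.stem_bn1 = BatchNorm2d(c1, dtype=dtype)
        self.stem_conv2 = Conv2d(c1, c2, 3, rng, stride=1, padding=1, dtype=dtype)
        self.stem_bn2 = BatchNorm2d(c2, dtype=dtype)
        self.stages = [
            [InvertedBottleneck(c2, rng, dtype=dtype) for _ in range(cfg.section_depth)]
            for _ in range(cfg.n_stages)
        ]
        self.patch_embed = PatchEmbed(c2, cfg.embed_dim, rng, dtype=dtype)
        self.spatial_attn = TokenSelfAttention(cfg.n_patches, cfg.embed_dim, "spatial",
                                               rng, dtype=dtype)
        self.channel_attn = TokenSelfAttention(cfg.n_patches, cfg.embed_dim, "channel",
                                               rng, dtype=dtype)
        self.fuse_alpha = Tensor(np.asarray(cfg.fusion_init, dtype=dtype), requires_grad=True)
        self.fuse_beta = Tensor(np.asarray(cfg.fusion_init, dtype=dtype), requires_grad=True)
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.head = Linear(cfg.embed_dim, cfg.n_classes, rng, dtype=dtype,
                           init_scale=0.1)

    def _submodules(self):
        yield from super()._submodules()
        for stage in self.stages:
            yield from stage

    def named_parameters(self, prefix: str = ""):
        yield from super().named_parameters(prefix)
        for si, stage in enumerate(self.stages):
            for bi, block in enumerate(stage):
                yield from block.named_parameters(f"{prefix}stages.{si}.{bi}.")

    def named_buffers(self, prefix: str = ""):
        yield from super().named_buffers(prefix)
        for si, stage in enumerate(self.stages):
            for bi, block in enumerate(stage):
                yield from block.named_buffers(f"{prefix}stages.{si}.{bi}.")

    def features(self, x: Tensor) -> Tensor:
        """Trunk + patch embedding + dual attention; returns (B, 16, D) tokens."""
        B, C, H, W = x.shape
        if C != self.cfg.in_channels or H != self.cfg.input_size or W != self.cfg.input_size:
            raise ValueError(
                f"expected input (B, {self.cfg.in_channels}, {self.cfg.input_size}, "
                f"{self.cfg.input_size}), got {x.shape}")
        h = self.act(self.stem_bn1(self.stem_conv1(x)))
        h = self.act(self.stem_bn2(self.stem_conv2(h)))
        for stage in self.stages:
            for block in stage:
                h = block(h)
            h = downsample_stage(h)
        phi_e = self.patch_embed(h)
        s = self.spatial_attn(phi_e)
        c = self.channel_attn(phi_e)
        return dual_attention_fuse(phi_e, s, c, self.fuse_alpha, self.fuse_beta)

    def forward(self, x: Tensor) -> Tensor:
        tokens = self.features(x)
        pooled = tokens.mean(axis=1)          # global average pool over tokens
        logits = self.head(self.dropout(pooled))
        return logits.softmax(axis=-1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probabilities for a (B, S, S, 3) channel-last image batch (eval mode)."""
        from .nn import no_grad
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                x = Tensor(np.ascontiguousarray(
                    np.transpose(images, (0, 3, 1, 2))).astype(_np_dtype(self.cfg.dtype)))
                return self.forward(x).data
        finally:
            self.train(was_training)

    def describe(self) -> dict:
        """Parameter and leaf-layer counts of the instantiated model."""
        n_layers = 0

        def walk(m: Module):
            nonlocal n_layers
            subs = list(m._submodules())
            if not subs:
                n_layers += 1
            for s in subs:
                walk(s)

        walk(self)
        return {"parameters": self.count_parameters(), "leaf_layers": n_layers}


def class_weights(counts) -> np.ndarray:
    """w_c = T / (C * n_c): inverse-frequency class weights.

    With counts (5531, 5530) this gives (0.99990958..., 1.00009043...) — an
    almost balanced correction for a nearly balanced dataset; with (10, 90)
    it up-weights the minority class to 5.0.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a 1-D sequence of per-class sample counts")
    if np.any(counts <= 0):
        raise ValueError(f"every class count must be positive, got {counts}")
    total = counts.sum()
    return total / (counts.size * counts)


def weighted_cross_entropy(probs, onehot, weights=None, eps: float = 1e-12):
    """Class-weighted categorical cross-entropy, averaged over the batch.

    ``probs`` may be a Tensor (gradient flows through) or an array.  Each row
    of ``probs`` must lie on the simplex and each row of ``onehot`` must be
    one-hot.  Probabilities are clamped at ``eps`` before the log so a zero
    probability at the true class yields a large finite loss instead of inf.
    With unit weights this is the ordinary categorical cross-entropy.
    """
    is_tensor = isinstance(probs, Tensor)
    p = probs if is_tensor else Tensor(np.asarray(probs, dtype=np.float64))
    o = np.asarray(onehot.data if isinstance(onehot, Tensor) else onehot, dtype=np.float64)
    if p.shape != o.shape:
        raise ValueError(f"probs shape {p.shape} != onehot shape {o.shape}")
    n_classes = o.shape[-1]
    if weights is None:
        w = np.ones(n_classes)
    else:
        w = np.asarray(weights, dtype=np.float64)
    if w.shape != (n_classes,):
        raise ValueError(f"weights must have shape ({n_classes},), got {w.shape}")
    batch = o.shape[0] if o.ndim == 2 else 1
    ow = (o * w).astype(p.dtype) if p.dtype.kind == "f" else o * w
    loss = -(p.clip_min(eps).log() * Tensor(ow)).sum() * (1.0 / batch)
    return loss if is_tensor else float(loss.data)
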