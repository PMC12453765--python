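"""Modified ViT-Tiny/16 classifier.

Standard vision-transformer encoder (patchify into 16x16 patches, linear
patch embedding with a prepended class token and a learned 1-D positional
table, then ``depth`` pre-norm encoder layers of multi-head self-attention
and a GeLU MLP), with the original class-token readout replaced by a
modified head: layer norm, global average pooling over *all* tokens
(class token included), a new fully connected layer and a softmax.

Default shape is the Tiny/16 convention: 12 layers, 3 heads, width 192.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Dropout, LayerNorm, Linear, Module, Tensor, concat, gelu

__all__ = ["VitConfig", "patchify", "MultiHeadAttention", "EncoderLayer", "TinyViT"]


@dataclass
class VitConfig:
    patch_size: int = 16
    depth: int = 12
    heads: int = 3
    hidden: int = 192
    mlp_ratio: int = 4
    n_classes: int = 2
    input_size: int = 224
    in_channels: int = 3
    dropout_rate: float = 0.0
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch size {self.patch_size}")
        if self.hidden % self.heads:
            raise ValueError(f"hidden {self.hidden} not divisible by heads {self.heads}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")

    @property
    def n_tokens(self) -> int:
        """Patch count m = H*W/p^2 plus the class token."""
        return (self.input_size // self.patch_size) ** 2 + 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VitConfig":
        return cls(**d)


def _np_dtype(name: str):
    return {"float32": np.float32, "float64": np.float64}[name]


def patchify(img: np.ndarray, p: int) -> np.ndarray:
    """Split an H x W (x C) image into m = H*W/p^2 flattened patches.

    Patches are taken in raster order; each is the raveled (p, p, C) block,
    giving rows of length p*p*C.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        img = img[:, :, None]
    H, W, C = img.shape
    if H % p or W % p:
        raise ValueError(f"image dims {H}x{W} are not divisible by patch size {p}")
    gh, gw = H // p, W // p
    patches = img.reshape(gh, p, gw, p, C).transpose(0, 2, 1, 3, 4)
    return patches.reshape(gh * gw, p * p * C)


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product self-attention.

    A single learned matrix maps each token to its query/key/value triple;
    per head, softmax(Q K^T / sqrt(d_head)) V; head outputs are concatenated
    and linearly projected back to the model width.
    """

    def __init__(self, hidden: int, heads: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        if hidden % heads:
            raise ValueError(f"hidden {hidden} not divisible by heads {heads}")
        self.heads = heads
        self.d_head = hidden // heads
        self.qkv = Linear(hidden, 3 * hidden, rng, dtype=dtype)
        self.out = Linear(hidden, hidden, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, N, k = x.shape
        h, dh = self.heads, self.d_head
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose((2, 0, 3, 1, 4))
        q, key, v = qkv[0], qkv[1], qkv[2]          # each (B, h, N, dh)
        scores = (q @ key.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        ctx = scores.softmax(axis=-1) @ v           # (B, h, N, dh)
        merged = ctx.transpose((0, 2, 1, 3)).reshape(B, N, h * dh)
        return self.out(merged)


class EncoderLayer(Module):
    """Pre-norm transformer block: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, cfg: VitConfig, rng: np.random.Generator, dtype):
        super().__init__()
        self.ln1 = LayerNorm(cfg.hidden, dtype=dtype)
        self.attn = MultiHeadAttention(cfg.hidden, cfg.heads, rng, dtype=dtype)
        self.ln2 = LayerNorm(cfg.hidden, dtype=dtype)
        inner = cfg.hidden * cfg.mlp_ratio
        self.fc1 = Linear(cfg.hidden, inner, rng, dtype=dtype)
        self.fc2 = Linear(inner, cfg.hidden, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(gelu(self.fc1(self.ln2(x))))


class TinyViT(Module):
    """Modified tiny16 vision transformer; forward maps (B, C, S, S) to probs."""

    def __init__(self, cfg: VitConfig | None = None):
        super().__init__()
        cfg = cfg or VitConfig()
        self.cfg = cfg
        dtype = _np_dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        p, k = cfg.patch_size, cfg.hidden
        self.embed = Linear(p * p * cfg.in_channels, k, rng, dtype=dtype)
        self.cls_token = Tensor(np.zeros((1, 1, k), dtype=dtype), requires_grad=True)
        self.pos_table = Tensor(
            (0.02 * rng.standard_normal((cfg.n_tokens, k))).astype(dtype),
            requires_grad=True)
        self.layers = [EncoderLayer(cfg, rng, dtype) for _ in range(cfg.depth)]
        self.norm = LayerNorm(k, dtype=dtype)
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.head = Linear(k, cfg.n_classes, rng, dtype=dtype, init_scale=0.1)

    def embed_sequence(self, x: Tensor) -> Tensor:
        """Patchify a (B, C, S, S) batch, project, prepend cls, add positions."""
        B, C, H, W = x.shape
        cfg = self.cfg
        if C != cfg.in_channels or H != cfg.input_size or W != cfg.input_size:
            raise ValueError(
                f"expected input (B, {cfg.in_channels}, {cfg.input_size}, "
                f"{cfg.input_size}), got {x.shape}")
        p = cfg.patch_size
        gh, gw = H // p, W // p
        patches = x.reshape(B, C, gh, p, gw, p).transpose((0, 2, 4, 3, 5, 1))
        patches = patches.reshape(B, gh * gw, p * p * C)
        tokens = self.embed(patches)
        cls = self.cls_token + Tensor(np.zeros((B, 1, cfg.hidden),
                                               dtype=self.cls_token.dtype))
        return concat([cls, tokens], axis=1) + self.pos_table

    def forward(self, x: Tensor) -> Tensor:
        seq = self.embed_sequence(x)
        for layer in self.layers:
            seq = layer(seq)
        pooled = self.norm(seq).mean(axis=1)      # GAP over all m+1 tokens
        logits = self.head(self.dropout(pooled))
        return logits.softmax(axis=-1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
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
        return {"parameters": self.count_parameters(),
                "tokens": self.cfg.n_tokens}
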