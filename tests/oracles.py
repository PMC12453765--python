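"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain nested loops / direct formula
transcription, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def conv2d_ref(x, w, b=None, stride=1, padding=0, groups=1):
    """Nested-loop 2-D cross-correlation; x (B,C,H,W), w (Cout,Cg,kh,kw)."""
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((B, Cout, Ho, Wo))
    cpg_out = Cout // groups
    for n in range(B):
        for o in range(Cout):
            g = o // cpg_out
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for c in range(Cg):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (xp[n, g * Cg + c, i * stride + u, j * stride + v]
                                        * w[o, c, u, v])
                    out[n, o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def maxpool2x2_ref(x):
    B, C, H, W = x.shape
    out = np.zeros((B, C, H // 2, W // 2))
    for n in range(B):
        for c in range(C):
            for i in range(H // 2):
                for j in range(W // 2):
                    out[n, c, i, j] = max(x[n, c, 2 * i, 2 * j], x[n, c, 2 * i, 2 * j + 1],
                                          x[n, c, 2 * i + 1, 2 * j], x[n, c, 2 * i + 1, 2 * j + 1])
    return out


def swish_ref(x):
    return x / (1.0 + np.exp(-x))


def dark_channel_ref(img, window):
    """Windowed min over channels and neighbourhood; edges clamped."""
    if img.ndim == 2:
        img = img[:, :, None]
    H, W, _ = img.shape
    half = window // 2
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            lo_i, hi_i = max(0, i - half), min(H, i + half + 1)
            lo_j, hi_j = max(0, j - half), min(W, j + half + 1)
            out[i, j] = img[lo_i:hi_i, lo_j:hi_j, :].min()
    return out


def airlight_ref(img, window, top_frac):
    dc = dark_channel_ref(img, window)
    n = max(1, int(round(top_frac * dc.size)))
    order = np.argsort(dc.ravel(), kind="stable")[-n:]
    return img.reshape(-1, 3)[order].mean(axis=0)


def transmission_ref(img, airlight, window, haze_weight, t_floor):
    t = 1.0 - haze_weight * dark_channel_ref(img / airlight, window)
    return np.clip(t, t_floor, 1.0)


def softmax_ref(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def attention_ref(x, wq, bq, wk, bk, wv, bv):
    """Single-sequence scaled dot-product attention; x (N, D), loops rows."""
    q = x @ wq + bq
    k = x @ wk + bk
    v = x @ wv + bv
    N, d = q.shape
    out = np.zeros_like(v)
    for i in range(N):
        scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(N)])
        out[i] = softmax_ref(scores) @ v
    return out


def mha_ref(x, w_qkv, b_qkv, w_out, b_out, heads):
    """Explicit per-head multi-head attention; x (N, k)."""
    N, k = x.shape
    dh = k // heads
    qkv = x @ w_qkv + b_qkv          # (N, 3k) laid out as [q | k | v]
    q_all, k_all, v_all = qkv[:, :k], qkv[:, k:2 * k], qkv[:, 2 * k:]
    pieces = []
    for h in range(heads):
        q = q_all[:, h * dh:(h + 1) * dh]
        kk = k_all[:, h * dh:(h + 1) * dh]
        v = v_all[:, h * dh:(h + 1) * dh]
        out = np.zeros((N, dh))
        for i in range(N):
            scores = np.array([q[i] @ kk[j] / np.sqrt(dh) for j in range(N)])
            out[i] = softmax_ref(scores) @ v
        pieces.append(out)
    return np.concatenate(pieces, axis=1) @ w_out + b_out


def gwo_step_ref(positions, leaders, tau, rng):
    """One grey-wolf position update, looping wolves/leaders/dimensions.

    Draw order per wolf and leader: r1 (all dims) then r2 (all dims),
    matching sample_coefficients.
    """
    n, ndim = positions.shape
    new = np.zeros_like(positions)
    for i in range(n):
        proposals = []
        for leader in leaders:
            r1 = rng.random(ndim)
            r2 = rng.random(ndim)
            c1 = 2.0 * tau * r1 - tau
            c2 = 2.0 * r2
            phi = np.abs(c2 * leader - positions[i])
            proposals.append(leader - c1 * phi)
        new[i] = np.clip(np.mean(proposals, axis=0), 0.0, 1.0)
    return new
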