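"""Image plane handling: validation, loading and saving.

All enhancement and network code in this package operates on channel-last
floating-point arrays with values in [0, 1] ("image planes"), either H x W
(single channel) or H x W x 3 (RGB).
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

IMAGE_EXTENSIONS = {".png", ".bmp", ".jpg", ".jpeg"}


def as_image(arr, name: str = "image") -> np.ndarray:
    """Validate and return `arr` as a float64 image plane in [0, 1]."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError(f"{name} must be HxW or HxWxC, got shape {img.shape}")
    if img.ndim == 3 and img.shape[2] not in (1, 3):
        raise ValueError(f"{name} must have 1 or 3 channels, got {img.shape[2]}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite pixels")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1], got range "
                         f"[{img.min():.4g}, {img.max():.4g}]")
    return img


def load_image(path: str | os.PathLike, size: int | None = None) -> np.ndarray:
    """Read a PNG/BMP/JPEG file into an RGB image plane in [0, 1]."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if size is not None and im.size != (size, size):
            im = im.resize((size, size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float64) / 255.0
    return arr


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    img = as_image(img)
    arr = np.round(img * 255.0).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    Image.fromarray(arr).save(path)
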