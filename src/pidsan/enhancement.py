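"""Four-stage contrast enhancement for low-contrast blood-smear microscopy.

The pipeline boosts faint structure in stained smear images before
classification:

1. hyperbolic-sine transform   f -> sinh(f) / sinh(1)
2. power law                   x -> rho * x**alpha, clipped to [0, 1]
3. dehazing                    (I - A) / t + A with a dark-channel-prior
                               estimate of the airlight A and transmission t
4. contrast stretching         (x - min) / (max - min)

Stages 1, 2 and 4 run per channel; dehazing shares one H x W transmission
map across channels with a per-channel airlight.  Every public function maps
[0, 1] into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter

from .image import as_image

SINH_1 = float(np.sinh(1.0))

__all__ = [
    "EnhanceParams", "sinh_transform", "power_law", "dark_channel",
    "estimate_airlight", "estimate_transmission", "dehaze",
    "contrast_stretch", "enhance",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Tunable constants of the enhancement pipeline.

    rho, alpha
        Brightness and contrast exponents of the power law.  The defaults
        (1.0, 0.9) mildly brighten mid-tones; both must be positive.
    haze_weight
        Fraction of the dark-channel estimate removed as haze, in (0, 1].
    window
        Odd patch size of the dark-channel minimum filter.
    t_floor
        Lower clamp on the transmission map, in (0, 1); prevents division
        blow-up in nearly opaque regions.
    airlight_top_frac
        Fraction of the brightest dark-channel pixels averaged into the
        airlight colour.
    """

    rho: float = 1.0
    alpha: float = 0.9
    haze_weight: float = 0.95
    window: int = 15
    t_floor: float = 0.1
    airlight_top_frac: float = 0.001

    def __post_init__(self):
        if self.rho <= 0 or self.alpha <= 0:
            raise ValueError(f"rho and alpha must be positive, got rho={self.rho}, alpha={self.alpha}")
        if not 0.0 < self.haze_weight <= 1.0:
            raise ValueError(f"haze_weight must be in (0, 1], got {self.haze_weight}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd positive integer, got {self.window}")
        if not 0.0 < self.t_floor < 1.0:
            raise ValueError(f"t_floor must be in (0, 1), got {self.t_floor}")
        if not 0.0 < self.airlight_top_frac <= 1.0:
            raise ValueError(f"airlight_top_frac must be in (0, 1], got {self.airlight_top_frac}")


def sinh_transform(img: np.ndarray) -> np.ndarray:
    """Elementwise (e^f - e^-f)/2, rescaled by 1/sinh(1) to stay in [0, 1].

    Strictly increasing, so the rank order of distinct pixel values is
    preserved while low intensities are compressed less than a plain
    exponential would.
    """
    img = as_image(img)
    return np.sinh(img) / SINH_1


def power_law(img: np.ndarray, rho: float = 1.0, alpha: float = 0.9) -> np.ndarray:
    """rho * x**alpha, clipped to [0, 1]; rho scales brightness, alpha contrast."""
    if rho <= 0 or alpha <= 0:
        raise ValueError(f"rho and alpha must be positive, got rho={rho}, alpha={alpha}")
    img = as_image(img)
    return np.clip(rho * np.power(img, alpha), 0.0, 1.0)


def dark_channel(img: np.ndarray, window: int) -> np.ndarray:
    """Windowed minimum over channels and a `window` x `window` neighbourhood."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    img = np.asarray(img, dtype=np.float64)
    per_pixel_min = img.min(axis=2) if img.ndim == 3 else img
    return minimum_filter(per_pixel_min, size=window, mode="nearest")


def estimate_airlight(img: np.ndarray, params: EnhanceParams) -> np.ndarray:
    """Airlight colour: mean of the image over the brightest dark-channel pixels."""
    img = as_image(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"airlight estimation needs a 3-channel image, got shape {img.shape}")
    dc = dark_channel(img, params.window)
    n = max(1, int(round(params.airlight_top_frac * dc.size)))
    flat = dc.ravel()
    top = np.argsort(flat, kind="stable")[-n:]
    pixels = img.reshape(-1, 3)[top]
    return pixels.mean(axis=0)


def estimate_transmission(img: np.ndarray, airlight: np.ndarray,
                          params: EnhanceParams) -> np.ndarray:
    """t = 1 - haze_weight * darkchannel(I / A), clamped to [t_floor, 1]."""
    img = as_image(img)
    airlight = np.asarray(airlight, dtype=np.float64)
    if np.any(airlight <= 0):
        raise ValueError(f"airlight components must be positive, got {airlight}")
    normalised = img / airlight if img.ndim == 3 else img / float(airlight.ravel()[0])
    t = 1.0 - params.haze_weight * dark_channel(normalised, params.window)
    return np.clip(t, params.t_floor, 1.0)


def dehaze(img: np.ndarray, airlight: np.ndarray, t: np.ndarray,
           t_floor: float = 0.1) -> np.ndarray:
    """Per pixel (I - A) / t + A, clipped to [0, 1]."""
    img = as_image(img)
    t = np.asarray(t, dtype=np.float64)
    if t.shape != img.shape[:2]:
        raise ValueError(f"transmission map shape {t.shape} does not match image {img.shape[:2]}")
    if t_floor <= 0 or np.any(t < t_floor - 1e-12):
        raise ValueError("transmission values must be >= t_floor > 0")
    airlight = np.asarray(airlight, dtype=np.float64)
    if img.ndim == 3:
        out = (img - airlight) / t[:, :, None] + airlight
    else:
        a = float(airlight.ravel()[0])
        out = (img - a) / t + a
    return np.clip(out, 0.0, 1.0)


def contrast_stretch(img: np.ndarray) -> np.ndarray:
    """Remap to full dynamic range; a constant image maps to all zeros."""
    img = as_image(img)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def enhance(img: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Full pipeline: sinh -> power law -> dehaze -> contrast stretch.

    Output is in [0, 1] and, for non-constant input, spans exactly [0, 1].
    Single-channel images skip the (colour-based) dehazing stage.
    """
    params = params or EnhanceParams()
    x = sinh_transform(img)
    x = power_law(x, params.rho, params.alpha)
    if x.ndim == 3 and x.shape[2] == 3:
        airlight = estimate_airlight(x, params)
        if np.all(airlight > 0):
            t = estimate_transmission(x, airlight, params)
            x = dehaze(x, airlight, t, params.t_floor)
    return contrast_stretch(x)
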