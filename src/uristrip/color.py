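"""RGB / HSV conversion and hue arithmetic.

Images are ``float64`` arrays of shape ``(height, width, 3)``. RGB channels
live on ``[0, 1]``. HSV images store hue in **degrees** on ``[0, 360)``
(channel 0), saturation and value on ``[0, 1]`` (channels 1, 2). Achromatic
pixels (saturation 0) carry hue 0 by convention.

The protein reagent's color runs from yellow through blue-green, well away
from the red 0/360 wrap, so hues are averaged arithmetically; a guard
rejects samples near the wrap where that would be wrong.
"""
from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

from .errors import HueWrapError

#: sampled hues closer than this to the 0/360 wrap abort the arithmetic mean
HUE_WRAP_MARGIN_DEG = 20.0


def _as_image(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {a.shape}")
    return a


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to HSV with hue in degrees.

    Standard hexcone model; saturation-0 pixels get hue 0.
    """
    rgb = _as_image(image)
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        raise ValueError("RGB intensities must lie in [0, 1]")
    hsv = _skcolor.rgb2hsv(np.clip(rgb, 0.0, 1.0))
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def hsv_to_rgb(image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv` (hue in degrees)."""
    hsv = _as_image(image).copy()
    hsv[..., 0] = (hsv[..., 0] % 360.0) / 360.0
    return _skcolor.hsv2rgb(hsv)


def hsv_triple_to_rgb(hue_deg: float, saturation: float, value: float) -> np.ndarray:
    """One HSV color to an RGB triple."""
    return hsv_to_rgb(np.array([[[hue_deg, saturation, value]]], dtype=float))[0, 0]


def mean_hue(hues_deg: np.ndarray, wrap_margin: float = HUE_WRAP_MARGIN_DEG) -> float:
    """Arithmetic mean of hue samples, guarding the circular wrap.

    Raises
    ------
    HueWrapError
        If any sample lies within ``wrap_margin`` degrees of 0/360, where
        an arithmetic mean of angles is unreliable.
    """
    h = np.asarray(hues_deg, dtype=float)
    if h.size == 0:
        raise ValueError("mean_hue of empty sample")
    if np.any((h < wrap_margin) | (h > 360.0 - wrap_margin)):
        raise HueWrapError(
            f"sampled hues within {wrap_margin} deg of the 0/360 wrap; "
            "arithmetic hue averaging is not valid there"
        )
    return float(h.mean())
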