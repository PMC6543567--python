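"""Camera calibration against a white reference.

The reader corrects the ambient illumination's color cast with a diagonal
white-balance model: per-channel gains estimated from an image of a white
sheet of paper, chosen so the corrected sheet has equal channel means. A
calibration is then verified by imaging an unused test strip and checking
that the measured pad hue falls within a tolerance of the known reference
hue of the dry reagent.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .color import rgb_to_hsv
from .errors import SpecificationError, UnusableReferenceError

#: channel means at or below this are considered too dark to calibrate on
_MIN_CHANNEL_MEAN = 0.05


@dataclass(frozen=True)
class CameraCalibration:
    """White-balance gains plus the reference check parameters.

    Parameters
    ----------
    gains
        Per-channel (R, G, B) multiplicative gains, all positive.
    reference_hue_deg
        Expected hue of the unused strip's protein pad.
    tolerance_deg
        Maximum |measured - reference| hue difference (inclusive) for the
        calibration check to pass.
    verified
        Whether :func:`verify_calibration` has passed for this profile.
    """

    gains: tuple[float, float, float]
    reference_hue_deg: float
    tolerance_deg: float = 5.0
    verified: bool = False

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in self.gains)
        if len(g) != 3 or any(v <= 0 for v in g):
            raise SpecificationError(f"gains must be 3 positive reals, got {self.gains}")
        if self.tolerance_deg <= 0:
            raise SpecificationError("tolerance_deg must be positive")
        object.__setattr__(self, "gains", g)

    def as_verified(self) -> "CameraCalibration":
        return replace(self, verified=True)


def estimate_white_balance(white_image: np.ndarray) -> tuple[float, float, float]:
    """Diagonal gains from a white-sheet image.

    The gain for channel c is (grand mean of the three channel means) /
    (channel-c mean), so applying the gains equalizes the channel means.

    Raises
    ------
    UnusableReferenceError
        If any channel mean is <= 0.05 (reference too dark).
    """
    img = np.asarray(white_image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3 or img[..., 0].size == 0:
        raise SpecificationError(f"expected a nonempty (H, W, 3) image, got {img.shape}")
    means = img.reshape(-1, 3).mean(axis=0)
    if np.any(means <= _MIN_CHANNEL_MEAN):
        raise UnusableReferenceError(
            f"white reference too dark (channel means {means.round(3).tolist()})"
        )
    grand = means.mean()
    return tuple(float(grand / m) for m in means)


def apply_calibration(image: np.ndarray, calibration: CameraCalibration) -> np.ndarray:
    """Channel-wise multiplication by the gains, clipped to [0, 1]."""
    img = np.asarray(image, dtype=float)
    return np.clip(img * np.asarray(calibration.gains), 0.0, 1.0)


def verify_calibration(strip_image, calibration, config) -> bool:
    """Check a calibration by reading an unused strip's protein pad.

    The strip image is calibrated, the pad is detected over the whole
    frame, and the mean hue of the pad's center region is compared to the
    calibration's reference hue. Passes iff the absolute difference is
    within the tolerance (inclusive).

    Raises
    ------
    PadNotFoundError
        If no pad contour is detected in the image.
    """
    from .reader import detect_pad  # deferred: reader imports this module

    calibrated = apply_calibration(strip_image, calibration)
    hsv = rgb_to_hsv(calibrated)
    pad = detect_pad(hsv, config)
    measured = float(hsv[pad.center.slices][..., 0].mean())
    return abs(measured - calibration.reference_hue_deg) <= calibration.tolerance_deg
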