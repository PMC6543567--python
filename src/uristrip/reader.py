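"""Colorimetric analysis of the protein pad.

The measurement pipeline mirrors a phone-camera strip reader: every video
frame is white-balanced, cropped to the on-screen guide region, converted
to HSV, and the protein pad is located on the saturation plane with a
Laplacian edge detector (the pad is far more saturated than the white
strip body, so its border is the dominant saturation transition). Sixty-
four random pixels are sampled near the pad center of each frame and their
hues averaged; the per-frame means of 30 frames are averaged again, giving
an approximately normal estimate of the pad's mean hue, which is binned to
a protein level.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .calibration import CameraCalibration, apply_calibration
from .color import mean_hue, rgb_to_hsv
from .errors import (
    InsufficientFramesError,
    PadNotFoundError,
    RoiBoundsError,
    SamplingError,
    SpecificationError,
)
from .geometry import Rect
from .scale import BinEdges, ProteinCategory, ProteinLevel, bin_hue

#: guide rectangle the user aligns the strip to; plain pixel rect
RegionOfInterest = Rect


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the image pipeline.

    Defaults follow the reading procedure: 30 video frames, 64 sampled
    pixels per frame, a width-5 Laplacian on the saturation channel with a
    3x3 median pre-filter, edges thresholded at 20% of the peak response.
    """

    n_frames: int = 30
    n_samples: int = 64
    laplacian_width: int = 5
    median_width: int = 3
    edge_threshold: float = 0.2
    min_pad_area: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_samples < 1:
            raise SpecificationError("n_frames and n_samples must be >= 1")
        for w in (self.laplacian_width, self.median_width):
            if w < 1 or w % 2 == 0:
                raise SpecificationError(f"kernel widths must be odd positive, got {w}")
        if not (0 < self.edge_threshold <= 1):
            raise SpecificationError("edge_threshold must be in (0, 1]")
        if self.min_pad_area < 1:
            raise SpecificationError("min_pad_area must be >= 1")


@dataclass(frozen=True)
class PadDetection:
    """Detected pad: bounding box, member-pixel mask (in ROI coordinates),
    and the center region used for sampling (inner half of the box)."""

    bbox: Rect
    mask: np.ndarray = field(repr=False, compare=False)
    center: Rect


@dataclass(frozen=True)
class HueEstimate:
    """Per-frame sampled mean hues and their grand mean (degrees)."""

    per_frame_means_deg: tuple[float, ...]
    grand_mean_deg: float
    n_frames: int
    n_samples: int


@dataclass(frozen=True)
class StripReadResult:
    """Full audit record of one strip read."""

    hue: HueEstimate
    level: ProteinLevel
    category: ProteinCategory
    calibration_passed: bool
    timestamp: _dt.datetime = field(
        compare=False, default_factory=lambda: _dt.datetime.now(_dt.timezone.utc)
    )


def extract_roi(frame: np.ndarray, guide: Rect) -> np.ndarray:
    """Exact pixel crop of the guide rectangle.

    Raises
    ------
    RoiBoundsError
        If the guide overhangs the frame.
    """
    img = np.asarray(frame)
    h, w = img.shape[:2]
    if not Rect(0, 0, w, h).contains(guide):
        raise RoiBoundsError(f"guide {guide} outside {w}x{h} frame")
    return img[guide.slices].copy()


def _laplacian_kernel(width: int) -> np.ndarray:
    # discrete Laplacian of the given width: -1 everywhere, center balances
    # the sum to zero, so uniform regions give exactly zero response
    k = -np.ones((width, width), dtype=float)
    k[width // 2, width // 2] = width * width - 1
    return k


def detect_pad(roi_hsv: np.ndarray, config: AnalysisConfig) -> PadDetection:
    """Locate the protein pad in an HSV region of interest.

    The saturation channel is median-filtered (noise reduction), convolved
    with the Laplacian, and |response| is thresholded at the configured
    fraction of its maximum. The thresholded edge map is morphologically
    closed; connected components below the minimum pad area are discarded
    and the component whose centroid is nearest the ROI center is returned.

    Raises
    ------
    PadNotFoundError
        If no component survives (uniform ROI, or all components too small).
    """
    sat = np.asarray(roi_hsv, dtype=float)[..., 1]
    if sat.size < config.min_pad_area:
        raise SpecificationError("ROI smaller than the minimum pad area")
    smoothed = ndimage.median_filter(sat, size=config.median_width)
    response = ndimage.convolve(
        smoothed, _laplacian_kernel(config.laplacian_width), mode="nearest"
    )
    magnitude = np.abs(response)
    peak = magnitude.max()
    if peak <= 1e-9:
        raise PadNotFoundError("no saturation edges in ROI (uniform image?)")
    edge_map = magnitude >= config.edge_threshold * peak
    closed = ndimage.binary_closing(edge_map, structure=np.ones((3, 3), dtype=bool))
    labels = _cc_label(closed, connectivity=2)
    regions = [r for r in regionprops(labels) if r.area >= config.min_pad_area]
    if not regions:
        raise PadNotFoundError(
            f"no edge component with area >= {config.min_pad_area} px"
        )
    rows, cols = sat.shape
    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    # tie-break on distance, then label order, keeps the result deterministic
    best = min(
        regions,
        key=lambda r: ((r.centroid[0] - cy0) ** 2 + (r.centroid[1] - cx0) ** 2, r.label),
    )
    min_row, min_col, max_row, max_col = best.bbox
    bbox = Rect(int(min_col), int(min_row), int(max_col - min_col), int(max_row - min_row))
    return PadDetection(bbox=bbox, mask=labels == best.label, center=bbox.inner_half())


def sample_center_hues(
    roi_hsv: np.ndarray,
    pad: PadDetection,
    n_samples: int,
    seed,
) -> float:
    """Mean hue of ``n_samples`` random pixels in the pad's center region.

    Locations are drawn uniformly *without replacement*, so the same seed
    always yields the same sample set and mean.

    Raises
    ------
    SamplingError
        If the center region holds fewer than ``n_samples`` pixels.
    HueWrapError
        If any sampled hue lies near the 0/360 wrap.
    """
    hues = np.asarray(roi_hsv, dtype=float)[pad.center.slices][..., 0].ravel()
    if hues.size < n_samples:
        raise SamplingError(
            f"center region has {hues.size} px, need {n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(hues.size, size=n_samples, replace=False)
    return mean_hue(hues[idx])


def _frame_seeds(seed: int, n: int) -> np.ndarray:
    # deterministic per-frame seed chain
    return np.random.SeedSequence(seed).generate_state(n)


def estimate_hue(
    frames: Sequence[np.ndarray],
    guide: Rect,
    calibration: CameraCalibration,
    config: AnalysisConfig,
) -> HueEstimate:
    """Mean pad hue over the first ``config.n_frames`` frames.

    Each frame passes through white-balance -> guide crop -> HSV -> pad
    detection -> center sampling; the grand mean is the arithmetic mean of
    the per-frame sampled means.

    Raises
    ------
    InsufficientFramesError
        If fewer than ``config.n_frames`` frames are supplied.
    PadNotFoundError
        Naming the offending frame, if detection fails anywhere.
    """
    if len(frames) < config.n_frames:
        raise InsufficientFramesError(
            f"need {config.n_frames} frames, got {len(frames)}"
        )
    seeds = _frame_seeds(config.seed, config.n_frames)
    means: list[float] = []
    for i in range(config.n_frames):
        calibrated = apply_calibration(frames[i], calibration)
        roi = extract_roi(calibrated, guide)
        hsv = rgb_to_hsv(roi)
        try:
            pad = detect_pad(hsv, config)
        except PadNotFoundError as exc:
            raise PadNotFoundError(f"frame {i}: {exc}") from exc
        means.append(sample_center_hues(hsv, pad, config.n_samples, seeds[i]))
    return HueEstimate(
        per_frame_means_deg=tuple(means),
        grand_mean_deg=float(np.mean(means)),
        n_frames=config.n_frames,
        n_samples=config.n_samples,
    )


def read_strip(
    frames: Sequence[np.ndarray],
    guide: Rect,
    calibration: CameraCalibration,
    edges: BinEdges,
    config: AnalysisConfig,
    *,
    calibration_passed: bool | None = None,
) -> StripReadResult:
    """Full strip read: hue estimation followed by binning.

    ``calibration_passed`` records the outcome of the earlier calibration
    check; it defaults to the calibration profile's ``verified`` flag.
    """
    est = estimate_hue(frames, guide, calibration, config)
    level, category = bin_hue(est.grand_mean_deg, edges)
    passed = calibration.verified if calibration_passed is None else calibration_passed
    return StripReadResult(
        hue=est, level=level, category=category, calibration_passed=bool(passed)
    )
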