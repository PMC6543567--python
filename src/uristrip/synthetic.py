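"""Synthetic strip imagery and log fixtures with known ground truth.

Stands in for a phone camera: renders a multi-pad test strip at known HSV
pad colors, applies a global illumination color cast (per-channel gains)
and i.i.d. Gaussian pixel noise, and reports the exact painted pad
rectangle and pre-noise hue as ground truth. Also fabricates titration
tables and dated urine-protein logs for the calibration and alerting
stages.

The noise model is deliberately minimal — additive Gaussian in RGB after
the cast, clipped to [0, 1] — which is what the 30-frame averaging step
assumes. No lens distortion, perspective, or shading is simulated.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .color import hsv_triple_to_rgb
from .errors import SpecificationError
from .geometry import Rect
from .monitoring import UrineLog, UrineLogEntry
from .scale import ProteinCategory, ProteinLevel

#: fixture hue scale (degrees) for negative, trace, 1+, 2+, 3+ — the
#: yellow -> blue-green direction of the protein reagent's color change
DEFAULT_LEVEL_HUES = (60.0, 75.0, 95.0, 125.0, 160.0)


@dataclass(frozen=True)
class PadSpec:
    """One reagent pad: its rectangle and target HSV color."""

    rect: Rect
    hue_deg: float
    saturation: float
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_deg < 360.0):
            raise SpecificationError(f"pad hue must be in [0, 360), got {self.hue_deg}")
        if not (0.0 <= self.saturation <= 1.0 and 0.0 <= self.value <= 1.0):
            raise SpecificationError("pad saturation/value must be in [0, 1]")


@dataclass(frozen=True)
class StripRenderSpec:
    """Everything needed to render a strip frame.

    ``illumination_gains`` are per-channel multiplicative factors applied
    after painting (the color cast); ``noise_sd`` is the per-channel
    Gaussian noise sd on the [0, 1] intensity scale.
    """

    width: int
    height: int
    strip: Rect
    pads: tuple[PadSpec, ...]
    protein_pad: int
    background_rgb: tuple[float, float, float] = (0.25, 0.25, 0.25)
    strip_rgb: tuple[float, float, float] = (0.95, 0.95, 0.95)
    illumination_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    protein_level: ProteinLevel | None = None

    def __post_init__(self) -> None:
        frame = Rect(0, 0, self.width, self.height)
        if not frame.contains(self.strip):
            raise SpecificationError("strip rectangle must lie inside the frame")
        if not self.pads:
            raise SpecificationError("at least one pad is required")
        for pad in self.pads:
            if not self.strip.contains(pad.rect):
                raise SpecificationError(f"pad {pad.rect} outside strip {self.strip}")
        for a in range(len(self.pads)):
            for b in range(a + 1, len(self.pads)):
                if self.pads[a].rect.overlaps(self.pads[b].rect):
                    raise SpecificationError("pad rectangles must not overlap")
        if not (0 <= self.protein_pad < len(self.pads)):
            raise SpecificationError("protein_pad index out of range")
        if any(g <= 0 for g in self.illumination_gains):
            raise SpecificationError("illumination gains must be positive")
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be >= 0")

    @property
    def protein(self) -> PadSpec:
        return self.pads[self.protein_pad]

    def with_hue(self, hue_deg: float) -> "StripRenderSpec":
        pads = list(self.pads)
        pads[self.protein_pad] = replace(pads[self.protein_pad], hue_deg=hue_deg)
        return replace(self, pads=tuple(pads))


@dataclass(frozen=True)
class GroundTruth:
    """What the renderer painted: exact pad box, pre-noise hue, level."""

    pad_bbox: Rect
    hue_deg: float
    level: ProteinLevel | None = None


def render_strip_frame(spec: StripRenderSpec, seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Render one camera frame plus its ground truth.

    Pads are painted at their HSV colors (converted to RGB), the whole
    frame is multiplied by the illumination gains and clipped, then
    independent zero-mean Gaussian noise is added per pixel per channel
    and clipped again. Ground truth reports the pre-noise hue and the
    exact painted rectangle.
    """
    img = np.empty((spec.height, spec.width, 3), dtype=float)
    img[...] = np.asarray(spec.background_rgb, dtype=float)
    img[spec.strip.slices] = np.asarray(spec.strip_rgb, dtype=float)
    for pad in spec.pads:
        img[pad.rect.slices] = hsv_triple_to_rgb(pad.hue_deg, pad.saturation, pad.value)
    img = np.clip(img * np.asarray(spec.illumination_gains, dtype=float), 0.0, 1.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, size=img.shape), 0.0, 1.0)
    truth = GroundTruth(
        pad_bbox=spec.protein.rect, hue_deg=spec.protein.hue_deg, level=spec.protein_level
    )
    return img, truth


def render_sequence(spec: StripRenderSpec, n_frames: int, seed: int) -> list[np.ndarray]:
    """Render a short video: shared geometry/colors, independent noise.

    Per-frame noise seeds are derived deterministically from ``seed``, so
    the whole sequence is a pure function of (spec, n_frames, seed).
    """
    if n_frames < 1:
        raise SpecificationError(f"n_frames must be >= 1, got {n_frames}")
    seeds = np.random.SeedSequence(seed).generate_state(n_frames)
    return [render_strip_frame(spec, int(s))[0] for s in seeds]


def render_white_sheet(
    gains: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (240, 320),
) -> np.ndarray:
    """White (1, 1, 1) sheet under the given cast, with camera noise."""
    g = np.asarray(gains, dtype=float)
    if g.shape != (3,) or np.any(g <= 0):
        raise SpecificationError(f"gains must be 3 positive reals, got {gains}")
    if noise_sd < 0:
        raise SpecificationError("noise_sd must be >= 0")
    img = np.clip(np.ones(shape + (3,), dtype=float) * g, 0.0, 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape), 0.0, 1.0)
    return img


def make_titration_set(
    level_hues: Sequence[float],
    reps: int,
    noise_sd_deg: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated titration table: ``reps`` noisy hue draws per level.

    ``level_hues`` gives the true mean hue of each of the five levels and
    must be strictly increasing.
    """
    hues = np.asarray(level_hues, dtype=float)
    if hues.shape != (5,):
        raise SpecificationError("level_hues must give one hue per protein level (5)")
    if not np.all(np.diff(hues) > 0):
        raise SpecificationError(f"level hues must be strictly increasing: {hues.tolist()}")
    if reps < 1:
        raise SpecificationError("reps must be >= 1")
    if noise_sd_deg < 0:
        raise SpecificationError("noise_sd_deg must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for level, mu in zip(ProteinLevel, hues):
        draws = mu + rng.normal(0.0, noise_sd_deg, size=reps)
        rows.extend({"level": level.label, "hue_deg": float(h)} for h in draws)
    return pd.DataFrame(rows, columns=["level", "hue_deg"])


_PATTERN_CHARS = {
    "L": ProteinCategory.LOW,
    "M": ProteinCategory.MEDIUM,
    "H": ProteinCategory.HIGH,
}


def make_urine_log(pattern: str, start_date: _dt.date) -> UrineLog:
    """Build a daily log from a compact pattern string.

    ``pattern`` is one character per consecutive calendar day starting at
    ``start_date``: ``L``/``M``/``H`` for a reading of that category,
    ``·`` (or ``.``) for a day with no reading.
    """
    if not pattern:
        raise SpecificationError("pattern must be nonempty")
    entries = []
    for offset, ch in enumerate(pattern):
        if ch in ("·", "."):
            continue
        if ch not in _PATTERN_CHARS:
            raise SpecificationError(f"illegal pattern character {ch!r}")
        entries.append(
            UrineLogEntry(
                date=start_date + _dt.timedelta(days=offset),
                time=None,
                category=_PATTERN_CHARS[ch],
                source="manual",
            )
        )
    return UrineLog.from_entries(entries)


def default_strip_spec(
    pad_hue_deg: float = 125.0,
    *,
    noise_sd: float = 0.0,
    gains: tuple[float, float, float] = (1.0, 1.0, 1.0),
    compact: bool = False,
    level: ProteinLevel | None = None,
) -> StripRenderSpec:
    """Standard two-pad fixture layout (distractor pad + protein pad).

    The full layout is a 640x480 frame with a vertical strip and 60x60
    pads; ``compact=True`` gives a 160x200 frame with 36x36 pads for
    cheap Monte Carlo runs. Pad value is kept at 0.70 so moderate casts
    (gains up to ~1.25 after normalization) never clip pad pixels.
    """
    if compact:
        width, height = 160, 200
        strip = Rect(60, 10, 44, 180)
        distractor = Rect(64, 20, 36, 36)
        protein = Rect(64, 110, 36, 36)
    else:
        width, height = 640, 480
        strip = Rect(285, 80, 70, 320)
        distractor = Rect(290, 110, 60, 60)
        protein = Rect(290, 250, 60, 60)
    return StripRenderSpec(
        width=width,
        height=height,
        strip=strip,
        pads=(
            PadSpec(distractor, hue_deg=30.0, saturation=0.5, value=0.7),
            PadSpec(protein, hue_deg=pad_hue_deg, saturation=0.6, value=0.7),
        ),
        protein_pad=1,
        illumination_gains=gains,
        noise_sd=noise_sd,
        protein_level=level,
    )


def spec_for_level(level: ProteinLevel, **kwargs) -> StripRenderSpec:
    """Fixture spec whose protein-pad hue sits at the level's true hue."""
    level = ProteinLevel(level)
    return default_strip_spec(DEFAULT_LEVEL_HUES[level], level=level, **kwargs)


def protein_pad_guide(spec: StripRenderSpec, margin: int = 30) -> Rect:
    """Guide rectangle centered on the protein pad, clipped to the frame."""
    r = spec.protein.rect.expanded(margin)
    x0, y0 = max(r.x, 0), max(r.y, 0)
    x1, y1 = min(r.x1, spec.width), min(r.y1, spec.height)
    return Rect(x0, y0, x1 - x0, y1 - y0)
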