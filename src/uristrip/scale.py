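"""The semi-quantitative protein scale and hue binning.

A dipstick protein pad is read on a five-level ordinal scale
(negative, trace, 1+, 2+, 3+). The reader reports a coarser three-level
category to users: negative/trace -> LOW, 1+ -> MEDIUM, 2+/3+ -> HIGH.
A measured mean hue is converted to a level by binning against four
monotone hue boundaries placed by titration calibration.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, SpecificationError


class ProteinLevel(enum.IntEnum):
    """Five-level dipstick read-out, ordered by increasing protein."""

    NEGATIVE = 0
    TRACE = 1
    PLUS_1 = 2
    PLUS_2 = 3
    PLUS_3 = 4

    @property
    def label(self) -> str:
        return _LEVEL_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "ProteinLevel":
        try:
            return _LABEL_TO_LEVEL[str(label).strip().lower()]
        except KeyError:
            raise SpecificationError(f"unknown protein level {label!r}") from None


_LEVEL_LABELS = {
    ProteinLevel.NEGATIVE: "negative",
    ProteinLevel.TRACE: "trace",
    ProteinLevel.PLUS_1: "1+",
    ProteinLevel.PLUS_2: "2+",
    ProteinLevel.PLUS_3: "3+",
}
_LABEL_TO_LEVEL = {v: k for k, v in _LEVEL_LABELS.items()}


class ProteinCategory(enum.IntEnum):
    """Three-level user-facing category, ordered by severity."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "ProteinCategory":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise SpecificationError(f"unknown protein category {label!r}") from None


#: fixed surjection from the 5-level scale onto the 3-level category
LEVEL_TO_CATEGORY = {
    ProteinLevel.NEGATIVE: ProteinCategory.LOW,
    ProteinLevel.TRACE: ProteinCategory.LOW,
    ProteinLevel.PLUS_1: ProteinCategory.MEDIUM,
    ProteinLevel.PLUS_2: ProteinCategory.HIGH,
    ProteinLevel.PLUS_3: ProteinCategory.HIGH,
}


def level_to_category(level: ProteinLevel) -> ProteinCategory:
    return LEVEL_TO_CATEGORY[ProteinLevel(level)]


@dataclass(frozen=True)
class BinEdges:
    """Four strictly increasing hue thresholds (degrees) delimiting
    negative | trace | 1+ | 2+ | 3+."""

    edges_deg: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        e = tuple(float(v) for v in self.edges_deg)
        if len(e) != 4:
            raise SpecificationError(f"expected 4 bin edges, got {len(e)}")
        if not all(a < b for a, b in zip(e, e[1:])):
            raise SpecificationError(f"bin edges must be strictly increasing: {e}")
        object.__setattr__(self, "edges_deg", e)


def bin_hue(hue_deg: float, edges: BinEdges) -> tuple[ProteinLevel, ProteinCategory]:
    """Bin a mean hue into a protein level and its category.

    Bins are half-open with boundary hues assigned to the upper region:
    hue < e1 -> negative, [e1, e2) -> trace, [e2, e3) -> 1+,
    [e3, e4) -> 2+, >= e4 -> 3+.
    """
    idx = int(np.searchsorted(edges.edges_deg, float(hue_deg), side="right"))
    level = ProteinLevel(idx)
    return level, level_to_category(level)


def fit_bin_edges(titration: pd.DataFrame) -> BinEdges:
    """Place bin edges from a titration table of (level, hue) measurements.

    Each edge is the midpoint of the mean hues of the two adjacent levels.

    Parameters
    ----------
    titration
        DataFrame with columns ``level`` (labels ``negative``, ``trace``,
        ``1+``, ``2+``, ``3+`` or :class:`ProteinLevel`) and ``hue_deg``.

    Raises
    ------
    CalibrationError
        If any level is unmeasured or the level mean hues are not strictly
        increasing.
    """
    if not {"level", "hue_deg"}.issubset(titration.columns):
        raise SpecificationError("titration table needs columns 'level' and 'hue_deg'")
    levels = titration["level"].map(
        lambda v: v if isinstance(v, ProteinLevel) else ProteinLevel.from_label(v)
    )
    means = titration.assign(level=levels).groupby("level")["hue_deg"].mean()
    missing = [lv.label for lv in ProteinLevel if lv not in means.index]
    if missing:
        raise CalibrationError(f"titration is missing level(s): {missing}")
    ordered = means.loc[list(ProteinLevel)].to_numpy()
    if not np.all(np.diff(ordered) > 0):
        raise CalibrationError(
            f"level mean hues must be strictly increasing, got {ordered.round(2).tolist()}"
        )
    mids = (ordered[:-1] + ordered[1:]) / 2.0
    return BinEdges(tuple(mids))
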