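"""Urine-protein log and relapse/remission alerting.

Clinical rules: a relapse is signalled by urine protein >= 2+ (the HIGH
category) on 3 consecutive calendar days; remission by negative/trace
(LOW) on 3 consecutive days. A day with no reading breaks a run. Days
with several readings count as their most severe category — conservative
for relapse detection. Alerts are edge-triggered: an alert fires only on
the first day its condition becomes true.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import DuplicateEntryError, SpecificationError
from .scale import ProteinCategory

_SOURCES = ("camera", "manual")
RELAPSE_RUN_DAYS = 3
REMISSION_RUN_DAYS = 3


@dataclass(frozen=True)
class UrineLogEntry:
    """One dated reading; ``time`` is optional, ``source`` records whether
    the reading came from the camera pipeline or was entered by hand."""

    date: _dt.date
    time: _dt.time | None
    category: ProteinCategory
    source: str = "manual"

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date):
            raise SpecificationError(f"date must be a datetime.date, got {self.date!r}")
        if self.source not in _SOURCES:
            raise SpecificationError(f"source must be one of {_SOURCES}")
        object.__setattr__(self, "category", ProteinCategory(self.category))

    @property
    def sort_key(self):
        return (self.date, self.time or _dt.time.min)


class UrineLog:
    """Immutable, date-sorted collection of readings."""

    def __init__(self, entries: Iterable[UrineLogEntry] = ()):
        self._entries = tuple(sorted(entries, key=lambda e: e.sort_key))

    @classmethod
    def from_entries(cls, entries: Iterable[UrineLogEntry]) -> "UrineLog":
        return cls(entries)

    @property
    def entries(self) -> tuple[UrineLogEntry, ...]:
        return self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[UrineLogEntry]:
        return iter(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, UrineLog) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"UrineLog({len(self._entries)} entries)"

    @property
    def dates(self) -> tuple[_dt.date, ...]:
        return tuple(sorted({e.date for e in self._entries}))


def add_reading(log: UrineLog, entry: UrineLogEntry) -> UrineLog:
    """Insert a reading in date order; exact duplicates are rejected.

    A duplicate means the same date, time and category (the source does
    not disambiguate).
    """
    for existing in log:
        if (existing.date, existing.time, existing.category) == (
            entry.date,
            entry.time,
            entry.category,
        ):
            raise DuplicateEntryError(
                f"reading {entry.category.label} on {entry.date} already logged"
            )
    return UrineLog((*log.entries, entry))


def daily_category(log: UrineLog, date: _dt.date) -> ProteinCategory | None:
    """Most severe category recorded on the given day; None if no reading."""
    cats = [e.category for e in log if e.date == date]
    return max(cats) if cats else None


def _run_holds(
    log: UrineLog, as_of: _dt.date, category: ProteinCategory, run_days: int
) -> bool:
    return all(
        daily_category(log, as_of - _dt.timedelta(days=back)) == category
        for back in range(run_days)
    )


def detect_relapse(log: UrineLog, as_of: _dt.date) -> bool:
    """HIGH (>= 2+) on ``as_of`` and the two preceding calendar days."""
    return _run_holds(log, as_of, ProteinCategory.HIGH, RELAPSE_RUN_DAYS)


def detect_remission(log: UrineLog, as_of: _dt.date) -> bool:
    """LOW (negative/trace) on ``as_of`` and the two preceding days."""
    return _run_holds(log, as_of, ProteinCategory.LOW, REMISSION_RUN_DAYS)


@dataclass(frozen=True)
class AlertState:
    """Alert flags for one evaluation date.

    ``streak_days`` is the length of the consecutive-day run of the
    current daily category ending on ``as_of`` (0 if no reading that day).
    """

    as_of: _dt.date
    relapse_alert: bool
    remission_alert: bool
    streak_days: int

    def __post_init__(self) -> None:
        if self.relapse_alert and self.remission_alert:
            raise SpecificationError("relapse and remission cannot both alert")


def _streak_days(log: UrineLog, as_of: _dt.date) -> int:
    today = daily_category(log, as_of)
    if today is None:
        return 0
    run = 0
    while daily_category(log, as_of - _dt.timedelta(days=run)) == today:
        run += 1
    return run


def evaluate_alerts(log: UrineLog, as_of: _dt.date) -> AlertState:
    """Edge-triggered alert evaluation for one date.

    An alert fires on ``as_of`` only if its 3-consecutive-day condition
    holds on ``as_of`` and did *not* hold on the previous day, so each
    state entry produces exactly one alert.
    """
    prev = as_of - _dt.timedelta(days=1)
    relapse = detect_relapse(log, as_of) and not detect_relapse(log, prev)
    remission = detect_remission(log, as_of) and not detect_remission(log, prev)
    return AlertState(
        as_of=as_of,
        relapse_alert=relapse,
        remission_alert=remission,
        streak_days=_streak_days(log, as_of),
    )


def alert_history(log: UrineLog) -> list[AlertState]:
    """Alert evaluation for every calendar day spanned by the log."""
    if not len(log):
        return []
    first, last = log.entries[0].date, log.entries[-1].date
    return [
        evaluate_alerts(log, first + _dt.timedelta(days=d))
        for d in range((last - first).days + 1)
    ]


# ---------------------------------------------------------------------------
# persistence and reporting

def log_to_frame(log: UrineLog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "date": e.date.isoformat(),
                "time": e.time.isoformat() if e.time else "",
                "category": e.category.label,
                "source": e.source,
            }
            for e in log
        ],
        columns=["date", "time", "category", "source"],
    )


def frame_to_log(frame: pd.DataFrame) -> UrineLog:
    entries = []
    for row in frame.itertuples(index=False):
        t = str(getattr(row, "time", "") or "")
        entries.append(
            UrineLogEntry(
                date=_dt.date.fromisoformat(str(row.date)),
                time=_dt.time.fromisoformat(t) if t else None,
                category=ProteinCategory.from_label(str(row.category)),
                source=str(getattr(row, "source", "manual") or "manual"),
            )
        )
    return UrineLog.from_entries(entries)


def save_log(log: UrineLog, path) -> None:
    log_to_frame(log).to_csv(path, index=False)


def load_log(path) -> UrineLog:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_log(frame)


def export_report(log: UrineLog, alerts: Sequence[AlertState], out_dir) -> dict:
    """Write a provider-ready report: entries CSV plus a JSON summary.

    Returns the summary dict. The CSV round-trips through
    :func:`load_log` to an identical log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries_path = out / "urine_log.csv"
    save_log(log, entries_path)
    counts = {cat.label: 0 for cat in ProteinCategory}
    for e in log:
        counts[e.category.label] += 1
    summary = {
        "n_entries": len(log),
        "category_counts": counts,
        "relapse_alert_dates": [a.as_of.isoformat() for a in alerts if a.relapse_alert],
        "remission_alert_dates": [
            a.as_of.isoformat() for a in alerts if a.remission_alert
        ],
        "entries_csv": entries_path.name,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
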