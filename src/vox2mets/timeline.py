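"""Minute-resolution daily MET timelines from parsed diary records.

The day is a 1440-minute grid.  Each resolved behavior record paints its
half-open minute interval ``[start, end)`` with the activity's MET
intensity; minutes with no record stay *uncovered*.  Daily summaries
follow the diary convention: METs·time is the per-minute sum of
intensity, and the average daily MET value is that total divided by the
covered (recorded) time — uncovered minutes are never imputed on the
diary side (imputation at 0.9 METs belongs to the accelerometer's
24-hour average only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional, Sequence

import numpy as np

from .compendium import CompendiumTable, MET_MAX, MET_MIN, assign_met
from .parser import AUTO, MANUAL, ParsedRecord

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

__all__ = [
    "DayTimeline",
    "TimelineError",
    "UndefinedAverageError",
    "resolve_overlaps",
    "build_timeline",
    "met_minutes",
    "average_mets",
    "recorded_hours",
]


class TimelineError(ValueError):
    """Raised when a timeline cannot be built."""


class UndefinedAverageError(TimelineError):
    """Average METs requested for a day with zero covered minutes."""


@dataclass
class DayTimeline:
    """Per-minute MET intensity and coverage for one participant-day.

    ``intensity[i]`` is meaningful exactly where ``covered[i]`` is true;
    uncovered minutes hold NaN.
    """

    participant: str
    date: Date
    intensity: np.ndarray = field(
        default_factory=lambda: np.full(MINUTES_PER_DAY, np.nan)
    )
    covered: np.ndarray = field(
        default_factory=lambda: np.zeros(MINUTES_PER_DAY, dtype=bool)
    )

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.intensity.shape != (MINUTES_PER_DAY,) or self.covered.shape != (
            MINUTES_PER_DAY,
        ):
            raise TimelineError("timeline arrays must have length 1440")
        set_vals = self.intensity[self.covered]
        if set_vals.size and (
            np.any(set_vals < MET_MIN) or np.any(set_vals > MET_MAX)
        ):
            raise TimelineError(
                f"covered intensities outside [{MET_MIN}, {MET_MAX}]"
            )


def resolve_overlaps(records: Sequence[ParsedRecord]) -> list[ParsedRecord]:
    """Make one day's records pairwise disjoint, last entry wins.

    Records must share one date and be auto or manual.  Where two records
    overlap, the later-inputted record keeps the overlapped minutes; the
    earlier one is truncated (and logged) or dropped when fully shadowed.
    Output is sorted by start minute.
    """
    records = list(records)
    if not records:
        return []
    dates = {r.date for r in records}
    if len(dates) > 1:
        raise TimelineError(f"records span multiple dates: {sorted(map(str, dates))}")
    for r in records:
        if r.parse_mode not in (AUTO, MANUAL):
            raise TimelineError(f"unresolved record {r.source_id!r} ({r.parse_mode})")

    # de-duplicate exact repeats, then paint minutes in input order
    seen: set[tuple] = set()
    ordered: list[ParsedRecord] = []
    for r in sorted(records, key=lambda r: (r.input_time is not None, r.input_time)):
        key = (r.activity, r.start, r.end, r.met)
        if key in seen:
            continue
        seen.add(key)
        ordered.append(r)

    owner = np.full(MINUTES_PER_DAY, -1, dtype=int)
    for idx, r in enumerate(ordered):
        owner[r.start : r.end] = idx

    resolved: list[ParsedRecord] = []
    for idx, r in enumerate(ordered):
        mine = np.flatnonzero(owner == idx)
        if mine.size == 0:
            logger.info("record %r [%d,%d) fully shadowed; dropped", r.activity, r.start, r.end)
            continue
        if mine.size < r.end - r.start:
            logger.info(
                "record %r [%d,%d) truncated by later entries", r.activity, r.start, r.end
            )
        # split surviving minutes into maximal runs
        breaks = np.flatnonzero(np.diff(mine) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [mine.size - 1]))
        for a, b in zip(starts, ends):
            resolved.append(
                ParsedRecord(
                    source_id=r.source_id,
                    date=r.date,
                    parse_mode=r.parse_mode,
                    activity=r.activity,
                    start=int(mine[a]),
                    end=int(mine[b]) + 1,
                    input_time=r.input_time,
                    met=r.met,
                )
            )
    resolved.sort(key=lambda r: r.start)
    return resolved


def build_timeline(
    records: Sequence[ParsedRecord],
    table: CompendiumTable,
    participant: str = "",
    date: Optional[Date] = None,
) -> DayTimeline:
    """Paint disjoint records onto a 1440-minute intensity grid.

    Each record's minutes ``[start, end)`` get its MET intensity from the
    compendium (or its explicit manual intensity).  A record whose
    activity is unmatched and carries no manual intensity aborts the
    build — it should have gone through manual review first.
    """
    records = list(records)
    if date is None:
        if not records:
            raise TimelineError("cannot infer date from an empty record list")
        date = records[0].date
    tl = DayTimeline(participant=participant, date=date)
    for r in records:
        met = assign_met(r, table)
        if met is None:
            raise TimelineError(
                f"activity {r.activity!r} not in compendium and no manual intensity"
            )
        if np.any(tl.covered[r.start : r.end]):
            raise TimelineError(
                f"records overlap at [{r.start},{r.end}); run resolve_overlaps first"
            )
        tl.intensity[r.start : r.end] = met
        tl.covered[r.start : r.end] = True
    return tl


def met_minutes(tl: DayTimeline) -> float:
    """Daily METs·time: sum of intensity × 1 min over covered minutes."""
    return float(np.nansum(tl.intensity[tl.covered]))


def average_mets(tl: DayTimeline) -> float:
    """Average daily METs: METs·time divided by covered minutes."""
    n = int(tl.covered.sum())
    if n == 0:
        raise UndefinedAverageError(
            f"{tl.participant}/{tl.date}: no covered minutes"
        )
    return met_minutes(tl) / n


def recorded_hours(tl: DayTimeline) -> float:
    """Hours of diary coverage (covered minutes / 60)."""
    return int(tl.covered.sum()) / 60.0
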