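"""Trigger-word parsing of speech-recognized diary utterances.

A voice diary entry is a short transcript string such as ``"study from
9:00 to 12:00"``.  Five trigger words — ``start``, ``end``, ``from``,
``to`` and ``do`` — anchor the grammar; utterances containing a
recognized pattern are *auto*-converted into a timed behavior record,
everything else becomes a *failed* record routed to manual review
(``"get up at 7:00"`` has no trigger word; ``"going home by riding a
bicycle"`` is a long object sentence; both fail by design).

Parsing is total: arbitrary text never raises, it yields a failed
record.  Clock times use the 24-hour clock and records never cross
midnight; an interval spanning midnight must be split upstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from datetime import date as Date, datetime
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

TRIGGER_WORDS = ("start", "end", "from", "to", "do")

AUTO = "auto"
MANUAL = "manual"
FAILED = "failed"

__all__ = [
    "TRIGGER_WORDS",
    "AUTO",
    "MANUAL",
    "FAILED",
    "Utterance",
    "ParsedRecord",
    "OpenSession",
    "ParserError",
    "TimeParseError",
    "OrderingError",
    "OrphanEndError",
    "normalize",
    "detect_triggers",
    "parse_time",
    "parse_utterance",
    "close_session",
    "manual_override",
    "conversion_rate",
    "TranscriptParser",
]


class ParserError(ValueError):
    """Base class for parsing errors."""


class TimeParseError(ParserError):
    """A token could not be read as a clock time."""


class OrderingError(ParserError):
    """Interval end does not come after its start."""


class OrphanEndError(ParserError):
    """A session end with no matching open session."""


@dataclass(frozen=True)
class Utterance:
    """One speech-recognized transcript string with its input timestamp."""

    id: str
    text: str
    input_time: datetime
    participant: Optional[str] = None

    @property
    def date(self) -> Date:
        return self.input_time.date()

    @property
    def minute_of_day(self) -> int:
        return self.input_time.hour * 60 + self.input_time.minute


@dataclass(frozen=True)
class ParsedRecord:
    """One behavioral interval extracted from an utterance.

    ``start``/``end`` are minutes of day with ``0 <= start < end <= 1440``
    (half-open at the minute level; records never cross midnight).
    ``parse_mode`` is ``auto``, ``manual`` or ``failed``; a failed record
    carries no activity or times.  ``met`` is an optional explicit
    intensity set during manual review, overriding the compendium.
    """

    source_id: str
    date: Date
    parse_mode: str
    activity: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    input_time: Optional[datetime] = None
    met: Optional[float] = None

    def __post_init__(self) -> None:
        if self.parse_mode not in (AUTO, MANUAL, FAILED):
            raise ValueError(f"bad parse_mode {self.parse_mode!r}")
        if self.parse_mode == FAILED:
            if self.activity is not None or self.start is not None or self.end is not None:
                raise ValueError("failed records carry no activity or times")
        else:
            if self.activity is None or self.start is None or self.end is None:
                raise ValueError(f"{self.parse_mode} record must have activity and times")
            if not (0 <= self.start < self.end <= 1440):
                raise OrderingError(
                    f"need 0 <= start < end <= 1440, got [{self.start}, {self.end})"
                )

    @property
    def duration(self) -> int:
        if self.start is None or self.end is None:
            return 0
        return self.end - self.start


@dataclass(frozen=True)
class OpenSession:
    """A pending "start <activity> now" awaiting its end utterance."""

    activity: str
    start: int
    date: Date
    source_id: str


_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2})$")
_OCLOCK_RE = re.compile(r"^(\d{1,2})$")
_KEEP = re.compile(r"[^a-z0-9:' ]")


def normalize(text: str) -> str:
    """Lower-case and strip punctuation to spaces, keeping ``:`` and ``'``."""
    return " ".join(_KEEP.sub(" ", text.lower()).split())


def detect_triggers(text: str) -> list[tuple[str, int]]:
    """All trigger-word occurrences as ``(word, token position)`` in order.

    The text must be non-empty after whitespace normalization.
    """
    norm = normalize(text)
    if not norm:
        raise ParserError("empty utterance text")
    return [(tok, i) for i, tok in enumerate(norm.split()) if tok in TRIGGER_WORDS]


def parse_time(token: str) -> int:
    """Minutes from local midnight for ``H:MM``, ``HH:MM`` or ``H o'clock``.

    24-hour clock; ``24:00`` is not a valid start-of-minute time.
    """
    token = normalize(token)
    m = _TIME_RE.match(token)
    if m is None:
        parts = token.split()
        if len(parts) == 2 and parts[1] == "o'clock" and _OCLOCK_RE.match(parts[0]):
            hour, minute = int(parts[0]), 0
        else:
            raise TimeParseError(f"unparseable time token {token!r}")
    else:
        hour, minute = int(m.group(1)), int(m.group(2))
    if not (0 <= hour <= 23 and 0 <= minute <= 59):
        raise TimeParseError(f"clock time out of range: {token!r}")
    return hour * 60 + minute


def _time_at(tokens: Sequence[str], i: int) -> Optional[int]:
    """Clock-time value of the token(s) at position i, else None."""
    tok = tokens[i]
    if _TIME_RE.match(tok):
        try:
            return parse_time(tok)
        except TimeParseError:
            return None
    if i + 1 < len(tokens) and tokens[i + 1] == "o'clock" and _OCLOCK_RE.match(tok):
        try:
            return parse_time(f"{tok} o'clock")
        except TimeParseError:
            return None
    return None


def _first_time(tokens: Sequence[str], lo: int, hi: int) -> tuple[Optional[int], int]:
    """First parseable clock time in tokens[lo:hi] and its position."""
    for i in range(lo, min(hi, len(tokens))):
        value = _time_at(tokens, i)
        if value is not None:
            return value, i
    return None, -1


def _activity_words(tokens: Sequence[str]) -> Optional[str]:
    """Join non-trigger, non-'at'/'now' tokens into an activity phrase."""
    words = [t for t in tokens if t not in TRIGGER_WORDS and t not in ("at", "now", "o'clock")]
    words = [t for t in words if not _TIME_RE.match(t) and not _OCLOCK_RE.match(t)]
    return " ".join(words) if words else None


def _failed(u: Utterance) -> ParsedRecord:
    return ParsedRecord(
        source_id=u.id, date=u.date, parse_mode=FAILED, input_time=u.input_time
    )


def _auto(u: Utterance, activity: str, start: int, end: int) -> ParsedRecord:
    return ParsedRecord(
        source_id=u.id,
        date=u.date,
        parse_mode=AUTO,
        activity=activity,
        start=start,
        end=end,
        input_time=u.input_time,
    )


def parse_utterance(
    u: Utterance, sessions: Optional[dict[str, OpenSession]] = None
) -> list[ParsedRecord]:
    """Convert one utterance into timed behavior records.

    Recognized auto patterns:

    * ``[do] <activity> from <t1> to <t2>``
    * ``start <activity> at <t1> ... end <activity> at <t2>``
    * ``<activity> start <t1> end <t2>``

    With a ``sessions`` mapping supplied, ``start <activity> now`` opens a
    pending session stamped with the utterance's input time (and returns
    no record); ``end <activity> now`` closes it through
    :func:`close_session`.  Any other text yields a single failed record —
    parsing never raises on arbitrary content.
    """
    if not u.text.strip():
        raise ParserError(f"utterance {u.id!r}: empty text")
    norm = normalize(u.text)
    if not norm:  # punctuation-only content: unparseable but not invalid
        return [_failed(u)]
    tokens = norm.split()

    record = _parse_from_to(u, tokens)
    if record is None:
        record = _parse_start_end(u, tokens)
    if record is not None:
        return [record]

    if sessions is not None:
        handled = _parse_session_form(u, tokens, sessions)
        if handled is not None:
            return handled

    return [_failed(u)]


def _parse_from_to(u: Utterance, tokens: Sequence[str]) -> Optional[ParsedRecord]:
    if "from" not in tokens or "to" not in tokens:
        return None
    fi = tokens.index("from")
    ti = tokens.index("to", fi + 1) if "to" in tokens[fi + 1 :] else -1
    if ti < 0:
        return None
    t1, _ = _first_time(tokens, fi + 1, ti)
    t2, _ = _first_time(tokens, ti + 1, len(tokens))
    activity = _activity_words(tokens[:fi])
    if activity is None or t1 is None or t2 is None or not t1 < t2:
        return None
    return _auto(u, activity, t1, t2)


def _parse_start_end(u: Utterance, tokens: Sequence[str]) -> Optional[ParsedRecord]:
    if "start" not in tokens or "end" not in tokens:
        return None
    si = tokens.index("start")
    if "end" not in tokens[si + 1 :]:
        return None
    ei = tokens.index("end", si + 1)
    t1, p1 = _first_time(tokens, si + 1, ei)
    t2, _ = _first_time(tokens, ei + 1, len(tokens))
    if t1 is None or t2 is None:
        return None
    # activity before "start" (postfix form) or between "start" and its time
    activity = _activity_words(tokens[:si]) or _activity_words(tokens[si + 1 : p1])
    second = _activity_words(tokens[ei + 1 :])
    if activity is None:
        return None
    if second is not None and second != activity:
        logger.warning(
            "utterance %s: start/end activity mismatch (%r vs %r); first wins",
            u.id, activity, second,
        )
    if not t1 < t2:
        return None
    return _auto(u, activity, t1, t2)


def _parse_session_form(
    u: Utterance, tokens: Sequence[str], sessions: dict[str, OpenSession]
) -> Optional[list[ParsedRecord]]:
    if len(tokens) < 2 or tokens[-1] != "now":
        return None
    head, body = tokens[0], tokens[1:-1]
    activity = _activity_words(body)
    if activity is None:
        return None
    if head == "start":
        sessions[activity] = OpenSession(
            activity=activity, start=u.minute_of_day, date=u.date, source_id=u.id
        )
        return []
    if head == "end":
        pending = sessions.pop(activity, None)
        if pending is None:
            raise OrphanEndError(f"utterance {u.id!r}: no open session for {activity!r}")
        return [close_session(pending, u)]
    return None


def close_session(pending: OpenSession, u: Utterance) -> ParsedRecord:
    """Close a pending session at the end-utterance's input time.

    The end must fall on the same date and strictly after the start
    (zero-length intervals are rejected).
    """
    if u.date != pending.date:
        raise OrphanEndError(
            f"utterance {u.id!r}: open session for {pending.activity!r} is on "
            f"{pending.date}, end is on {u.date}"
        )
    end = u.minute_of_day
    if end <= pending.start:
        raise OrderingError(
            f"session {pending.activity!r}: end minute {end} not after start "
            f"{pending.start}"
        )
    return ParsedRecord(
        source_id=u.id,
        date=u.date,
        parse_mode=AUTO,
        activity=pending.activity,
        start=pending.start,
        end=end,
        input_time=u.input_time,
    )


def manual_override(
    record: ParsedRecord,
    activity: str,
    start: int,
    end: int,
    met: Optional[float] = None,
) -> ParsedRecord:
    """Resolve a failed record by hand, yielding a ``manual`` record.

    Mirrors the study workflow in which non-convertible text was checked
    and converted manually.  Only failed records may be overridden.
    """
    if record.parse_mode != FAILED:
        raise ParserError(
            f"manual_override requires a failed record, got {record.parse_mode!r}"
        )
    if end <= start:
        raise OrderingError(f"end {end} not after start {start}")
    return replace(
        record, parse_mode=MANUAL, activity=activity, start=start, end=end, met=met
    )


def conversion_rate(records: Sequence[ParsedRecord]) -> float:
    """Fraction of records auto-converted, in [0, 1]."""
    if not records:
        raise ValueError("conversion_rate of an empty record list is undefined")
    n_auto = sum(1 for r in records if r.parse_mode == AUTO)
    return n_auto / len(records)


class TranscriptParser:
    """Stateful parser over an utterance stream, tracking open sessions.

    Feeds utterances in input order; "start ... now" / "end ... now"
    session forms are matched across utterances.  Orphan ends and
    mis-ordered sessions become failed records rather than exceptions, so
    a whole transcript always parses.
    """

    def __init__(self) -> None:
        self.sessions: dict[str, OpenSession] = {}

    def feed(self, u: Utterance) -> list[ParsedRecord]:
        try:
            return parse_utterance(u, sessions=self.sessions)
        except (OrphanEndError, OrderingError) as exc:
            logger.warning("utterance %s: %s", u.id, exc)
            return [_failed(u)]

    def parse_all(self, utterances: Sequence[Utterance]) -> list[ParsedRecord]:
        records: list[ParsedRecord] = []
        for u in sorted(utterances, key=lambda x: x.input_time):
            records.extend(self.feed(u))
        for pending in self.sessions.values():
            logger.warning("unclosed session %r from %s", pending.activity, pending.source_id)
        return records
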