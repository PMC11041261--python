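"""Behavior → MET-intensity correspondence table.

The diary pipeline converts activity words ("walking", "training", ...)
into exercise intensities expressed in METs (multiples of resting
metabolic rate).  The packaged default table is a ~50-row subset of the
2011 Compendium of Physical Activities, with two deliberate pins:
``training`` = 5.0 METs and ``sleep`` = 0.9 METs (the same constant used
to impute unmeasured accelerometer time, keeping the two instruments'
arithmetic consistent).

Matching is exact-token over labels and synonyms; there is no fuzzy
matching.  A word absent from the table is a *not-found* value, never a
default intensity — unmatched records are routed to manual review.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

MET_MIN = 0.9
MET_MAX = 20.0

__all__ = [
    "MetEntry",
    "CompendiumTable",
    "CompendiumError",
    "load_compendium",
    "default_compendium",
    "match_activity",
    "assign_met",
]


class CompendiumError(ValueError):
    """Raised for malformed or inconsistent compendium tables."""


@dataclass(frozen=True)
class MetEntry:
    """One behavior with its MET intensity.

    Parameters
    ----------
    label : str
        Canonical activity word, lower-case.
    synonyms : tuple of str
        Alternative tokens mapping to the same entry.
    met_value : float
        Intensity in METs, within [0.9, 20.0].
    category : str
        Free-text group (sleep, locomotion, sports, ...).
    """

    label: str
    synonyms: tuple[str, ...] = ()
    met_value: float = 1.0
    category: str = ""

    def __post_init__(self) -> None:
        if not self.label or self.label != self.label.strip().lower():
            raise CompendiumError(f"label must be a lower-case token: {self.label!r}")
        if not (MET_MIN <= self.met_value <= MET_MAX):
            raise CompendiumError(
                f"met_value {self.met_value} for {self.label!r} outside "
                f"[{MET_MIN}, {MET_MAX}]"
            )

    def tokens(self) -> Iterator[str]:
        yield self.label
        yield from self.synonyms


@dataclass
class CompendiumTable:
    """Validated collection of :class:`MetEntry` rows.

    Tokens (labels and synonyms together) are unique across the table,
    so every token resolves to exactly one entry.
    """

    entries: list[MetEntry]
    version: str = "unversioned"
    _index: dict[str, MetEntry] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise CompendiumError("compendium table is empty")
        index: dict[str, MetEntry] = {}
        for entry in self.entries:
            for token in entry.tokens():
                if token in index:
                    raise CompendiumError(
                        f"duplicate token {token!r} (entries {index[token].label!r} "
                        f"and {entry.label!r})"
                    )
                index[token] = entry
        self._index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def get(self, token: str) -> Optional[MetEntry]:
        return self._index.get(token)


def load_compendium(path: Union[str, Path]) -> CompendiumTable:
    """Load a behavior→MET table from a CSV file.

    The file must have header columns ``label,synonyms,met_value,category``;
    synonyms are ``|``-separated.  Duplicate tokens and out-of-range MET
    values are rejected.

    Raises
    ------
    CompendiumError
        On a malformed row (the message names the line number), a
        duplicate token, or an empty file.
    """
    path = Path(path)
    entries: list[MetEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "synonyms", "met_value", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CompendiumError(
                f"{path}: expected header columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                synonyms = tuple(
                    s.strip().lower() for s in (row["synonyms"] or "").split("|") if s.strip()
                )
                entry = MetEntry(
                    label=(row["label"] or "").strip().lower(),
                    synonyms=synonyms,
                    met_value=float(row["met_value"]),
                    category=(row["category"] or "").strip(),
                )
            except (TypeError, ValueError, KeyError) as exc:
                raise CompendiumError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            entries.append(entry)
    if not entries:
        raise CompendiumError(f"{path}: no data rows")
    return CompendiumTable(entries=entries, version=str(path))


def default_compendium() -> CompendiumTable:
    """Return the packaged default table (2011 Compendium subset)."""
    source = resources.files("vox2mets.data").joinpath("compendium.csv")
    with resources.as_file(source) as path:
        table = load_compendium(path)
    table.version = "vox2mets packaged compendium (2011 Compendium subset)"
    return table


def match_activity(word: str, table: CompendiumTable) -> Optional[MetEntry]:
    """Resolve a normalized token to its table entry.

    Exact label match first, then synonym match (the table index already
    encodes that precedence since tokens are unique).  Returns ``None``
    when the word is not in the table — never a default entry.
    """
    return table.get(word.strip().lower())


def assign_met(record, table: CompendiumTable) -> Optional[float]:
    """Intensity in METs for a parsed record's activity word.

    Returns ``None`` (flagged for manual review) when the activity word is
    not in the table.  Deterministic and independent of the record's times.
    An explicit per-record intensity override (``record.met``) wins over
    the table.
    """
    override = getattr(record, "met", None)
    if override is not None:
        return float(override)
    activity = getattr(record, "activity", None)
    if not activity:
        raise ValueError("record has no activity word")
    entry = match_activity(activity, table)
    return None if entry is None else entry.met_value
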