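"""End-to-end orchestration: transcripts + epochs → validation reports.

The pipeline chains the stages in study order — parse utterances, assign
compendium intensities, resolve overlaps, build per-day timelines,
process accelerometer days, pair the two instruments per analysis mode,
and compute the agreement statistics — and writes every intermediate
table plus a run manifest, so a run is reproducible and auditable.

All study constants (10 h / 14 h thresholds, 0.9 MET imputation, 1.96
limits-of-agreement multiplier, the zero-count threshold) live in
:class:`RunConfig` with the study's values as defaults; sensitivity
analyses need no code change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .accelerometer import EpochSeries, detect_nonwear, day_average_24h, epochs_to_minutes, read_epochs, wear_hours
from .compendium import CompendiumTable, default_compendium, load_compendium
from .parser import (
    FAILED,
    ParsedRecord,
    TranscriptParser,
    Utterance,
    manual_override,
)
from .simulate import NoiseSpec, TrueSchedule, emit_epochs, emit_transcripts
from .timeline import DayTimeline, build_timeline, resolve_overlaps
from .validation import MODES, ParticipantDay, ValidationReport, report

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 1
EXIT_EMPTY_ANALYSIS = 2

__all__ = [
    "RunConfig",
    "PipelineError",
    "EmptyAnalysisError",
    "read_transcripts",
    "write_transcripts",
    "write_epochs",
    "parse_transcripts",
    "records_by_day",
    "build_timelines",
    "cohort_days",
    "run_pipeline",
    "review_queue",
    "apply_overrides",
]


class PipelineError(RuntimeError):
    """Input or schema failure; maps to exit code 1."""


class EmptyAnalysisError(RuntimeError):
    """No participant-day survived the filters; maps to exit code 2."""


@dataclass
class RunConfig:
    """Paths, thresholds and constants for one pipeline run."""

    transcripts: Optional[Path] = None
    epochs: Optional[Path] = None
    compendium: Optional[Path] = None
    out: Path = Path("vox2mets_out")
    min_wear_hours: float = 10.0
    voice_hour_modes: tuple[float, ...] = (10.0, 14.0)
    zero_threshold: float = 0.0
    loa_multiplier: float = 1.96
    imputation_met: float = 0.9
    seed: int = 0
    overrides: Optional[Path] = None

    def __post_init__(self) -> None:
        for name in ("min_wear_hours", "loa_multiplier", "imputation_met"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def load_table(self) -> CompendiumTable:
        if self.compendium is None:
            return default_compendium()
        return load_compendium(self.compendium)


# ---------------------------------------------------------------------------
# transcript / epoch file I/O


def read_transcripts(path: Union[str, Path]) -> list[Utterance]:
    """Read utterances from delimited text or JSON-lines.

    Columns/keys: ``id``, ``text``, ``input_time`` (ISO-8601), and
    optionally ``participant`` (required for end-to-end pairing).
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"transcripts file not found: {path}")
    try:
        if path.suffix in (".jsonl", ".json", ".ndjson"):
            df = pd.read_json(path, lines=True, dtype={"id": str})
        else:
            df = pd.read_csv(path, dtype={"id": str})
    except ValueError as exc:
        raise PipelineError(f"{path}: cannot read transcripts: {exc}") from exc
    required = {"id", "text", "input_time"}
    if not required.issubset(df.columns):
        raise PipelineError(f"{path}: expected columns {sorted(required)}")
    utterances = []
    for i, row in df.iterrows():
        if not isinstance(row["text"], str) or not row["text"].strip():
            raise PipelineError(f"{path}: empty text in record id={row['id']!r}")
        utterances.append(
            Utterance(
                id=str(row["id"]),
                text=row["text"],
                input_time=pd.Timestamp(row["input_time"]).to_pydatetime(),
                participant=(
                    str(row["participant"])
                    if "participant" in df.columns and pd.notna(row["participant"])
                    else None
                ),
            )
        )
    return utterances


def write_transcripts(utterances: Sequence[Utterance], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "id": [u.id for u in utterances],
            "participant": [u.participant for u in utterances],
            "text": [u.text for u in utterances],
            "input_time": [u.input_time.isoformat() for u in utterances],
        }
    ).to_csv(path, index=False)


def write_epochs(series: Sequence[EpochSeries], path: Union[str, Path]) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant": s.participant,
                "date": s.date.isoformat(),
                "epoch_index": np.arange(s.values.size),
                "met": s.values,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stage helpers


def parse_transcripts(utterances: Sequence[Utterance]) -> list[ParsedRecord]:
    """Parse a transcript stream in input-time order (session-aware)."""
    return TranscriptParser().parse_all(utterances)


def records_by_day(
    utterances: Sequence[Utterance], records: Sequence[ParsedRecord]
) -> dict[tuple[str, object], list[ParsedRecord]]:
    """Group resolved records by (participant, date) via their source utterance."""
    participant_of = {u.id: u.participant for u in utterances}
    groups: dict[tuple[str, object], list[ParsedRecord]] = {}
    for r in records:
        if r.parse_mode == FAILED:
            continue
        participant = participant_of.get(r.source_id)
        if participant is None:
            raise PipelineError(
                f"record {r.source_id!r} has no participant; transcripts need a "
                "participant column for end-to-end runs"
            )
        groups.setdefault((participant, r.date), []).append(r)
    return groups


def build_timelines(
    utterances: Sequence[Utterance],
    records: Sequence[ParsedRecord],
    table: CompendiumTable,
) -> list[DayTimeline]:
    timelines = []
    for (participant, date), recs in sorted(records_by_day(utterances, records).items()):
        resolved = resolve_overlaps(recs)
        timelines.append(
            build_timeline(resolved, table, participant=participant, date=date)
        )
    return timelines


def cohort_days(
    schedules: Sequence[TrueSchedule],
    noise: NoiseSpec,
    table: CompendiumTable,
    rng: Optional[np.random.Generator] = None,
) -> list[ParticipantDay]:
    """Simulate and process a cohort fully in memory (no files).

    For each true schedule, emits transcripts and epochs under the noise
    model, parses the transcripts and builds the paired participant-day.
    Days whose diary yields no resolvable record are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    days: list[ParticipantDay] = []
    for sched in schedules:
        utterances = emit_transcripts(sched, noise, rng=rng)
        epochs = emit_epochs(sched, noise, rng=rng)
        records = parse_transcripts(utterances)
        kept = [r for r in records if r.parse_mode != FAILED]
        if not kept:
            continue
        resolved = resolve_overlaps(kept)
        tl = build_timeline(
            resolved, table, participant=sched.participant, date=sched.date
        )
        days.append(ParticipantDay(timeline=tl, epochs=epochs))
    return days


# ---------------------------------------------------------------------------
# manual-review workflow


def review_queue(records: Sequence[ParsedRecord], path: Union[str, Path]) -> int:
    """Write failed records to a CSV override template; returns the count."""
    failed = [r for r in records if r.parse_mode == FAILED]
    pd.DataFrame(
        {
            "source_id": [r.source_id for r in failed],
            "date": [r.date.isoformat() for r in failed],
            "activity": "",
            "start": "",
            "end": "",
            "met": "",
        }
    ).to_csv(path, index=False)
    return len(failed)


def apply_overrides(
    records: Sequence[ParsedRecord], path: Union[str, Path]
) -> list[ParsedRecord]:
    """Apply a filled review file, turning failed records into manual ones.

    Rows with an empty activity are skipped (still unreviewed).  Unknown
    or duplicate ``source_id`` values are errors listing the offending
    ids.  Applying the same file to the same parse output is idempotent.
    """
    df = pd.read_csv(path, dtype={"source_id": str})
    df = df[df["activity"].notna() & (df["activity"].astype(str).str.strip() != "")]
    dupes = df.loc[df["source_id"].duplicated(), "source_id"].tolist()
    if dupes:
        raise PipelineError(f"duplicate override rows for ids: {sorted(set(dupes))}")
    by_id = {r.source_id: r for r in records if r.parse_mode == FAILED}
    unknown = [sid for sid in df["source_id"] if sid not in by_id]
    if unknown:
        raise PipelineError(f"overrides reference unknown/non-failed ids: {unknown}")
    out: list[ParsedRecord] = []
    overrides = df.set_index("source_id")
    for r in records:
        if r.parse_mode == FAILED and r.source_id in overrides.index:
            row = overrides.loc[r.source_id]
            met = float(row["met"]) if not pd.isna(row.get("met")) and str(row.get("met")).strip() != "" else None
            out.append(
                manual_override(
                    r,
                    activity=str(row["activity"]).strip().lower(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    met=met,
                )
            )
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# full run


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts; returns the manifest.

    Raises :class:`PipelineError` on unreadable/malformed inputs and
    :class:`EmptyAnalysisError` when no mode has an analyzable day set.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    table = cfg.load_table()
    if cfg.transcripts is None or cfg.epochs is None:
        raise PipelineError("run_pipeline needs both transcripts and epochs paths")
    utterances = read_transcripts(cfg.transcripts)
    records = parse_transcripts(utterances)
    if cfg.overrides is not None:
        records = apply_overrides(records, cfg.overrides)

    queue_path = out / "review_queue.csv"
    n_failed = review_queue(records, queue_path)

    pd.DataFrame(
        {
            "source_id": [r.source_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "parse_mode": [r.parse_mode for r in records],
            "activity": [r.activity for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "met": [r.met for r in records],
        }
    ).to_csv(out / "parsed_records.csv", index=False)

    timelines = build_timelines(utterances, records, table)
    tl_rows = []
    for tl in timelines:
        tl_rows.append(
            pd.DataFrame(
                {
                    "participant": tl.participant,
                    "date": tl.date.isoformat(),
                    "minute": np.arange(tl.covered.size),
                    "met": np.where(tl.covered, tl.intensity, np.nan),
                    "covered": tl.covered.astype(int),
                }
            )
        )
    if tl_rows:
        pd.concat(tl_rows, ignore_index=True).to_csv(out / "timelines.csv", index=False)

    epoch_days = read_epochs(cfg.epochs, zero_threshold=cfg.zero_threshold)
    accel_rows = []
    for s in epoch_days:
        mask = detect_nonwear(s)
        accel_rows.append(
            {
                "participant": s.participant,
                "date": s.date.isoformat(),
                "wear_hours": wear_hours(mask),
                "average_24h": day_average_24h(
                    epochs_to_minutes(s), mask, imputed_met=cfg.imputation_met
                ),
            }
        )
    pd.DataFrame(accel_rows).to_csv(out / "accel_days.csv", index=False)

    tl_by_key = {(tl.participant, tl.date): tl for tl in timelines}
    days = [
        ParticipantDay(timeline=tl_by_key[(s.participant, s.date)], epochs=s)
        for s in epoch_days
        if (s.participant, s.date) in tl_by_key
    ]

    reports = report(
        days,
        min_wear_hours=cfg.min_wear_hours,
        loa_multiplier=cfg.loa_multiplier,
    )
    if all(rep.insufficient for rep in reports.values()):
        raise EmptyAnalysisError(
            "no analysis mode has at least 2 paired participant-days"
        )

    for mode, rep in reports.items():
        pairs_df = pd.DataFrame(
            {
                "participant": [p.participant for p in rep.pairs],
                "date": [p.date.isoformat() for p in rep.pairs],
                "voice_mean": [p.voice_mean for p in rep.pairs],
                "accel_mean": [p.accel_mean for p in rep.pairs],
                "matched_minutes": [p.matched_minutes for p in rep.pairs],
            }
        )
        pairs_df.to_csv(out / f"pairs_{mode}.csv", index=False)
        pairs_df[["voice_mean", "accel_mean"]].to_csv(
            out / f"scatter_{mode}.csv", index=False
        )
        pd.DataFrame(
            {
                "mean": [(p.voice_mean + p.accel_mean) / 2 for p in rep.pairs],
                "diff": [p.voice_mean - p.accel_mean for p in rep.pairs],
            }
        ).to_csv(out / f"bland_altman_{mode}.csv", index=False)

    with (out / "report.json").open("w") as fh:
        json.dump({m: r.to_dict() for m, r in reports.items()}, fh, indent=2)

    mode_counts = {m: reports[m].n_days for m in reports}
    manifest = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(cfg).items()
        },
        "n_utterances": len(utterances),
        "n_records": len(records),
        "n_auto": sum(1 for r in records if r.parse_mode == "auto"),
        "n_manual": sum(1 for r in records if r.parse_mode == "manual"),
        "n_failed": n_failed,
        "n_timeline_days": len(timelines),
        "n_epoch_days": len(epoch_days),
        "days_per_mode": mode_counts,
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
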