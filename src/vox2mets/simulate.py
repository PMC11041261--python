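"""Synthetic paired voice-diary + accelerometer cohorts.

The study's raw participant data are not deposited, so every pipeline
stage is exercised against simulated cohorts generated from a known true
activity schedule.  A *template day* (sleep, meals, commute walking,
study blocks, an optional sport, evening leisure) is jittered per
participant-day; the template leaves short unreported gaps between
activities, as real diaries do.  From each true schedule the simulator
emits

* transcripts — each interval rendered in one of the parser's
  recognized trigger-word patterns, or (with probability
  ``p_trigger_omission``) in a deliberately non-parseable form modeled
  on the study's failure examples ("get up at 7:00", "going home by
  riding a bicycle");
* accelerometer epochs — six 10-s epochs per scheduled minute at the
  true MET value, plus optional Gaussian noise (truncated at 0) and an
  optional additive bias on sports activities (modeling the device
  reading intense exercise above the diary's fixed compendium value);
  unscheduled minutes are zero counts, and sleep can be emitted as zero
  counts to model device removal overnight.

Default cohort size is 20 participants × 7 days — 140 participant-days,
the study's design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .accelerometer import EPOCHS_PER_DAY, EPOCHS_PER_MINUTE, EpochSeries
from .compendium import CompendiumTable, default_compendium, match_activity
from .parser import Utterance
from .timeline import MINUTES_PER_DAY

DEFAULT_PARTICIPANTS = 20
DEFAULT_DAYS = 7

__all__ = [
    "ScheduledInterval",
    "TrueSchedule",
    "NoiseSpec",
    "CohortSpec",
    "generate_schedule",
    "emit_transcripts",
    "emit_epochs",
    "recovery_experiment",
]


@dataclass(frozen=True)
class ScheduledInterval:
    """One true behavior: label, [start, end) minutes, true MET, category."""

    activity: str
    start: int
    end: int
    met: float
    category: str = ""

    @property
    def is_sport(self) -> bool:
        return self.category == "sports"


@dataclass
class TrueSchedule:
    """Ground-truth activity schedule for one participant-day."""

    participant: str
    date: Date
    intervals: list[ScheduledInterval]

    def __post_init__(self) -> None:
        prev_end = 0
        for iv in sorted(self.intervals, key=lambda iv: iv.start):
            if iv.end - iv.start < 1 or iv.start < 0 or iv.end > MINUTES_PER_DAY:
                raise ValueError(f"bad interval {iv}")
            if iv.start < prev_end:
                raise ValueError(f"overlapping intervals at minute {iv.start}")
            prev_end = iv.end


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and compliance knobs for the forward model.

    p_record_missing : probability an interval is never spoken.
    p_trigger_omission : probability an utterance is emitted in a
        non-parseable form (no usable trigger pattern).
    accel_sigma : per-epoch Gaussian intensity noise SD, METs.
    met_bias : additive offset applied to the device signal on sports
        intervals (device sees harder exercise than the diary's fixed
        compendium value when positive).
    nonwear_blocks : minute intervals forced to zero counts.
    sleep_nonwear : emit sleep intervals as zero counts (device removed
        overnight, as study participants were instructed).
    """

    p_record_missing: float = 0.0
    p_trigger_omission: float = 0.0
    accel_sigma: float = 0.0
    met_bias: float = 0.0
    nonwear_blocks: tuple[tuple[int, int], ...] = ()
    sleep_nonwear: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.p_record_missing, self.p_trigger_omission):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.accel_sigma < 0:
            raise ValueError("accel_sigma must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort dimensions: participants × days per participant."""

    n_participants: int = DEFAULT_PARTICIPANTS
    n_days: int = DEFAULT_DAYS
    start_date: Date = Date(2020, 1, 6)
    p_sport_day: float = 0.5


# (activity, nominal start, nominal end, boundary jitter in minutes);
# None marks the slot replaced by a sport on sport days
_TEMPLATE = [
    ("sleep", 0, 420, 25),
    ("grooming", 425, 445, 5),
    ("meal", 450, 475, 5),
    ("walking", 485, 510, 5),
    ("study", 520, 690, 15),
    ("meal", 700, 740, 5),
    ("study", 750, 920, 15),
    ("walking", 930, 955, 5),
    (None, 965, 1030, 10),
    ("meal", 1100, 1140, 10),
    ("bathing", 1150, 1170, 5),
    ("tv", 1180, 1300, 15),
    ("sleep", 1320, 1440, 0),
]

_SPORTS = ("training", "running", "basketball", "tennis", "swimming")

# Non-parseable utterance pool: the study's printed failure phrases plus
# templated variants (no usable trigger pattern).
_UNPARSEABLE = (
    "get up at 7:00",
    "going home by riding a bicycle",
    "finished {activity} a while ago",
    "i was busy with {activity} this morning",
    "{activity} went well today",
)

_PATTERNS = (
    "{activity} from {t1} to {t2}",
    "do {activity} from {t1} to {t2}",
    "start {activity} at {t1}, end {activity} at {t2}",
    "{activity} start {t1} end {t2}",
)


def _fmt(minute: int) -> str:
    return f"{minute // 60}:{minute % 60:02d}"


def generate_schedule(
    spec: CohortSpec,
    seed: int,
    table: Optional[CompendiumTable] = None,
) -> list[TrueSchedule]:
    """Reproducible true schedules for a cohort, one per participant-day.

    Daily schedules follow the jittered template; every activity label
    resolves in the compendium, whose MET value is the ground truth.
    """
    if spec.n_participants < 1 or spec.n_days < 1:
        raise ValueError("need at least one participant-day")
    if table is None:
        table = default_compendium()
    if len(table) == 0:
        raise ValueError("empty compendium")
    rng = np.random.default_rng(seed)
    schedules: list[TrueSchedule] = []
    for p in range(spec.n_participants):
        participant = f"P{p + 1:02d}"
        for d in range(spec.n_days):
            date = spec.start_date + timedelta(days=d)
            sport_day = rng.random() < spec.p_sport_day
            intervals: list[ScheduledInterval] = []
            prev_end = 0
            for slot, (label, lo, hi, jit) in enumerate(_TEMPLATE):
                if label is None:
                    if not sport_day:
                        continue
                    label = str(rng.choice(_SPORTS))
                start = lo + (int(rng.integers(-jit, jit + 1)) if jit else 0)
                end = hi + (int(rng.integers(-jit, jit + 1)) if jit else 0)
                start = max(start, prev_end + (1 if intervals else 0))
                end = min(max(end, start + 5), MINUTES_PER_DAY)
                if end - start < 1:
                    continue
                entry = match_activity(label, table)
                if entry is None:
                    raise ValueError(f"template activity {label!r} not in compendium")
                intervals.append(
                    ScheduledInterval(
                        activity=label,
                        start=start,
                        end=end,
                        met=entry.met_value,
                        category=entry.category,
                    )
                )
                prev_end = end
            schedules.append(
                TrueSchedule(participant=participant, date=date, intervals=intervals)
            )
    return schedules


def emit_transcripts(
    sched: TrueSchedule,
    noise: NoiseSpec = NoiseSpec(),
    rng: Optional[np.random.Generator] = None,
) -> list[Utterance]:
    """Render a true schedule as diary utterances, ordered by start time.

    With zero noise every utterance parses automatically and round-trips
    its interval exactly.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    utterances: list[Utterance] = []
    for k, iv in enumerate(sorted(sched.intervals, key=lambda iv: iv.start)):
        if rng.random() < noise.p_record_missing:
            continue
        if rng.random() < noise.p_trigger_omission:
            text = str(rng.choice(_UNPARSEABLE)).format(activity=iv.activity)
        else:
            pattern = str(rng.choice(_PATTERNS))
            text = pattern.format(
                activity=iv.activity, t1=_fmt(iv.start), t2=_fmt(min(iv.end, 1439))
            )
        spoken_minute = min(iv.end, MINUTES_PER_DAY - 1)
        utterances.append(
            Utterance(
                id=f"{sched.participant}-{sched.date.isoformat()}-{k:03d}",
                text=text,
                input_time=datetime.combine(
                    sched.date, time(spoken_minute // 60, spoken_minute % 60)
                ),
                participant=sched.participant,
            )
        )
    return utterances


def emit_epochs(
    sched: TrueSchedule,
    noise: NoiseSpec = NoiseSpec(),
    rng: Optional[np.random.Generator] = None,
) -> EpochSeries:
    """Forward-model the device: 10-s epochs from the true schedule.

    Scheduled minutes carry the true MET (plus ``met_bias`` on sports)
    with optional Gaussian epoch noise truncated at 0; unscheduled
    minutes, ``nonwear_blocks`` and (optionally) sleep are zero counts.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    values = np.zeros(EPOCHS_PER_DAY)
    for iv in sched.intervals:
        if noise.sleep_nonwear and iv.activity == "sleep":
            continue
        base = iv.met + (noise.met_bias if iv.is_sport else 0.0)
        lo, hi = iv.start * EPOCHS_PER_MINUTE, iv.end * EPOCHS_PER_MINUTE
        block = np.full(hi - lo, base)
        if noise.accel_sigma > 0:
            block = block + rng.normal(0.0, noise.accel_sigma, hi - lo)
        values[lo:hi] = np.clip(block, 0.0, None)
    for lo, hi in noise.nonwear_blocks:
        values[lo * EPOCHS_PER_MINUTE : hi * EPOCHS_PER_MINUTE] = 0.0
    return EpochSeries(
        participant=sched.participant, date=sched.date, values=values
    )


def recovery_experiment(
    spec: CohortSpec,
    noise_grid: Sequence[NoiseSpec],
    seed: int,
    table: Optional[CompendiumTable] = None,
):
    """Run the full pipeline per noise level; summarize matched-mode agreement.

    Returns a list of dicts (one per noise level) with the matched-mode
    mean difference, Pearson r (NaN when degenerate) and day count.
    Agreement degrades monotonically in expectation with rising
    ``accel_sigma`` and ``met_bias``.
    """
    from .pipeline import cohort_days  # deferred: pipeline imports this module

    if table is None:
        table = default_compendium()
    schedules = generate_schedule(spec, seed=seed, table=table)
    rows = []
    from .validation import report as run_report

    for level, noise in enumerate(noise_grid):
        rng = np.random.default_rng((seed, level))
        days = cohort_days(schedules, noise, table, rng=rng)
        rep = run_report(days, modes=("matched",))["matched"]
        ba = rep.bland_altman
        corr = rep.correlation
        rows.append(
            {
                "accel_sigma": noise.accel_sigma,
                "met_bias": noise.met_bias,
                "n_days": rep.n_days,
                "mean_diff": ba.mean_diff if ba is not None else float("nan"),
                "r": corr.r if corr is not None else float("nan"),
                "r_degenerate": bool(corr.degenerate) if corr is not None else True,
            }
        )
    return rows
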