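"""Method-agreement analyses between the voice diary and the accelerometer.

Three analysis modes mirror the validation design:

``ge10h`` / ``ge14h``
    Participant-days with at least 10 (resp. 14) hours of diary
    coverage; the diary mean is the average over covered minutes, the
    accelerometer mean is the 24-hour average with 0.9-MET imputation.
``matched``
    Time-matched analysis: both instruments restricted, minute by
    minute, to the intersection of diary coverage and accelerometer
    wear before averaging.

An accelerometer wear filter (≥ 10 h by default) applies in every mode.
Per-mode statistics are the paired t-test, Pearson's r, and Bland–Altman
agreement (difference = voice − accelerometer; limits of agreement =
mean ± 1.96·SD with the n−1 SD; trend = OLS regression of difference on
pairwise mean).  Degenerate inputs (zero-variance differences, constant
series) are reported as explicit flags, never as p = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import accelerometer as accel
from .accelerometer import EpochSeries, day_average_24h, detect_nonwear, epochs_to_minutes, wear_hours
from .timeline import DayTimeline, average_mets, recorded_hours

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96
MODES = ("ge10h", "ge14h", "matched")
VOICE_HOUR_THRESHOLDS = {"ge10h": 10.0, "ge14h": 14.0}

__all__ = [
    "MODES",
    "LOA_MULTIPLIER",
    "NoOverlapError",
    "ParticipantDay",
    "PairedDay",
    "PairedT",
    "Pearson",
    "BlandAltman",
    "ValidationReport",
    "time_match",
    "daily_pairs",
    "paired_t",
    "pearson",
    "bland_altman",
    "report",
]


class NoOverlapError(ValueError):
    """Diary coverage and accelerometer wear share no minutes on a day."""


@dataclass
class ParticipantDay:
    """One participant-day of paired raw inputs (diary timeline + epochs)."""

    timeline: DayTimeline
    epochs: EpochSeries

    @property
    def participant(self) -> str:
        return self.timeline.participant

    @property
    def date(self) -> Date:
        return self.timeline.date


@dataclass(frozen=True)
class PairedDay:
    """Per-day paired means for one analysis mode."""

    participant: str
    date: Date
    voice_mean: float
    accel_mean: float
    mode: str
    matched_minutes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "matched" and (self.matched_minutes or 0) < 1:
            raise ValueError("matched mode requires at least one matched minute")


@dataclass(frozen=True)
class PairedT:
    t: float
    p: float
    n: int
    degenerate: bool = False  # zero-variance differences


@dataclass(frozen=True)
class Pearson:
    r: float
    p: float
    n: int
    degenerate: bool = False  # a constant series


@dataclass(frozen=True)
class BlandAltman:
    """Agreement summary: difference (voice − accelerometer) vs mean."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_intercept: float
    trend_r: float
    trend_p: float
    n: int
    trend_degenerate: bool = False  # constant pairwise means


@dataclass
class ValidationReport:
    """All per-mode statistics, or an insufficient-data marker."""

    mode: str
    n_days: int
    insufficient: bool = False
    voice_mean: float = math.nan
    voice_sd: float = math.nan
    accel_mean: float = math.nan
    accel_sd: float = math.nan
    ttest: Optional[PairedT] = None
    correlation: Optional[Pearson] = None
    bland_altman: Optional[BlandAltman] = None
    pairs: list[PairedDay] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {
            "mode": self.mode,
            "n_days": self.n_days,
            "insufficient": self.insufficient,
            "voice_mean": self.voice_mean,
            "voice_sd": self.voice_sd,
            "accel_mean": self.accel_mean,
            "accel_sd": self.accel_sd,
        }
        if self.ttest is not None:
            out["paired_t"] = vars(self.ttest).copy()
        if self.correlation is not None:
            out["pearson"] = vars(self.correlation).copy()
        if self.bland_altman is not None:
            out["bland_altman"] = vars(self.bland_altman).copy()
        return out


def time_match(
    tl: DayTimeline, accel_minutes: np.ndarray, wear: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Minute-matched diary and accelerometer series for one day.

    Minutes are included iff the diary covers them AND the device was
    worn.  Raises :class:`NoOverlapError` when the intersection is empty
    (the day is excluded from the matched analysis).
    """
    wear = np.asarray(wear, dtype=bool)
    keep = tl.covered & wear
    if not keep.any():
        raise NoOverlapError(
            f"{tl.participant}/{tl.date}: no minute is both diary-covered and worn"
        )
    return tl.intensity[keep], np.asarray(accel_minutes, dtype=float)[keep]


def daily_pairs(
    days: Sequence[ParticipantDay],
    mode: str,
    min_wear_hours: float = accel.DEFAULT_MIN_WEAR_HOURS,
    voice_hours: Optional[float] = None,
) -> list[PairedDay]:
    """Per-day paired means for one analysis mode.

    The accelerometer wear filter (≥ ``min_wear_hours``) applies in all
    modes.  ``ge10h``/``ge14h`` additionally require the stated hours of
    diary coverage; ``matched`` requires a non-empty minute match.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if voice_hours is None:
        voice_hours = VOICE_HOUR_THRESHOLDS.get(mode, 0.0)
    pairs: list[PairedDay] = []
    for day in days:
        mask = detect_nonwear(day.epochs)
        if wear_hours(mask) < min_wear_hours:
            continue
        minutes = epochs_to_minutes(day.epochs)
        if mode == "matched":
            try:
                v, a = time_match(day.timeline, minutes, mask)
            except NoOverlapError as exc:
                logger.info("%s", exc)
                continue
            pairs.append(
                PairedDay(
                    participant=day.participant,
                    date=day.date,
                    voice_mean=float(v.mean()),
                    accel_mean=float(a.mean()),
                    mode=mode,
                    matched_minutes=int(v.size),
                )
            )
        else:
            if recorded_hours(day.timeline) < voice_hours:
                continue
            pairs.append(
                PairedDay(
                    participant=day.participant,
                    date=day.date,
                    voice_mean=average_mets(day.timeline),
                    accel_mean=day_average_24h(minutes, mask),
                    mode=mode,
                )
            )
    return pairs


def _diffs(pairs: Sequence[PairedDay]) -> np.ndarray:
    return np.array([p.voice_mean - p.accel_mean for p in pairs])


def paired_t(pairs: Sequence[PairedDay]) -> PairedT:
    """Two-sided paired t-test on (voice − accelerometer) daily means."""
    n = len(pairs)
    if n < 2:
        raise ValueError(f"paired t-test needs at least 2 pairs, got {n}")
    d = _diffs(pairs)
    if np.ptp(d) == 0.0:
        return PairedT(t=math.nan, p=math.nan, n=n, degenerate=True)
    voice = np.array([p.voice_mean for p in pairs])
    accl = np.array([p.accel_mean for p in pairs])
    res = stats.ttest_rel(voice, accl)
    return PairedT(t=float(res.statistic), p=float(res.pvalue), n=n)


def pearson(pairs: Sequence[PairedDay]) -> Pearson:
    """Sample Pearson correlation of the two daily-mean series."""
    n = len(pairs)
    if n < 3:
        raise ValueError(f"Pearson correlation needs at least 3 pairs, got {n}")
    voice = np.array([p.voice_mean for p in pairs])
    accl = np.array([p.accel_mean for p in pairs])
    if np.ptp(voice) == 0.0 or np.ptp(accl) == 0.0:
        return Pearson(r=math.nan, p=math.nan, n=n, degenerate=True)
    res = stats.pearsonr(voice, accl)
    return Pearson(r=float(res.statistic), p=float(res.pvalue), n=n)


def bland_altman(
    pairs: Sequence[PairedDay], loa_multiplier: float = LOA_MULTIPLIER
) -> BlandAltman:
    """Bland–Altman agreement with trend regression.

    Difference is voice − accelerometer; limits of agreement are
    mean ± 1.96·SD (sample SD, n−1).  The trend test regresses the
    difference on the pairwise mean (OLS) and reports slope, intercept,
    r and the two-sided p for the slope.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"Bland-Altman needs at least 3 pairs, got {n}")
    d = _diffs(pairs)
    m = np.array([(p.voice_mean + p.accel_mean) / 2.0 for p in pairs])
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - loa_multiplier * sd_diff
    loa_high = mean_diff + loa_multiplier * sd_diff
    if np.ptp(m) == 0.0:
        return BlandAltman(
            mean_diff=mean_diff,
            sd_diff=sd_diff,
            loa_low=loa_low,
            loa_high=loa_high,
            trend_slope=math.nan,
            trend_intercept=math.nan,
            trend_r=math.nan,
            trend_p=math.nan,
            n=n,
            trend_degenerate=True,
        )
    reg = stats.linregress(m, d)
    trend_p = float(reg.pvalue) if sd_diff > 0 else math.nan
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        trend_slope=float(reg.slope),
        trend_intercept=float(reg.intercept),
        trend_r=float(reg.rvalue),
        trend_p=trend_p,
        n=n,
    )


def report(
    days: Sequence[ParticipantDay],
    modes: Sequence[str] = MODES,
    min_wear_hours: float = accel.DEFAULT_MIN_WEAR_HOURS,
    loa_multiplier: float = LOA_MULTIPLIER,
) -> dict[str, ValidationReport]:
    """One :class:`ValidationReport` per analysis mode.

    Modes with fewer than 2 paired days are marked insufficient; the
    correlation and Bland–Altman entries additionally require 3 days.
    """
    out: dict[str, ValidationReport] = {}
    for mode in modes:
        pairs = daily_pairs(days, mode, min_wear_hours=min_wear_hours)
        n = len(pairs)
        rep = ValidationReport(mode=mode, n_days=n, pairs=pairs)
        if n < 2:
            rep.insufficient = True
            out[mode] = rep
            continue
        voice = np.array([p.voice_mean for p in pairs])
        accl = np.array([p.accel_mean for p in pairs])
        rep.voice_mean = float(voice.mean())
        rep.voice_sd = float(voice.std(ddof=1))
        rep.accel_mean = float(accl.mean())
        rep.accel_sd = float(accl.std(ddof=1))
        rep.ttest = paired_t(pairs)
        if n >= 3:
            rep.correlation = pearson(pairs)
            rep.bland_altman = bland_altman(pairs, loa_multiplier=loa_multiplier)
        out[mode] = rep
    return out
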