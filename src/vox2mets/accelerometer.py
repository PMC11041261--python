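"""Accelerometer epoch processing: non-wear, wear time, 24-h average METs.

The reference instrument exports activity intensity in METs at 10-second
epochs (8640 per day).  Epochs at or below a detection threshold
(default 0.0 METs) are *zero counts*; a maximal run of zero counts
strictly longer than 60 minutes is classified as non-wear (device off —
the wearer removed it, e.g. for sleep or bathing).  Wear time is
24 h minus non-wear time, and only days with at least 10 h of wear are
analyzed.  The 24-hour average MET value substitutes 0.9 METs for every
non-wear minute, so a fully non-worn day averages exactly 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

EPOCH_SECONDS = 10
EPOCHS_PER_DAY = 86400 // EPOCH_SECONDS  # 8640
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS  # 6
MINUTES_PER_DAY = 1440
NONWEAR_RUN_EPOCHS = 60 * EPOCHS_PER_MINUTE  # runs must be STRICTLY longer
IMPUTED_MET = 0.9
DEFAULT_MIN_WEAR_HOURS = 10.0

__all__ = [
    "EpochSeries",
    "EpochReadError",
    "read_epochs",
    "detect_nonwear",
    "wear_hours",
    "nonwear_hours",
    "epochs_to_minutes",
    "day_average_24h",
    "valid_days",
]


class EpochReadError(ValueError):
    """Raised for malformed epoch files."""


@dataclass
class EpochSeries:
    """One day of 10-second accelerometer intensities for one participant."""

    participant: str
    date: Date
    values: np.ndarray
    zero_threshold: float = 0.0
    epoch_seconds: int = field(default=EPOCH_SECONDS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.epoch_seconds != EPOCH_SECONDS:
            raise EpochReadError(f"epoch length must be {EPOCH_SECONDS} s")
        if self.values.shape != (EPOCHS_PER_DAY,):
            raise EpochReadError(
                f"expected {EPOCHS_PER_DAY} epochs, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise EpochReadError("negative epoch intensities")

    def zero_counts(self) -> np.ndarray:
        """Boolean array: epoch at/below the detection threshold."""
        return self.values <= self.zero_threshold


def read_epochs(
    path: Union[str, Path], zero_threshold: float = 0.0
) -> list[EpochSeries]:
    """Read per-participant-day epoch series from a delimited text file.

    Expected columns: ``participant,date,epoch_index,met`` with
    ``epoch_index`` in [0, 8639].  Missing epochs are filled as zero
    counts with a warning; duplicate indices and negative METs are
    errors.
    """
    df = pd.read_csv(path, dtype={"participant": str})
    required = {"participant", "date", "epoch_index", "met"}
    if not required.issubset(df.columns):
        raise EpochReadError(f"{path}: expected columns {sorted(required)}")
    if (df["met"] < 0).any():
        bad = df.index[df["met"] < 0][0]
        raise EpochReadError(f"{path}: negative MET at row {bad}")
    if ((df["epoch_index"] < 0) | (df["epoch_index"] >= EPOCHS_PER_DAY)).any():
        bad = df.loc[
            (df["epoch_index"] < 0) | (df["epoch_index"] >= EPOCHS_PER_DAY),
            "epoch_index",
        ].iloc[0]
        raise EpochReadError(f"{path}: epoch_index {bad} outside [0, {EPOCHS_PER_DAY - 1}]")

    series: list[EpochSeries] = []
    for (participant, date_str), group in df.groupby(["participant", "date"], sort=True):
        if group["epoch_index"].duplicated().any():
            dup = group.loc[group["epoch_index"].duplicated(), "epoch_index"].iloc[0]
            raise EpochReadError(
                f"{path}: duplicate epoch_index {dup} for {participant}/{date_str}"
            )
        values = np.zeros(EPOCHS_PER_DAY)
        values[group["epoch_index"].to_numpy()] = group["met"].to_numpy()
        n_missing = EPOCHS_PER_DAY - len(group)
        if n_missing:
            warnings.warn(
                f"{participant}/{date_str}: {n_missing} missing epochs filled as zero counts",
                stacklevel=2,
            )
        series.append(
            EpochSeries(
                participant=str(participant),
                date=pd.Timestamp(date_str).date(),
                values=values,
                zero_threshold=zero_threshold,
            )
        )
    return series


def detect_nonwear(s: EpochSeries) -> np.ndarray:
    """Per-minute wear mask (1440 booleans, True = worn).

    A maximal run of consecutive zero-count epochs strictly longer than
    60 minutes (> 360 epochs) is non-wear; a minute is non-wear iff all
    6 of its epochs lie inside such a run.  A run of exactly 60 minutes
    therefore counts as wear.
    """
    zero = s.zero_counts()
    nonwear_epochs = np.zeros(EPOCHS_PER_DAY, dtype=bool)
    # maximal zero runs via change-point indices
    padded = np.concatenate(([False], zero, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    for start, stop in zip(changes[::2], changes[1::2]):
        if stop - start > NONWEAR_RUN_EPOCHS:
            nonwear_epochs[start:stop] = True
    by_minute = nonwear_epochs.reshape(MINUTES_PER_DAY, EPOCHS_PER_MINUTE)
    return ~by_minute.all(axis=1)


def wear_hours(mask: np.ndarray) -> float:
    """Worn time in hours from a per-minute wear mask."""
    mask = np.asarray(mask, dtype=bool)
    return int(mask.sum()) / 60.0


def nonwear_hours(mask: np.ndarray) -> float:
    """Non-worn time in hours; wear_hours + nonwear_hours = 24 exactly."""
    mask = np.asarray(mask, dtype=bool)
    return int((~mask).sum()) / 60.0


def epochs_to_minutes(s: EpochSeries) -> np.ndarray:
    """Per-minute MET array (1440): arithmetic mean of each minute's 6 epochs.

    Means are accumulated in extended precision so that a minute of six
    identical epochs reproduces that value bit-for-bit in float64.
    """
    blocks = s.values.reshape(MINUTES_PER_DAY, EPOCHS_PER_MINUTE)
    return blocks.astype(np.longdouble).mean(axis=1).astype(np.float64)


def day_average_24h(
    minutes: np.ndarray, mask: np.ndarray, imputed_met: float = IMPUTED_MET
) -> float:
    """24-hour average METs with 0.9 imputed for each non-wear minute."""
    minutes = np.asarray(minutes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if minutes.shape != (MINUTES_PER_DAY,) or mask.shape != (MINUTES_PER_DAY,):
        raise ValueError("minute arrays must have length 1440")
    filled = np.where(mask, minutes, imputed_met)
    # extended-precision accumulation: a fully imputed day averages to
    # exactly the imputation constant in float64
    return float(filled.astype(np.longdouble).mean())


def valid_days(
    days: Sequence[EpochSeries], min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS
) -> list[EpochSeries]:
    """Days meeting the wear-time inclusion rule (wear ≥ threshold, inclusive)."""
    if min_wear_hours <= 0:
        raise ValueError("min_wear_hours must be positive")
    return [s for s in days if wear_hours(detect_nonwear(s)) >= min_wear_hours]
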