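"""Wear-time validation and intensity classification for count series.

Non-wear is flagged by the standard consecutive-zero rule: any run of zero
counts at least as long as the window (default 60 min) is off-body.  Days
with >= 8 h (480 min) of wear are valid; a patient enters cohort analyses
only with >= 4 valid days in each of the two post-discharge weeks.
Intensity bands follow the vertical-axis count cut-points: stationary below
100 counts/min, MVPA at or above the configured ambulation cut (default
1952 counts/min), light in between.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .data_model import ConfigError, CountsEpochSeries, DomainError

__all__ = [
    "Intensity",
    "IntensityCutpoints",
    "WearFlagSeries",
    "ValidDay",
    "detect_nonwear",
    "classify_intensity",
    "validate_days",
    "patient_inclusion",
    "cohort_daily_profile",
    "VALID_DAY_MIN",
    "MIN_VALID_DAYS_PER_WEEK",
]

VALID_DAY_MIN = 480          # >= 8 hours of wear makes a valid day
MIN_VALID_DAYS_PER_WEEK = 4  # inclusion needs >= 4/7 in both weeks


class Intensity(str, enum.Enum):
    STATIONARY = "STATIONARY"
    LIGHT = "LIGHT"
    MVPA = "MVPA"


@dataclass(frozen=True)
class IntensityCutpoints:
    """Counts-per-minute thresholds separating the three intensity bands."""

    stationary_below: int = 100
    mvpa_at_or_above: int = 1952

    def __post_init__(self) -> None:
        if not (0 < self.stationary_below < self.mvpa_at_or_above):
            raise ConfigError(
                f"need 0 < stationary_below ({self.stationary_below}) < "
                f"mvpa_at_or_above ({self.mvpa_at_or_above})"
            )


def classify_intensity(counts_value: float, cuts: IntensityCutpoints = IntensityCutpoints()) -> Intensity:
    """Band a single counts-per-minute value."""
    if counts_value < 0:
        raise DomainError(f"negative counts {counts_value}")
    if counts_value < cuts.stationary_below:
        return Intensity.STATIONARY
    if counts_value >= cuts.mvpa_at_or_above:
        return Intensity.MVPA
    return Intensity.LIGHT


@dataclass
class WearFlagSeries:
    """Per-epoch wear verdicts plus the counts they were derived from."""

    counts: CountsEpochSeries
    worn: np.ndarray  # bool, aligned to counts.frame.index

    def wear_min_by_day(self) -> pd.Series:
        epm = self.counts.epoch_length / timedelta(minutes=1)
        s = pd.Series(self.worn.astype(float) * epm, index=self.counts.frame.index)
        return s.groupby(s.index.date).sum()


def detect_nonwear(counts: CountsEpochSeries, window: timedelta = timedelta(minutes=60)) -> WearFlagSeries:
    """Flag non-wear with the consecutive-zero-count rule.

    Any run of zero-count epochs spanning at least ``window`` is not worn;
    every other epoch is worn.  Idempotent by construction, and a longer
    window can only flag fewer epochs.
    """
    if window < counts.epoch_length:
        raise ConfigError(f"non-wear window {window} shorter than epoch length {counts.epoch_length}")
    n_required = int(window / counts.epoch_length)
    zero = (counts.frame["counts"].to_numpy() == 0)
    worn = np.ones(len(zero), dtype=bool)
    if len(zero) == 0:
        return WearFlagSeries(counts, worn)
    # run-length encode the zero mask
    change = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(zero)]))
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= n_required:
            worn[s:e] = False
    return WearFlagSeries(counts, worn)


@dataclass(frozen=True)
class ValidDay:
    """Day-level wear verdict and activity summary.

    Percentages are of worn time and are ``None`` on zero-wear days; when
    present they sum to 100 up to rounding.
    """

    date: date
    day_index: int | None
    wear_min: float
    valid: bool
    steps: int
    pct_stationary: float | None
    pct_light: float | None
    pct_mvpa: float | None

    def to_record(self) -> dict:
        return {
            "date": self.date.isoformat(),
            "day_index": -1 if self.day_index is None else self.day_index,
            "wear_min": self.wear_min,
            "valid": self.valid,
            "steps": self.steps,
            "pct_stationary": np.nan if self.pct_stationary is None else self.pct_stationary,
            "pct_light": np.nan if self.pct_light is None else self.pct_light,
            "pct_mvpa": np.nan if self.pct_mvpa is None else self.pct_mvpa,
        }


def validate_days(
    flags: WearFlagSeries,
    cuts: IntensityCutpoints = IntensityCutpoints(),
) -> list[ValidDay]:
    """Apply the >= 480 worn-minute valid-day rule and summarise each day.

    Intensity percentages and steps are computed over worn epochs only.
    """
    counts = flags.counts
    f = counts.frame
    epm = counts.epoch_length / timedelta(minutes=1)
    vals = f["counts"].to_numpy()
    steps = f["steps"].to_numpy()
    worn = flags.worn
    days: list[ValidDay] = []
    day_labels = np.asarray(f.index.date)
    for day in pd.unique(day_labels):
        m = day_labels == day
        w = worn & m
        wear_min = float(w.sum() * epm)
        day_steps = int(steps[w].sum())
        if w.any():
            v = vals[w]
            n = len(v)
            stationary = float((v < cuts.stationary_below).sum()) / n * 100.0
            mvpa = float((v >= cuts.mvpa_at_or_above).sum()) / n * 100.0
            light = 100.0 - stationary - mvpa
            pcts = (round(stationary, 2), round(light, 2), round(mvpa, 2))
        else:
            pcts = (None, None, None)
        day_index = None
        if counts.discharge_date is not None:
            day_index = (day - counts.discharge_date).days
        days.append(
            ValidDay(
                date=day,
                day_index=day_index,
                wear_min=wear_min,
                valid=wear_min >= VALID_DAY_MIN,
                steps=day_steps,
                pct_stationary=pcts[0],
                pct_light=pcts[1],
                pct_mvpa=pcts[2],
            )
        )
    return days


def patient_inclusion(valid_days: list[ValidDay]) -> dict:
    """Apply the >=4-valid-days-in-both-weeks inclusion rule.

    Week 1 is study days 1-7, week 2 days 8-14; day indices outside 1-14
    are a domain error.
    """
    week1 = week2 = 0
    for d in valid_days:
        if d.day_index is None or not (1 <= d.day_index <= 14):
            raise DomainError(f"day index {d.day_index} outside 1-14 ({d.date})")
        if d.valid:
            if d.day_index <= 7:
                week1 += 1
            else:
                week2 += 1
    return {
        "week1_valid_days": week1,
        "week2_valid_days": week2,
        "included": week1 >= MIN_VALID_DAYS_PER_WEEK and week2 >= MIN_VALID_DAYS_PER_WEEK,
    }


def cohort_daily_profile(patients_days: dict[str, list[ValidDay]]) -> pd.DataFrame:
    """Per-day-index cohort means over patients with a valid day at that index.

    Expects only included patients; returns a frame indexed by day index with
    mean steps, mean intensity percentages, and the number of contributing
    patients per day.  Empty input yields an empty frame.
    """
    records = []
    for pid, days in patients_days.items():
        for d in days:
            if d.valid and d.day_index is not None:
                records.append(
                    {
                        "patient_id": pid,
                        "day_index": d.day_index,
                        "steps": d.steps,
                        "pct_stationary": d.pct_stationary,
                        "pct_light": d.pct_light,
                        "pct_mvpa": d.pct_mvpa,
                    }
                )
    cols = ["day_index", "mean_steps", "mean_pct_stationary", "mean_pct_light", "mean_pct_mvpa", "n"]
    if not records:
        return pd.DataFrame(columns=cols).set_index("day_index")
    frame = pd.DataFrame.from_records(records)
    grouped = frame.groupby("day_index")
    out = pd.DataFrame(
        {
            "mean_steps": grouped["steps"].mean(),
            "mean_pct_stationary": grouped["pct_stationary"].mean(),
            "mean_pct_light": grouped["pct_light"].mean(),
            "mean_pct_mvpa": grouped["pct_mvpa"].mean(),
            "n": grouped["patient_id"].nunique(),
        }
    )
    return out
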