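"""Vibration-prompt detection from consecutive sedentary time.

The device vibrates once the wearer has been continuously sedentary (sitting
or lying, device worn) for the patient-chosen interval.  Detection is a
streaming counter over the epoch grid:

* the counter increments on every worn sedentary epoch;
* it resets to zero on any non-sedentary posture, any non-worn status, at
  midnight, and on prompt emission (the device re-arms after vibrating, so
  unbroken sitting yields prompts exactly one interval apart);
* a prompt is stamped the instant the counter reaches the interval, i.e. at
  the *end* of the interval-th sedentary epoch.

``detect_prompts_oracle`` is an independent quadratic-time re-scan used only
as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .data_model import (
    AlignmentError,
    ConfigError,
    PostureEpochSeries,
    PromptSetting,
)

__all__ = ["PromptEvent", "detect_prompts", "detect_prompts_oracle", "unanswered_runs", "UnansweredRun"]


@dataclass(frozen=True)
class PromptEvent:
    """A detected vibration prompt.

    ``timestamp`` marks the end of the qualifying sedentary window; the
    ``interval_used`` minutes strictly before it are all worn-sedentary and
    contain no other prompt.  ``day_index`` counts study days with discharge
    as day 0 (None when the series has no discharge date).
    """

    timestamp: datetime
    preceding_bout_start: datetime
    interval_used: PromptSetting
    day_index: int | None = None

    def to_record(self) -> dict:
        return {
            "timestamp": pd.Timestamp(self.timestamp),
            "preceding_bout_start": pd.Timestamp(self.preceding_bout_start),
            "interval_min": self.interval_used.minutes,
            "day_index": -1 if self.day_index is None else self.day_index,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "PromptEvent":
        day = int(rec["day_index"])
        return cls(
            pd.Timestamp(rec["timestamp"]).to_pydatetime(),
            pd.Timestamp(rec["preceding_bout_start"]).to_pydatetime(),
            PromptSetting(int(rec["interval_min"])),
            None if day == -1 else day,
        )


def _epochs_per_interval(series: PostureEpochSeries, setting: PromptSetting) -> int:
    n, rem = divmod(setting.interval, series.epoch_length)
    if rem or n < 1:
        raise ConfigError(
            f"prompt interval {setting.minutes} min is not a positive multiple of the "
            f"epoch length {series.epoch_length}"
        )
    return int(n)


def _make_event(
    series: PostureEpochSeries, ts: pd.Timestamp, setting: PromptSetting
) -> PromptEvent:
    prompt_ts = ts + series.epoch_length
    day = None
    if series.discharge_date is not None:
        day = series.day_index(ts)
    return PromptEvent(
        prompt_ts.to_pydatetime(),
        (prompt_ts - setting.interval).to_pydatetime(),
        setting,
        day,
    )


def detect_prompts(series: PostureEpochSeries, setting: PromptSetting) -> list[PromptEvent]:
    """Detect vibration prompts in a posture series.

    Returns prompts in temporal order.  The counter does not persist across
    calendar days and is suppressed whenever the device is not worn.
    """
    n_required = _epochs_per_interval(series, setting)
    sed = series.is_sedentary
    index = series.timestamps
    events: list[PromptEvent] = []
    counter = 0
    prev_date = None
    for i in range(len(index)):
        ts = index[i]
        if prev_date is not None and ts.date() != prev_date:
            counter = 0
        prev_date = ts.date()
        if sed[i]:
            counter += 1
            if counter == n_required:
                events.append(_make_event(series, ts, setting))
                counter = 0
        else:
            counter = 0
    return events


def detect_prompts_oracle(series: PostureEpochSeries, setting: PromptSetting) -> list[PromptEvent]:
    """Quadratic-time re-scan oracle for :func:`detect_prompts`.

    For every epoch, checks exhaustively whether the trailing window of one
    interval is entirely worn-sedentary, within one calendar day, and free of
    already-emitted prompts.  Intentionally naive; used only in tests.
    """
    n_required = _epochs_per_interval(series, setting)
    sed = series.is_sedentary
    index = series.timestamps
    events: list[PromptEvent] = []
    emitted_ends: set[pd.Timestamp] = set()
    for i in range(len(index)):
        start = i - n_required + 1
        if start < 0:
            continue
        window_ok = all(sed[j] for j in range(start, i + 1))
        if not window_ok:
            continue
        if index[start].date() != index[i].date():
            continue
        # a prompt emitted strictly inside the trailing window blocks this one
        window_times = {index[j] for j in range(start, i + 1)}
        if window_times & emitted_ends:
            continue
        events.append(_make_event(series, index[i], setting))
        # record the epoch timestamps consumed by this prompt
        emitted_ends.add(index[i])
    return events


@dataclass(frozen=True)
class UnansweredRun:
    """A maximal run of consecutive prompts with no behavioural response."""

    length: int
    start: datetime
    end: datetime


def unanswered_runs(prompts, classifications) -> list[UnansweredRun]:
    """Maximal consecutive runs of non-responded prompts, in temporal order.

    ``classifications`` must align 1:1 with ``prompts``; each must expose a
    boolean ``responded`` attribute.
    """
    prompts = list(prompts)
    classifications = list(classifications)
    if len(prompts) != len(classifications):
        raise AlignmentError(
            f"{len(prompts)} prompts but {len(classifications)} classifications"
        )
    runs: list[UnansweredRun] = []
    run_start: int | None = None
    for i, (p, c) in enumerate(zip(prompts, classifications)):
        if not c.responded:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            runs.append(
                UnansweredRun(i - run_start, prompts[run_start].timestamp, prompts[i - 1].timestamp)
            )
            run_start = None
    if run_start is not None:
        runs.append(
            UnansweredRun(
                len(prompts) - run_start,
                prompts[run_start].timestamp,
                prompts[-1].timestamp,
            )
        )
    return runs
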