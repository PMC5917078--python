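"""Post-prompt behavioural adjudication and prompt-outcome summaries.

Each prompt opens a 15-minute analysis window.  A *response* is any worn
epoch spent standing or stepping inside that window; the window is truncated
at the next prompt and at the first non-worn epoch.  Latency is the ordinal
position (in minutes) of the first active epoch after the prompt, so an
immediate stand has latency 1 and latencies live in (0, 15].  Behavioural
magnitudes — minutes standing, minutes walking, steps — are accumulated over
the first 5 minutes only, the frame in which the trial reported them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .data_model import (
    ACTIVE_POSTURES,
    DeviceStatus,
    DomainError,
    ManifestError,
    PatientManifestEntry,
    Posture,
    PostureEpochSeries,
)
from .prompts import PromptEvent

__all__ = [
    "ResponseClassification",
    "PromptSummary",
    "classify_response",
    "classify_all",
    "summarize_prompts",
    "stratify_by_setting",
    "round_half_up",
]

RESPONSE_WINDOW_MIN = 15
MAGNITUDE_WINDOW_MIN = 5


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of the trial's
    reported percentages, e.g. 106/325 -> 32.62)."""
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class ResponseClassification:
    """Adjudication of one prompt's 15-minute window."""

    prompt: PromptEvent
    responded: bool
    latency_min: float | None
    within_5min: bool
    stand_min: float
    walk_min: float
    steps: int
    window_truncated: bool
    #: worn epochs actually observed in the (truncated) window; 0 means the
    #: prompt's window was pure non-wear and its non-response is an artefact.
    window_worn_epochs: int = 0

    def __post_init__(self) -> None:
        if self.within_5min and not self.responded:
            raise DomainError("within_5min implies responded")
        if self.responded and not (0 < self.latency_min <= RESPONSE_WINDOW_MIN):
            raise DomainError(f"latency {self.latency_min} outside (0, {RESPONSE_WINDOW_MIN}]")
        if self.stand_min + self.walk_min > MAGNITUDE_WINDOW_MIN + 1e-9:
            raise DomainError("stand + walk minutes exceed the 5-min magnitude window")

    def to_record(self) -> dict:
        rec = self.prompt.to_record()
        rec.update(
            responded=self.responded,
            latency_min=float("nan") if self.latency_min is None else float(self.latency_min),
            within_5min=self.within_5min,
            stand_min=float(self.stand_min),
            walk_min=float(self.walk_min),
            steps=int(self.steps),
            window_truncated=self.window_truncated,
            window_worn_epochs=int(self.window_worn_epochs),
        )
        return rec


def classify_response(
    series: PostureEpochSeries,
    prompt: PromptEvent,
    next_prompt: PromptEvent | None = None,
) -> ResponseClassification:
    """Adjudicate a single prompt on the series it was detected on.

    The analysis window covers the 15 epochs starting at the prompt timestamp,
    truncated at ``next_prompt`` and at the first non-worn epoch (a body-worn
    vibrator cannot elicit observable behaviour once the device is off the
    body).  A window cut short by any of these sets ``window_truncated``.
    """
    f = series.frame
    idx = f.index
    prompt_ts = pd.Timestamp(prompt.timestamp)
    if not (idx[0] <= prompt_ts <= idx[-1] + series.epoch_length):
        raise DomainError(
            f"prompt at {prompt_ts} outside series span {idx[0]}..{idx[-1]}"
        )
    epm = series.epoch_length / timedelta(minutes=1)  # minutes per epoch
    n_window = int(RESPONSE_WINDOW_MIN / epm)
    n_mag = int(MAGNITUDE_WINDOW_MIN / epm)

    start = idx.searchsorted(prompt_ts, side="left")
    end = min(start + n_window, len(idx))
    truncated = end < start + n_window  # series itself ran out
    if next_prompt is not None:
        next_ts = pd.Timestamp(next_prompt.timestamp)
        cut = idx.searchsorted(next_ts, side="left")
        if cut < end:
            end = cut
            truncated = True

    postures = f["posture"].to_numpy()
    statuses = f["device_status"].to_numpy()
    steps_arr = f["steps"].to_numpy()
    active_tokens = {p.value for p in ACTIVE_POSTURES}

    responded = False
    latency: float | None = None
    stand_min = 0.0
    walk_min = 0.0
    steps = 0
    worn_epochs = 0
    for offset, i in enumerate(range(start, end)):
        if statuses[i] != DeviceStatus.WORN.value:
            truncated = True
            break
        worn_epochs += 1
        active = postures[i] in active_tokens
        if active and not responded:
            responded = True
            latency = (offset + 1) * epm
        if offset < n_mag:
            if postures[i] == Posture.STANDING.value:
                stand_min += epm
            elif postures[i] == Posture.STEPPING.value:
                walk_min += epm
                steps += int(steps_arr[i])
    within5 = responded and latency is not None and latency <= MAGNITUDE_WINDOW_MIN
    return ResponseClassification(
        prompt=prompt,
        responded=responded,
        latency_min=latency,
        within_5min=within5,
        stand_min=stand_min,
        walk_min=walk_min,
        steps=steps,
        window_truncated=truncated,
        window_worn_epochs=worn_epochs,
    )


def classify_all(series: PostureEpochSeries, prompts: list[PromptEvent]) -> list[ResponseClassification]:
    """Classify every prompt, passing each its successor for truncation."""
    out = []
    for i, p in enumerate(prompts):
        nxt = prompts[i + 1] if i + 1 < len(prompts) else None
        out.append(classify_response(series, p, nxt))
    return out


@dataclass(frozen=True)
class PromptSummary:
    """Cohort- or patient-level prompt outcome statistics.

    Rates are percentages in [0, 100], reported to 2 decimals with ties away
    from zero; all are ``None`` when ``n_prompts`` is 0 (never a division by
    zero).  Magnitude means/SDs are over within-5-minute responses only.
    """

    n_prompts: int
    n_responded: int
    n_within5: int
    n_days_observed: int
    n_days_with_prompt: int
    response_rate_pct: float | None
    pct_nonresponse: float | None
    pct_within5_of_responses: float | None
    prompts_per_day: float
    pct_days_with_any_prompt: float
    mean_stand_min: float | None
    sd_stand_min: float | None
    mean_walk_min: float | None
    sd_walk_min: float | None
    mean_steps: float | None
    sd_steps: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd


def summarize_prompts(
    classifications: list[ResponseClassification],
    n_days_observed: int,
    *,
    exclude_nonwear_windows: bool = False,
) -> PromptSummary:
    """Summarise prompt outcomes over an observation period.

    ``exclude_nonwear_windows`` drops prompts whose window contained no worn
    epoch at all (non-response purely by truncation) from the denominator;
    the default keeps them, matching a conservative intention-to-treat read.
    """
    if n_days_observed <= 0:
        raise DomainError(f"n_days_observed must be positive, got {n_days_observed}")
    kept = list(classifications)
    if exclude_nonwear_windows:
        kept = [c for c in kept if c.window_worn_epochs > 0]
    n = len(kept)
    n_resp = sum(c.responded for c in kept)
    n_w5 = sum(c.within_5min for c in kept)
    days_prompted = len({pd.Timestamp(c.prompt.timestamp).date() for c in kept})
    w5 = [c for c in kept if c.within_5min]
    mean_stand, sd_stand = _mean_sd([c.stand_min for c in w5])
    mean_walk, sd_walk = _mean_sd([c.walk_min for c in w5])
    mean_steps, sd_steps = _mean_sd([float(c.steps) for c in w5])
    return PromptSummary(
        n_prompts=n,
        n_responded=n_resp,
        n_within5=n_w5,
        n_days_observed=n_days_observed,
        n_days_with_prompt=days_prompted,
        response_rate_pct=None if n == 0 else round_half_up(100.0 * n_resp / n),
        pct_nonresponse=None if n == 0 else round_half_up(100.0 * (n - n_resp) / n),
        pct_within5_of_responses=None if n_resp == 0 else round_half_up(100.0 * n_w5 / n_resp),
        prompts_per_day=round_half_up(n / n_days_observed),
        pct_days_with_any_prompt=round_half_up(100.0 * days_prompted / n_days_observed),
        mean_stand_min=mean_stand,
        sd_stand_min=sd_stand,
        mean_walk_min=mean_walk,
        sd_walk_min=sd_walk,
        mean_steps=mean_steps,
        sd_steps=sd_steps,
    )


def stratify_by_setting(
    per_patient: dict[str, PromptSummary],
    manifest: list[PatientManifestEntry],
) -> pd.DataFrame:
    """Pool per-patient summaries by prompt-interval setting.

    Returns a frame keyed by interval minutes with pooled prompts/day, % of
    observed days with any prompt, % non-response (of prompts) and % of
    prompts answered within 5 minutes — the framing in which the trial
    compared its 30- and 60-minute choosers.
    """
    by_id = {e.patient_id: e for e in manifest}
    rows: dict[int, dict[str, float]] = {}
    for pid, summary in per_patient.items():
        entry = by_id.get(pid)
        if entry is None:
            raise ManifestError(f"patient {pid!r} not in manifest")
        if entry.prompt_setting is None:
            raise ManifestError(f"patient {pid!r} has no prompt setting (group {entry.group.value})")
        key = entry.prompt_setting.minutes
        agg = rows.setdefault(
            key,
            {"n_patients": 0, "n_prompts": 0, "n_responded": 0, "n_within5": 0,
             "n_days": 0, "n_days_prompted": 0},
        )
        agg["n_patients"] += 1
        agg["n_prompts"] += summary.n_prompts
        agg["n_responded"] += summary.n_responded
        agg["n_within5"] += summary.n_within5
        agg["n_days"] += summary.n_days_observed
        agg["n_days_prompted"] += summary.n_days_with_prompt
    records = []
    for key in sorted(rows):
        agg = rows[key]
        n, nr = agg["n_prompts"], agg["n_responded"]
        records.append(
            {
                "setting_min": key,
                "n_patients": int(agg["n_patients"]),
                "n_prompts": int(n),
                "prompts_per_day": round_half_up(n / agg["n_days"]) if agg["n_days"] else None,
                "pct_days_prompted": round_half_up(100.0 * agg["n_days_prompted"] / agg["n_days"])
                if agg["n_days"]
                else None,
                "pct_nonresponse": round_half_up(100.0 * (n - nr) / n) if n else None,
                "pct_within5_of_prompts": round_half_up(100.0 * agg["n_within5"] / n) if n else None,
            }
        )
    return pd.DataFrame.from_records(records, columns=[
        "setting_min", "n_patients", "n_prompts", "prompts_per_day",
        "pct_days_prompted", "pct_nonresponse", "pct_within5_of_prompts",
    ]).set_index("setting_min")
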