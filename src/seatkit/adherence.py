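"""Device wear-day counting, charging compliance, and missing-data attribution.

A 14-day monitoring period has 13 overnight charging opportunities (night of
day d to day d+1, d = 1..13); one charge in every window is 100% compliance.
The device logs charging itself, so a window counts as compliant when it
contains at least one CHARGING epoch.  Days with no worn epoch are attributed
to a manual switch-off, a dead battery, or plain non-wear by majority status.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .data_model import DeviceStatus, DomainError, PostureEpochSeries
from .responses import round_half_up

__all__ = [
    "DayAttribution",
    "AdherenceReport",
    "charging_compliance",
    "attribute_missing",
    "adherence_report",
    "OVERNIGHT_START",
    "OVERNIGHT_END",
]

#: Overnight charging window bounds: 18:00 of day d to 12:00 of day d+1.
OVERNIGHT_START = time(18, 0)
OVERNIGHT_END = time(12, 0)


class DayAttribution(str, enum.Enum):
    WORN = "WORN"
    SWITCHED_OFF = "SWITCHED_OFF"
    BATTERY_DEAD = "BATTERY_DEAD"
    NOT_WORN = "NOT_WORN"


@dataclass(frozen=True)
class AdherenceReport:
    """Day-level adherence summary for one patient-period."""

    patient_id: str
    days_worn: int
    charging_days: int
    n_windows: int
    charging_compliance_pct: float
    attribution: dict[date, DayAttribution]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "days_worn": self.days_worn,
            "charging_days": self.charging_days,
            "n_windows": self.n_windows,
            "charging_compliance_pct": self.charging_compliance_pct,
            "attribution": {d.isoformat(): a.value for d, a in sorted(self.attribution.items())},
        }


def charging_compliance(
    series: PostureEpochSeries,
    *,
    overnight_start: time = OVERNIGHT_START,
    overnight_end: time = OVERNIGHT_END,
) -> dict:
    """Count overnight windows containing a charge.

    Full compliance over 14 days is 13 windows with >= 1 CHARGING epoch each.
    A series covering fewer days triggers a partial-period warning and a
    pro-rated denominator (windows that fit in the observed span).
    """
    dates = series.dates()
    if not dates:
        raise DomainError(f"{series.patient_id}: empty series")
    n_days = (dates[-1] - dates[0]).days + 1
    n_windows = max(n_days - 1, 0)
    if n_days < 14:
        warnings.warn(
            f"{series.patient_id}: series covers {n_days} days (<14); charging "
            f"compliance pro-rated over {n_windows} overnight windows",
            stacklevel=2,
        )
    charging_ts = series.frame.index[
        series.frame["device_status"].to_numpy() == DeviceStatus.CHARGING.value
    ]
    charged = 0
    first = dates[0]
    for w in range(n_windows):
        day_d = first + timedelta(days=w)
        start = datetime.combine(day_d, overnight_start)
        end = datetime.combine(day_d + timedelta(days=1), overnight_end)
        if ((charging_ts >= start) & (charging_ts < end)).any():
            charged += 1
    pct = round_half_up(100.0 * charged / n_windows) if n_windows else 0.0
    return {"charging_days": charged, "n_windows": n_windows, "compliance_pct": pct}


def attribute_missing(series: PostureEpochSeries) -> dict[date, DayAttribution]:
    """Label every calendar day of the series.

    A day with any worn epoch is WORN.  A day with none is SWITCHED_OFF if
    OFF epochs outnumber BATTERY_DEAD ones, BATTERY_DEAD if the reverse (ties
    go to BATTERY_DEAD — conservative toward device fault), and NOT_WORN when
    neither status appears enough to dominate.
    """
    f = series.frame
    status = f["device_status"]
    day_labels = np.asarray(f.index.date)
    out: dict[date, DayAttribution] = {}
    for day in pd.unique(day_labels):
        m = day_labels == day
        s = status[m]
        if (s == DeviceStatus.WORN.value).any():
            out[day] = DayAttribution.WORN
            continue
        n_off = int((s == DeviceStatus.OFF.value).sum())
        n_dead = int((s == DeviceStatus.BATTERY_DEAD.value).sum())
        if n_off == 0 and n_dead == 0:
            out[day] = DayAttribution.NOT_WORN
        elif n_off > n_dead:
            out[day] = DayAttribution.SWITCHED_OFF
        else:
            out[day] = DayAttribution.BATTERY_DEAD
    return out


def adherence_report(series: PostureEpochSeries) -> AdherenceReport:
    """Full adherence summary: days worn, charging compliance, attribution."""
    attribution = attribute_missing(series)
    compliance = charging_compliance(series)
    return AdherenceReport(
        patient_id=series.patient_id,
        days_worn=sum(a is DayAttribution.WORN for a in attribution.values()),
        charging_days=compliance["charging_days"],
        n_windows=compliance["n_windows"],
        charging_compliance_pct=compliance["compliance_pct"],
        attribution=attribution,
    )
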