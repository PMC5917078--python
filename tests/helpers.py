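"""Shared construction helpers for the test suite."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from seatkit import DeviceStatus, Posture, PostureEpochSeries

EPOCH = timedelta(minutes=1)

#: one character per epoch: posture/status shorthand
CHAR_MAP = {
    "S": (Posture.SITTING, DeviceStatus.WORN),
    "L": (Posture.LYING, DeviceStatus.WORN),
    "D": (Posture.STANDING, DeviceStatus.WORN),
    "W": (Posture.STEPPING, DeviceStatus.WORN),
    "N": (Posture.SITTING, DeviceStatus.NOT_WORN),
    "O": (Posture.SITTING, DeviceStatus.OFF),
    "C": (Posture.LYING, DeviceStatus.CHARGING),
    "B": (Posture.SITTING, DeviceStatus.BATTERY_DEAD),
}


def series_from_string(
    pattern: str,
    start: datetime = datetime(2016, 3, 2, 9, 0),
    *,
    steps_per_walk: int = 10,
    patient_id: str = "T001",
    discharge_date: date | None = date(2016, 3, 1),
) -> PostureEpochSeries:
    """Build a 1-min-epoch series from a compact posture string.

    ``S`` sit, ``L`` lie, ``D`` stand, ``W`` step (worn); ``N`` not worn,
    ``O`` off, ``C`` charging, ``B`` battery dead.
    """
    postures, statuses, steps = [], [], []
    for ch in pattern:
        posture, status = CHAR_MAP[ch]
        postures.append(posture.value)
        statuses.append(status.value)
        steps.append(steps_per_walk if ch == "W" else 0)
    frame = pd.DataFrame(
        {"posture": postures, "steps": steps, "device_status": statuses},
        index=pd.date_range(start, periods=len(pattern), freq=EPOCH),
    )
    return PostureEpochSeries(patient_id, frame, EPOCH, discharge_date)


def random_pattern(rng: np.random.Generator, n: int, p_sit: float = 0.6) -> str:
    """Random posture string biased toward sitting, with occasional non-wear."""
    chars = np.array(list("SLDWNOCB"))
    probs = np.array([p_sit, 0.08, 0.12, 0.08, 0.06, 0.02, 0.02, 0.02])
    probs[0] = 1.0 - probs[1:].sum()
    return "".join(rng.choice(chars, size=n, p=probs))
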