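"""Domain types and delimited-text I/O shared by every analysis stage.

The substrate of the pipeline is the *posture epoch*: a fixed-length time bin
(1 min by default) carrying the inclinometer's posture verdict, the steps
accrued in the bin, and the device status.  Epoch series live on a contiguous
timestamp grid; gaps in input files are filled with ``NOT_WORN`` epochs so that
downstream stages can assume a dense grid.

All file formats are plain CSV with ISO-8601 timestamps, one file per patient.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Posture",
    "DeviceStatus",
    "SEDENTARY_POSTURES",
    "ACTIVE_POSTURES",
    "PostureEpoch",
    "PostureEpochSeries",
    "CountsEpoch",
    "CountsEpochSeries",
    "PromptSetting",
    "Group",
    "PatientManifestEntry",
    "FlowLog",
    "SeatkitError",
    "ParseError",
    "ConfigError",
    "DomainError",
    "AlignmentError",
    "ManifestError",
    "FunnelError",
    "SerializationError",
    "read_posture_series",
    "write_posture_series",
    "read_counts_series",
    "write_counts_series",
    "read_manifest",
    "write_manifest",
    "read_flow_log",
    "write_events",
    "read_events",
    "count_sit_to_stand",
]

EPOCH_60S = timedelta(seconds=60)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class SeatkitError(Exception):
    """Base class for all seatkit errors."""


class ParseError(SeatkitError):
    """Malformed input file; the message names the offending line."""


class ConfigError(SeatkitError):
    """Invalid configuration value."""


class DomainError(SeatkitError):
    """Input outside the operation's domain (bad score, bad day index, ...)."""


class AlignmentError(SeatkitError):
    """Two sequences that must be aligned 1:1 are not."""


class ManifestError(SeatkitError):
    """A patient referenced in an analysis is missing from the manifest."""


class FunnelError(SeatkitError):
    """A trial-flow record violates the screening funnel invariant."""


class SerializationError(SeatkitError):
    """Event records cannot be written as flat delimited text."""


# ---------------------------------------------------------------------------
# enums and atomic types
# ---------------------------------------------------------------------------

class Posture(str, enum.Enum):
    SITTING = "SITTING"
    LYING = "LYING"
    STANDING = "STANDING"
    STEPPING = "STEPPING"


class DeviceStatus(str, enum.Enum):
    WORN = "WORN"
    NOT_WORN = "NOT_WORN"
    OFF = "OFF"
    CHARGING = "CHARGING"
    BATTERY_DEAD = "BATTERY_DEAD"


#: Postures counted as sedentary: sitting or reclining/lying.  Standing breaks
#: sedentary time even without steps.
SEDENTARY_POSTURES = frozenset({Posture.SITTING, Posture.LYING})

#: Postures that count as a behavioural response to a prompt.
ACTIVE_POSTURES = frozenset({Posture.STANDING, Posture.STEPPING})


class Group(str, enum.Enum):
    CONTROL = "CONTROL"
    EDUCATION = "EDUCATION"
    EDUCATION_FEEDBACK = "EDUCATION_FEEDBACK"


@dataclass(frozen=True)
class PromptSetting:
    """Patient-chosen consecutive-sedentary interval that triggers a vibration.

    The trial offered presets of 30, 45 and 60 minutes; any interval of at
    least one minute is accepted so sensitivity analyses can vary it.
    """

    minutes: int

    PRESETS = (30, 45, 60)

    def __post_init__(self) -> None:
        if int(self.minutes) != self.minutes or self.minutes < 1:
            raise ConfigError(f"prompt interval must be a whole number of minutes >= 1, got {self.minutes!r}")
        object.__setattr__(self, "minutes", int(self.minutes))

    @property
    def interval(self) -> timedelta:
        return timedelta(minutes=self.minutes)


@dataclass(frozen=True)
class PostureEpoch:
    """One fixed-length bin of inclinometer output."""

    timestamp: datetime
    posture: Posture
    steps: int
    device_status: DeviceStatus

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise DomainError(f"steps must be non-negative, got {self.steps}")
        if self.steps > 0 and self.posture is not Posture.STEPPING:
            raise DomainError(
                f"steps={self.steps} on a {self.posture.value} epoch at {self.timestamp}; "
                "steps may only accrue while STEPPING"
            )


@dataclass(frozen=True)
class CountsEpoch:
    """One accelerometer epoch: vertical-axis activity counts plus steps."""

    timestamp: datetime
    counts: int
    steps: int = 0

    def __post_init__(self) -> None:
        if self.counts < 0 or self.steps < 0:
            raise DomainError("counts and steps must be non-negative")


# ---------------------------------------------------------------------------
# epoch series containers
# ---------------------------------------------------------------------------

_POSTURE_COLS = ["posture", "steps", "device_status"]


def _check_grid(index: pd.DatetimeIndex, epoch_length: timedelta, what: str) -> None:
    if len(index) > 1:
        deltas = np.diff(index.values)
        step = np.timedelta64(epoch_length)
        if not (deltas == step).all():
            bad = int(np.argmax(deltas != step))
            raise DomainError(
                f"{what}: timestamps not on a contiguous {epoch_length} grid near "
                f"{index[bad]} -> {index[bad + 1]}"
            )


@dataclass
class PostureEpochSeries:
    """A patient-period of posture epochs on a contiguous grid.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    frame : pandas.DataFrame
        Indexed by epoch start timestamp, with columns ``posture``, ``steps``
        and ``device_status`` (string tokens matching the enums).
    epoch_length : timedelta
        Grid resolution, default 60 s.
    discharge_date : date, optional
        Hospital discharge date (study day 0).  Day index of an epoch is
        ``epoch date - discharge_date``; the monitored period is days 1-14.
    """

    patient_id: str
    frame: pd.DataFrame
    epoch_length: timedelta = EPOCH_60S
    discharge_date: date | None = None

    def __post_init__(self) -> None:
        self.frame = self.frame[_POSTURE_COLS].copy()
        self.frame.index = pd.DatetimeIndex(self.frame.index, name="timestamp")
        self.frame["steps"] = self.frame["steps"].astype(np.int64)
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_epochs(
        cls,
        patient_id: str,
        epochs: Sequence[PostureEpoch],
        epoch_length: timedelta = EPOCH_60S,
        discharge_date: date | None = None,
    ) -> "PostureEpochSeries":
        frame = pd.DataFrame(
            {
                "posture": [e.posture.value for e in epochs],
                "steps": [e.steps for e in epochs],
                "device_status": [e.device_status.value for e in epochs],
            },
            index=pd.DatetimeIndex([e.timestamp for e in epochs], name="timestamp"),
        )
        return cls(patient_id, frame, epoch_length, discharge_date)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        f = self.frame
        if not f.index.is_monotonic_increasing or f.index.has_duplicates:
            raise DomainError(f"{self.patient_id}: timestamps must be strictly increasing")
        _check_grid(f.index, self.epoch_length, self.patient_id)
        bad_posture = ~f["posture"].isin([p.value for p in Posture])
        if bad_posture.any():
            tok = f.loc[bad_posture, "posture"].iloc[0]
            raise DomainError(f"{self.patient_id}: unknown posture token {tok!r}")
        bad_status = ~f["device_status"].isin([s.value for s in DeviceStatus])
        if bad_status.any():
            tok = f.loc[bad_status, "device_status"].iloc[0]
            raise DomainError(f"{self.patient_id}: unknown device status token {tok!r}")
        if (f["steps"] < 0).any():
            raise DomainError(f"{self.patient_id}: negative step counts")
        stray = (f["steps"] > 0) & (f["posture"] != Posture.STEPPING.value)
        if stray.any():
            ts = f.index[stray][0]
            raise DomainError(
                f"{self.patient_id}: steps>0 on a non-STEPPING epoch at {ts}"
            )

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PostureEpochSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.epoch_length == other.epoch_length
            and self.discharge_date == other.discharge_date
            and self.frame.equals(other.frame)
        )

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def is_worn(self) -> np.ndarray:
        return (self.frame["device_status"] == DeviceStatus.WORN.value).to_numpy()

    @property
    def is_sedentary(self) -> np.ndarray:
        """Worn AND in a sitting/lying posture."""
        sed = self.frame["posture"].isin([p.value for p in SEDENTARY_POSTURES]).to_numpy()
        return sed & self.is_worn

    @property
    def is_active(self) -> np.ndarray:
        """Worn AND standing or stepping."""
        act = self.frame["posture"].isin([p.value for p in ACTIVE_POSTURES]).to_numpy()
        return act & self.is_worn

    def epochs(self) -> Iterator[PostureEpoch]:
        for ts, row in self.frame.iterrows():
            yield PostureEpoch(
                ts.to_pydatetime(),
                Posture(row["posture"]),
                int(row["steps"]),
                DeviceStatus(row["device_status"]),
            )

    def day_index(self, ts: datetime | pd.Timestamp) -> int:
        """Study day of a timestamp (discharge date = day 0)."""
        if self.discharge_date is None:
            raise DomainError(f"{self.patient_id}: no discharge date set")
        return (pd.Timestamp(ts).date() - self.discharge_date).days

    def dates(self) -> list[date]:
        return sorted({ts.date() for ts in self.frame.index})


@dataclass
class CountsEpochSeries:
    """Accelerometer activity-count series on a contiguous grid."""

    patient_id: str
    frame: pd.DataFrame  # index timestamp; columns counts, steps
    epoch_length: timedelta = EPOCH_60S
    discharge_date: date | None = None

    def __post_init__(self) -> None:
        self.frame = self.frame[["counts", "steps"]].copy()
        self.frame.index = pd.DatetimeIndex(self.frame.index, name="timestamp")
        self.frame = self.frame.astype(np.int64)
        if not self.frame.index.is_monotonic_increasing or self.frame.index.has_duplicates:
            raise DomainError(f"{self.patient_id}: timestamps must be strictly increasing")
        _check_grid(self.frame.index, self.epoch_length, self.patient_id)
        if (self.frame.to_numpy() < 0).any():
            raise DomainError(f"{self.patient_id}: counts and steps must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountsEpochSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.epoch_length == other.epoch_length
            and self.frame.equals(other.frame)
        )


# ---------------------------------------------------------------------------
# manifest and flow log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientManifestEntry:
    """One row of the trial manifest.

    ``prompt_setting`` is present exactly when the patient is in the
    feedback arm (the only arm whose device vibrates).
    """

    patient_id: str
    group: Group
    discharge_date: date
    prompt_setting: PromptSetting | None = None

    def __post_init__(self) -> None:
        has_setting = self.prompt_setting is not None
        if has_setting != (self.group is Group.EDUCATION_FEEDBACK):
            raise DomainError(
                f"{self.patient_id}: prompt setting must be present iff the patient "
                f"is in the feedback arm (group={self.group.value})"
            )


_FLOW_FLAGS = ["screened", "eligible", "approached", "consented", "enrolled", "completed_followup"]


@dataclass
class FlowLog:
    """Screening -> consent -> completion records for trial-flow metrics.

    Enforces the funnel invariant: consented implies approached implies
    eligible implies screened, and completed implies enrolled.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.copy()
        for col in _FLOW_FLAGS:
            if col not in f.columns:
                raise DomainError(f"flow log missing column {col!r}")
            f[col] = f[col].astype(bool)
        if "patient_id" not in f.columns:
            raise DomainError("flow log missing column 'patient_id'")
        if "ineligibility_reason" not in f.columns:
            f["ineligibility_reason"] = ""
        f["ineligibility_reason"] = f["ineligibility_reason"].fillna("").astype(str)
        if "group" not in f.columns:
            f["group"] = ""
        self.frame = f.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        chain = [("consented", "approached"), ("approached", "eligible"),
                 ("eligible", "screened"), ("enrolled", "consented"),
                 ("completed_followup", "enrolled")]
        for narrower, wider in chain:
            bad = f[narrower] & ~f[wider]
            if bad.any():
                pid = f.loc[bad, "patient_id"].iloc[0]
                raise FunnelError(
                    f"record {pid!r}: {narrower}=True but {wider}=False violates the funnel"
                )

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_ts(token: str, path: Path, line_no: int) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(token)
    except (ValueError, TypeError):
        raise ParseError(f"{path}: line {line_no}: malformed timestamp {token!r}") from None
    if ts is pd.NaT:
        raise ParseError(f"{path}: line {line_no}: malformed timestamp {token!r}")
    return ts


def read_posture_series(
    path: str | Path,
    epoch_length: timedelta = EPOCH_60S,
    *,
    patient_id: str | None = None,
    discharge_date: date | None = None,
) -> PostureEpochSeries:
    """Read a posture CSV and return a validated, gap-filled series.

    The file must have header columns ``timestamp,posture,steps,device_status``.
    Gaps in the timestamp grid are filled with ``NOT_WORN`` epochs (posture
    SITTING, steps 0); epochs present in the file are never altered.  Parse
    problems raise :class:`ParseError` naming the offending line (line 1 is
    the header).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"timestamp", "posture", "steps", "device_status"}
    missing = required - set(raw.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    postures = {p.value for p in Posture}
    statuses = {s.value for s in DeviceStatus}
    rows = []
    prev_ts: pd.Timestamp | None = None
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        ts = _parse_ts(row.timestamp, path, line_no)
        if prev_ts is not None and ts <= prev_ts:
            raise ParseError(f"{path}: line {line_no}: non-monotone timestamp {ts}")
        if row.posture not in postures:
            raise ParseError(f"{path}: line {line_no}: unknown posture token {row.posture!r}")
        if row.device_status not in statuses:
            raise ParseError(f"{path}: line {line_no}: unknown device status {row.device_status!r}")
        try:
            steps = int(row.steps)
        except ValueError:
            raise ParseError(f"{path}: line {line_no}: non-integer steps {row.steps!r}") from None
        if steps < 0:
            raise ParseError(f"{path}: line {line_no}: negative steps {steps}")
        if steps > 0 and row.posture != Posture.STEPPING.value:
            raise ParseError(
                f"{path}: line {line_no}: steps={steps} on a {row.posture} epoch"
            )
        if prev_ts is not None:
            gap = (ts - prev_ts).to_pytimedelta()
            n_steps, rem = divmod(gap, epoch_length)
            if rem:
                raise ParseError(
                    f"{path}: line {line_no}: timestamp {ts} is off the {epoch_length} grid"
                )
        rows.append((ts, row.posture, steps, row.device_status))
        prev_ts = ts

    frame = pd.DataFrame(rows, columns=["timestamp", "posture", "steps", "device_status"])
    frame = frame.set_index("timestamp")
    if len(frame):
        full = pd.date_range(frame.index[0], frame.index[-1], freq=epoch_length)
        frame = frame.reindex(full)
        filled = frame["posture"].isna()
        frame.loc[filled, "posture"] = Posture.SITTING.value
        frame.loc[filled, "steps"] = 0
        frame.loc[filled, "device_status"] = DeviceStatus.NOT_WORN.value
    return PostureEpochSeries(
        patient_id or path.stem,
        frame,
        epoch_length,
        discharge_date,
    )


def write_posture_series(series: PostureEpochSeries, path: str | Path) -> Path:
    path = Path(path)
    out = series.frame.copy()
    out.index = out.index.map(lambda t: t.isoformat())
    out.index.name = "timestamp"
    out.to_csv(path)
    return path


def read_counts_series(
    path: str | Path,
    epoch_length: timedelta = EPOCH_60S,
    *,
    patient_id: str | None = None,
    discharge_date: date | None = None,
) -> CountsEpochSeries:
    """Read a counts CSV (``timestamp,counts,steps``); gaps are zero-filled."""
    path = Path(path)
    raw = pd.read_csv(path)
    missing = {"timestamp", "counts"} - set(raw.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "steps" not in raw.columns:
        raw["steps"] = 0
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(raw["timestamp"]))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: malformed timestamp ({exc})") from None
    frame = pd.DataFrame({"counts": raw["counts"].values, "steps": raw["steps"].values}, index=idx)
    if len(frame):
        full = pd.date_range(frame.index[0], frame.index[-1], freq=epoch_length)
        frame = frame.reindex(full, fill_value=0)
    return CountsEpochSeries(patient_id or path.stem, frame, epoch_length, discharge_date)


def write_counts_series(series: CountsEpochSeries, path: str | Path) -> Path:
    path = Path(path)
    out = series.frame.copy()
    out.index = out.index.map(lambda t: t.isoformat())
    out.index.name = "timestamp"
    out.to_csv(path)
    return path


def read_manifest(path: str | Path) -> list[PatientManifestEntry]:
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = i + 2
        try:
            group = Group(row.group)
        except ValueError:
            raise ParseError(f"{path}: line {line_no}: unknown group {row.group!r}") from None
        setting = None
        raw_setting = getattr(row, "prompt_setting_min", "")
        if raw_setting not in ("", "NA"):
            setting = PromptSetting(int(raw_setting))
        discharge = _parse_ts(row.discharge_date, path, line_no).date()
        entries.append(PatientManifestEntry(row.patient_id, group, discharge, setting))
    return entries


def write_manifest(entries: Iterable[PatientManifestEntry], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in entries],
            "group": [e.group.value for e in entries],
            "discharge_date": [e.discharge_date.isoformat() for e in entries],
            "prompt_setting_min": [
                "" if e.prompt_setting is None else e.prompt_setting.minutes for e in entries
            ],
        }
    )
    frame.to_csv(path, index=False)
    return path


def read_flow_log(path: str | Path) -> FlowLog:
    return FlowLog(pd.read_csv(path))


# ---------------------------------------------------------------------------
# generic timestamped-event I/O
# ---------------------------------------------------------------------------

_SCALARS = (str, int, float, bool, np.integer, np.floating, np.bool_)


def write_events(events: Sequence[dict], path: str | Path, *, columns: Sequence[str] | None = None) -> Path:
    """Write timestamped event records as delimited text.

    Each event is a flat mapping of scalar fields; ``datetime``/``date``
    values are serialized as ISO-8601.  An empty list yields a header-only
    file (``columns`` must then be given, or the file has an empty header).
    Fields mixing incompatible types across events raise
    :class:`SerializationError`.
    """
    path = Path(path)
    events = list(events)
    if columns is None:
        columns = list(events[0].keys()) if events else []
    cells: dict[str, list] = {c: [] for c in columns}
    types: dict[str, type] = {}
    for ev in events:
        for c in columns:
            v = ev.get(c)
            if v is None:
                cells[c].append("")
                continue
            if isinstance(v, (datetime, pd.Timestamp)):
                v_out, kind = pd.Timestamp(v).isoformat(), datetime
            elif isinstance(v, date):
                v_out, kind = v.isoformat(), date
            elif isinstance(v, _SCALARS):
                v_out, kind = v, (bool if isinstance(v, (bool, np.bool_)) else type(v))
            else:
                raise SerializationError(f"field {c!r}: non-scalar value {v!r}")
            seen = types.setdefault(c, kind)
            compatible = seen is kind or ({seen, kind} <= {int, float, np.integer, np.floating})
            if not compatible:
                raise SerializationError(
                    f"field {c!r}: mixed types {seen.__name__} and {kind.__name__}"
                )
            cells[c].append(v_out)
    pd.DataFrame(cells, columns=list(columns)).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[dict]:
    """Read a :func:`write_events` file back into a list of dicts.

    Columns that parse fully as ISO-8601 timestamps come back as
    ``pandas.Timestamp``; integers and floats are inferred by pandas.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in frame.columns:
        if frame[col].dtype == object:
            try:
                parsed = pd.to_datetime(frame[col], format="ISO8601")
            except (ValueError, TypeError):
                continue
            frame[col] = parsed
    return frame.to_dict(orient="records")


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def count_sit_to_stand(series: PostureEpochSeries) -> int:
    """Number of sit-to-stand transitions in a series.

    A transition is a WORN epoch in {SITTING, LYING} immediately followed by a
    WORN epoch in {STANDING, STEPPING}.
    """
    sed = series.is_sedentary
    act = series.is_active
    if len(sed) < 2:
        return 0
    return int(np.sum(sed[:-1] & act[1:]))
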