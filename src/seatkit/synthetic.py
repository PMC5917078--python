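"""Synthetic inclinometer/accelerometer cohorts with ground-truth event logs.

The generator emulates the data-generating process of a two-week
post-discharge monitoring period: patient-chosen prompt intervals (30/45/60
min), waking days alternating sedentary bouts and short activity breaks,
probabilistic prompt responses with a latency and a stand-then-walk
magnitude, overnight charging behaviour, battery depletion, and whole-day
manual switch-offs.

Two contracts matter for testability:

* the generator runs the *same* consecutive-sedentary counter as the prompt
  detector, so ground-truth prompt times match detector output exactly on
  clean data;
* every recorded ground-truth event describes what was actually emitted into
  the epoch stream, so the response classifier's verdicts agree with the log
  event-by-event.

Durations are drawn in continuous minutes and rendered onto the 1-min epoch
grid by stochastic rounding (floor + Bernoulli on the fraction), which keeps
the expected rendered duration equal to the drawn one.  Truncated-normal
duration distributions are parametrized by their post-truncation mean, so the
configured mean is the mean of the durations the generator actually draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import (
    ConfigError,
    CountsEpochSeries,
    DeviceStatus,
    Group,
    PatientManifestEntry,
    Posture,
    PostureEpochSeries,
    PromptSetting,
    write_events,
)

__all__ = [
    "SyntheticConfig",
    "TruePrompt",
    "TrueDay",
    "GroundTruthLog",
    "Cohort",
    "generate_cohort",
    "generate_counts",
    "build_concept_day_fixture",
    "truncnorm_with_mean",
]

EPOCH = timedelta(minutes=1)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions.

    ``prompt_interval_mix`` gives the proportion of patients on each preset;
    the default 6:1:5 over 30/45/60 min mirrors the choices of the 12
    feedback-arm patients.  Stand/walk magnitudes default to 1.4 (SD 0.8) and
    0.4 (SD 0.3) min; ``step_rate`` of 53 steps per walking minute puts the
    mean steps per response at about 21.2.  ``p_within5`` places 41% of the
    response-latency mass in the first five minutes.  The battery lasts 2.5
    days between charges.
    """

    n_patients: int = 12
    seed: int = 0
    start_date: date = date(2016, 3, 1)  # discharge date = study day 0
    n_days: int = 14
    prompt_interval_mix: tuple[tuple[int, float], ...] = ((30, 6 / 12), (45, 1 / 12), (60, 5 / 12))
    p_respond: float = 0.33
    p_within5: float = 0.41
    latency_max_min: int = 15
    stand_duration_mean: float = 1.4
    stand_duration_sd: float = 0.8
    walk_duration_mean: float = 0.4
    walk_duration_sd: float = 0.3
    step_rate: float = 53.0
    wake_start: time = time(8, 0)
    wake_end: time = time(22, 30)
    sedentary_fraction: float = 0.75
    mean_active_break_min: float = 5.0
    p_lying_bout: float = 0.1
    p_charge_nightly: float = 0.8
    battery_life_days: float = 2.5
    p_manual_off_day: float = 0.03
    ambulation_cutpoint: int = 1952

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        for p, name in [
            (self.p_respond, "p_respond"),
            (self.p_within5, "p_within5"),
            (self.p_charge_nightly, "p_charge_nightly"),
            (self.p_manual_off_day, "p_manual_off_day"),
            (self.p_lying_bout, "p_lying_bout"),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        mix = dict(self.prompt_interval_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(w < 0 for w in mix.values()):
            raise ConfigError("prompt_interval_mix proportions must be non-negative and sum to 1")
        for m in mix:
            PromptSetting(m)  # validates
            if m <= self.latency_max_min:
                raise ConfigError(
                    f"prompt interval {m} min must exceed the {self.latency_max_min}-min "
                    "response window for unambiguous prompt attribution"
                )
        if not (0.0 < self.sedentary_fraction < 1.0):
            raise ConfigError(
                "sedentary_fraction must be strictly inside (0, 1); a cohort that is "
                "never sedentary cannot be prompted"
            )
        for v, name in [
            (self.stand_duration_mean, "stand_duration_mean"),
            (self.stand_duration_sd, "stand_duration_sd"),
            (self.walk_duration_mean, "walk_duration_mean"),
            (self.walk_duration_sd, "walk_duration_sd"),
            (self.step_rate, "step_rate"),
            (self.mean_active_break_min, "mean_active_break_min"),
            (self.battery_life_days, "battery_life_days"),
        ]:
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.wake_start >= self.wake_end:
            raise ConfigError("wake_start must precede wake_end")

    @property
    def mean_sedentary_bout_min(self) -> float:
        f = self.sedentary_fraction
        return f / (1.0 - f) * self.mean_active_break_min


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruePrompt:
    """One ground-truth prompt as emitted into the epoch stream.

    ``responded`` reflects what actually happened: a drawn response that
    could not be rendered before the day ended is logged as a non-response.
    Magnitudes are the drawn (continuous) behaviour behind the rendered
    epochs; ``latency_min`` is the ordinal minute of the first active epoch.
    """

    patient_id: str
    timestamp: datetime
    responded: bool
    latency_min: int | None
    stand_min: float | None
    walk_min: float | None
    steps: int | None

    def to_record(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timestamp": pd.Timestamp(self.timestamp),
            "responded": self.responded,
            "latency_min": np.nan if self.latency_min is None else self.latency_min,
            "stand_min": np.nan if self.stand_min is None else self.stand_min,
            "walk_min": np.nan if self.walk_min is None else self.walk_min,
            "steps": np.nan if self.steps is None else self.steps,
        }


@dataclass(frozen=True)
class TrueDay:
    patient_id: str
    date: date
    worn: bool
    charged: bool
    battery_dead: bool
    manual_off: bool

    def to_record(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "date": self.date.isoformat(),
            "worn": self.worn,
            "charged": self.charged,
            "battery_dead": self.battery_dead,
            "manual_off": self.manual_off,
        }


@dataclass
class GroundTruthLog:
    prompts: list[TruePrompt] = field(default_factory=list)
    days: list[TrueDay] = field(default_factory=list)

    def prompts_for(self, patient_id: str) -> list[TruePrompt]:
        return [p for p in self.prompts if p.patient_id == patient_id]

    def days_for(self, patient_id: str) -> list[TrueDay]:
        return [d for d in self.days if d.patient_id == patient_id]

    def write(self, prompts_path: str | Path, days_path: str | Path) -> None:
        write_events(
            [p.to_record() for p in self.prompts],
            prompts_path,
            columns=["patient_id", "timestamp", "responded", "latency_min", "stand_min", "walk_min", "steps"],
        )
        write_events(
            [d.to_record() for d in self.days],
            days_path,
            columns=["patient_id", "date", "worn", "charged", "battery_dead", "manual_off"],
        )


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` produces for one synthetic trial."""

    config: SyntheticConfig
    manifest: list[PatientManifestEntry]
    series: dict[str, PostureEpochSeries]
    counts: dict[str, CountsEpochSeries]
    ground_truth: GroundTruthLog


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

def truncnorm_with_mean(target_mean: float, sd: float) -> stats.rv_continuous:
    """Frozen truncated normal on (0, inf) whose mean equals ``target_mean``.

    The latent location is solved so that the post-truncation mean is the
    configured one; the latent scale is ``sd``.
    """
    if target_mean <= 0 or sd <= 0:
        raise ConfigError("truncated-normal mean and sd must be positive")

    def post_trunc_mean(mu: float) -> float:
        a = -mu / sd
        return mu + sd * stats.norm.pdf(a) / stats.norm.sf(a)

    lo = target_mean - 10.0 * sd
    mu = optimize.brentq(lambda m: post_trunc_mean(m) - target_mean, lo, target_mean)
    return stats.truncnorm(a=-mu / sd, b=np.inf, loc=mu, scale=sd)


def _stoch_round(x: float, rng: np.random.Generator) -> int:
    """floor(x) + Bernoulli(frac(x)): integer with expectation exactly x."""
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def _apportion(mix: dict[int, float], n: int) -> list[int]:
    """Largest-remainder apportionment of n patients over interval presets."""
    keys = sorted(mix)
    quotas = {k: mix[k] * n for k in keys}
    alloc = {k: int(np.floor(quotas[k])) for k in keys}
    short = n - sum(alloc.values())
    by_rem = sorted(keys, key=lambda k: (-(quotas[k] - alloc[k]), k))
    for k in by_rem[:short]:
        alloc[k] += 1
    out: list[int] = []
    for k in keys:
        out.extend([k] * alloc[k])
    return out


# ---------------------------------------------------------------------------
# per-patient simulation
# ---------------------------------------------------------------------------

class _PatientSim:
    """Minute-resolution state machine for one patient's 14 days."""

    def __init__(self, pid: str, setting: PromptSetting | None, cfg: SyntheticConfig,
                 rng: np.random.Generator):
        self.pid = pid
        self.setting = setting
        self.cfg = cfg
        self.rng = rng
        self.stand_dist = truncnorm_with_mean(cfg.stand_duration_mean, cfg.stand_duration_sd)
        self.walk_dist = truncnorm_with_mean(cfg.walk_duration_mean, cfg.walk_duration_sd)
        self.prompts: list[TruePrompt] = []
        self.days: list[TrueDay] = []

    # -- behaviour-model state (reset each waking day) --------------------
    def _reset_day(self) -> None:
        self.counter = 0
        self.bout_left = 0
        self.bout_sedentary = True
        self.bout_posture = Posture.SITTING
        self.hold_sed_until = -1          # minute-of-day bound for non-response hold
        self.queue: list[tuple[Posture, int]] = []  # pending injected epochs
        self.pending: dict | None = None  # drawn response awaiting injection

    def _draw_bout(self, sedentary: bool) -> None:
        cfg = self.cfg
        mean = cfg.mean_sedentary_bout_min if sedentary else cfg.mean_active_break_min
        self.bout_left = max(1, _stoch_round(self.rng.exponential(mean), self.rng))
        self.bout_sedentary = sedentary
        if sedentary:
            lying = self.rng.random() < cfg.p_lying_bout
            self.bout_posture = Posture.LYING if lying else Posture.SITTING

    def _draw_response_plan(self, minute_of_day: int) -> None:
        """Decide the fate of a prompt that just fired at ``minute_of_day``."""
        cfg, rng = self.cfg, self.rng
        if rng.random() >= cfg.p_respond:
            # non-response: remain sedentary for the full analysis window
            self.pending = {"responded": False}
            self.hold_sed_until = minute_of_day + cfg.latency_max_min
            return
        if rng.random() < cfg.p_within5:
            latency = int(rng.integers(1, 6))
        else:
            latency = int(rng.integers(6, cfg.latency_max_min + 1))
        stand = float(self.stand_dist.rvs(random_state=rng))
        walk = float(self.walk_dist.rvs(random_state=rng))
        stand_ep = max(1, _stoch_round(stand, rng))  # a response always shows a stand-up
        walk_ep = _stoch_round(walk, rng)
        steps = max(1, int(round(cfg.step_rate * walk)))
        self.pending = {
            "responded": True,
            "latency": latency,
            "stand": stand,
            "walk": walk,
            "steps": steps,
            "stand_ep": stand_ep,
            "walk_ep": walk_ep,
            "countdown": latency - 1,  # sedentary epochs before the stand-up
        }

    def _activate_pending(self) -> None:
        """Move the drawn response into the injection queue."""
        p = self.pending
        assert p is not None and p["responded"]
        queue: list[tuple[Posture, int]] = [(Posture.STANDING, 0)] * p["stand_ep"]
        if p["walk_ep"]:
            per = max(1, p["steps"] // p["walk_ep"])
            left = p["steps"]
            for i in range(p["walk_ep"]):
                s = per if i < p["walk_ep"] - 1 else max(1, left)
                left -= s
                queue.append((Posture.STEPPING, s))
        self.queue = queue

    # -- main loop --------------------------------------------------------
    def run(self) -> tuple[PostureEpochSeries, GroundTruthLog]:
        cfg = self.cfg
        rng = self.rng
        start = datetime.combine(cfg.start_date + timedelta(days=1), time(0, 0))
        n_min = cfg.n_days * 1440
        index = pd.date_range(start, periods=n_min, freq=EPOCH)
        postures = np.empty(n_min, dtype=object)
        statuses = np.empty(n_min, dtype=object)
        steps = np.zeros(n_min, dtype=np.int64)

        wake_a = cfg.wake_start.hour * 60 + cfg.wake_start.minute
        wake_b = cfg.wake_end.hour * 60 + cfg.wake_end.minute
        charge_a, charge_b = 2 * 60, 6 * 60  # overnight charge rendered 02:00-06:00
        battery_capacity = cfg.battery_life_days * 1440.0
        battery_left = battery_capacity

        # day-level draws, fixed up front
        manual_off = rng.random(cfg.n_days) < cfg.p_manual_off_day
        # charge on the night following day d (1-based); none after the last day
        charges_night = rng.random(cfg.n_days) < cfg.p_charge_nightly
        charges_night[-1] = False

        day_flags: list[dict] = [
            {"worn": False, "charged": False, "battery_dead": False, "manual_off": bool(manual_off[d])}
            for d in range(cfg.n_days)
        ]

        interval = self.setting.minutes if self.setting else None
        self._reset_day()
        self._draw_bout(sedentary=True)

        for i in range(n_min):
            day = i // 1440          # 0-based offset from study day 1
            mod = i % 1440           # minute of day
            if mod == 0:
                if self.pending is not None:
                    # a drawn response the day ended before rendering: the
                    # stream shows no movement, so the truth is a non-response
                    self._log_prompt(emitted=False)
                    self.pending = None
                self._reset_day()
                self._draw_bout(sedentary=True)

            # --- device status ------------------------------------------
            charging_now = charge_a <= mod < charge_b and day > 0 and charges_night[day - 1]
            if charging_now:
                statuses[i] = DeviceStatus.CHARGING.value
                postures[i] = Posture.LYING.value
                battery_left = battery_capacity
                day_flags[day]["charged"] = True
                continue
            if manual_off[day]:
                statuses[i] = DeviceStatus.OFF.value
                postures[i] = Posture.SITTING.value
                continue
            battery_left -= 1.0
            if battery_left <= 0:
                statuses[i] = DeviceStatus.BATTERY_DEAD.value
                postures[i] = Posture.SITTING.value
                day_flags[day]["battery_dead"] = True
                continue
            if not (wake_a <= mod < wake_b):
                statuses[i] = DeviceStatus.NOT_WORN.value
                postures[i] = Posture.LYING.value
                continue

            # --- worn waking epoch: behaviour model ----------------------
            statuses[i] = DeviceStatus.WORN.value
            day_flags[day]["worn"] = True

            if self.pending is not None:
                if self.pending["countdown"] > 0:
                    self.pending["countdown"] -= 1
                else:
                    self._activate_pending()
                    self._log_prompt(emitted=True)
                    self.pending = None

            if self.queue:
                posture, n_steps = self.queue.pop(0)
                postures[i] = posture.value
                steps[i] = n_steps
                self.counter = 0
                if not self.queue:
                    self._draw_bout(sedentary=True)
                    self.bout_left = max(self.bout_left, 1)
                continue

            holding = self.pending is not None or mod < self.hold_sed_until
            if self.bout_left <= 0 and not holding:
                self._draw_bout(sedentary=not self.bout_sedentary)

            if self.bout_sedentary or holding:
                postures[i] = self.bout_posture.value
                self.bout_left -= 1
                self.counter += 1
                if interval is not None and self.counter == interval:
                    self.counter = 0
                    self._prompt_fired_at = index[i] + EPOCH
                    self._draw_response_plan(mod + 1)
                    if not self.pending["responded"]:
                        self._log_prompt(emitted=False)
                        self.pending = None
            else:
                stepping = self.rng.random() < 0.4
                if stepping:
                    postures[i] = Posture.STEPPING.value
                    steps[i] = max(1, int(rng.poisson(cfg.step_rate)))
                else:
                    postures[i] = Posture.STANDING.value
                self.bout_left -= 1
                self.counter = 0

        # a response still pending when the series ends was never rendered
        if self.pending is not None:
            self._log_prompt(emitted=False)
            self.pending = None

        frame = pd.DataFrame(
            {"posture": postures, "steps": steps, "device_status": statuses}, index=index
        )
        series = PostureEpochSeries(self.pid, frame, EPOCH, cfg.start_date)
        for d in range(cfg.n_days):
            flags = day_flags[d]
            self.days.append(
                TrueDay(
                    self.pid,
                    cfg.start_date + timedelta(days=1 + d),
                    worn=flags["worn"],
                    charged=flags["charged"],
                    battery_dead=flags["battery_dead"],
                    manual_off=flags["manual_off"],
                )
            )
        return series, GroundTruthLog(self.prompts, self.days)

    def _log_prompt(self, *, emitted: bool) -> None:
        p = self.pending
        ts = self._prompt_fired_at
        if emitted and p is not None and p["responded"]:
            self.prompts.append(
                TruePrompt(
                    self.pid, ts.to_pydatetime(), True, p["latency"],
                    p["stand"], p["walk"], p["steps"],
                )
            )
        else:
            self.prompts.append(
                TruePrompt(self.pid, ts.to_pydatetime(), False, None, None, None, None)
            )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_counts(
    series: PostureEpochSeries,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> CountsEpochSeries:
    """Map a posture series onto the accelerometer count scale.

    Sitting, lying and standing epochs draw counts uniformly in [0, 100):
    on a hip-worn accelerometer, quiet standing sits below the stationary
    cut-point, which deliberately reproduces the known limitation that counts
    measure stationary time, not posture.  Stepping epochs draw counts at or
    above the ambulation cut-point; non-worn, off, charging and battery-dead
    epochs emit zero.
    """
    f = series.frame
    n = len(f)
    worn = (f["device_status"] == DeviceStatus.WORN.value).to_numpy()
    stepping = (f["posture"] == Posture.STEPPING.value).to_numpy() & worn
    counts = np.zeros(n, dtype=np.int64)
    quiet = worn & ~stepping
    counts[quiet] = rng.integers(0, 100, size=int(quiet.sum()))
    cut = config.ambulation_cutpoint
    counts[stepping] = rng.integers(cut, cut + 2000, size=int(stepping.sum()))
    steps = np.where(worn, f["steps"].to_numpy(), 0)
    frame = pd.DataFrame({"counts": counts, "steps": steps}, index=f.index)
    return CountsEpochSeries(series.patient_id, frame, series.epoch_length, series.discharge_date)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Simulate a full cohort: posture series, counts, manifest, ground truth.

    Fourteen days per patient on a 1-min grid; the seed fully determines the
    output.  All patients sit in the feedback arm with a prompt interval
    apportioned deterministically from ``prompt_interval_mix`` (largest
    remainder), so the default mix reproduces the 6:1:5 split over
    30/45/60 min exactly at n=12.
    """
    intervals = _apportion(dict(config.prompt_interval_mix), config.n_patients)
    root = np.random.SeedSequence(config.seed)
    behaviour_seeds = root.spawn(config.n_patients)
    counts_seeds = root.spawn(config.n_patients)

    manifest: list[PatientManifestEntry] = []
    series: dict[str, PostureEpochSeries] = {}
    counts: dict[str, CountsEpochSeries] = {}
    truth = GroundTruthLog()
    for k in range(config.n_patients):
        pid = f"P{k + 1:03d}"
        setting = PromptSetting(intervals[k])
        manifest.append(
            PatientManifestEntry(pid, Group.EDUCATION_FEEDBACK, config.start_date, setting)
        )
        sim = _PatientSim(pid, setting, config, np.random.default_rng(behaviour_seeds[k]))
        s, log = sim.run()
        series[pid] = s
        counts[pid] = generate_counts(s, config, np.random.default_rng(counts_seeds[k]))
        truth.prompts.extend(log.prompts)
        truth.days.extend(log.days)
    return Cohort(config, manifest, series, counts, truth)


# ---------------------------------------------------------------------------
# worked-example fixture
# ---------------------------------------------------------------------------

def build_concept_day_fixture(discharge: date = date(2016, 3, 1)) -> dict:
    """Deterministic single-day series reproducing the concept-diagram day.

    With the 30-min setting, prompt detection on this day yields prompts at
    exactly 09:30, 14:45, 16:30, 18:45, 19:15, 19:45, 21:00, 21:45 and 22:15.
    The five at 09:30, 14:45, 16:30, 21:00 and 22:15 are followed by standing
    and walking within 5 min; the evening triplet 18:45/19:15/19:45 falls in
    one unbroken sitting spell (three consecutive unanswered prompts) and the
    21:45 prompt is likewise unanswered.

    Returns ``{"series": PostureEpochSeries, "setting": PromptSetting(30)}``.
    """
    day = discharge + timedelta(days=1)
    start = datetime.combine(day, time(8, 0))
    end = datetime.combine(day, time(23, 0))
    n = int((end - start) / EPOCH)
    postures = np.array([Posture.SITTING.value] * n, dtype=object)
    steps = np.zeros(n, dtype=np.int64)

    def _i(hh: int, mm: int) -> int:
        return int((datetime.combine(day, time(hh, mm)) - start) / EPOCH)

    def sit(a, b):
        postures[_i(*a):_i(*b)] = Posture.SITTING.value

    def stand(a, b):
        postures[_i(*a):_i(*b)] = Posture.STANDING.value

    def step(a, b, per_min):
        i, j = _i(*a), _i(*b)
        postures[i:j] = Posture.STEPPING.value
        steps[i:j] = per_min

    def filler(a, b):
        """Sitting interleaved with standing so no 30-min sedentary run forms;
        the final minute is always standing so the next block starts fresh."""
        i, j = _i(*a), _i(*b)
        t = i
        while t < j:
            t += 25                      # up to 25 min sitting (already SITTING)
            if t < j:
                postures[t:min(t + 2, j)] = Posture.STANDING.value
                t += 2
        postures[j - 1] = Posture.STANDING.value

    filler((8, 0), (9, 0))
    sit((9, 0), (9, 32))                  # prompt 09:30; 2 min to react
    stand((9, 32), (9, 34))
    step((9, 34), (9, 35), 21)
    filler((9, 35), (14, 15))
    sit((14, 15), (14, 46))               # prompt 14:45
    stand((14, 46), (14, 48))
    step((14, 48), (14, 49), 18)
    filler((14, 49), (16, 0))
    sit((16, 0), (16, 33))                # prompt 16:30
    stand((16, 33), (16, 34))
    step((16, 34), (16, 35), 25)
    filler((16, 35), (18, 15))
    sit((18, 15), (20, 0))                # prompts 18:45, 19:15, 19:45 — unanswered
    stand((20, 0), (20, 1))
    step((20, 1), (20, 2), 15)
    sit((20, 2), (20, 29))
    stand((20, 29), (20, 30))
    sit((20, 30), (21, 2))                # prompt 21:00
    stand((21, 2), (21, 4))
    step((21, 4), (21, 5), 20)
    sit((21, 5), (21, 14))
    stand((21, 14), (21, 15))
    sit((21, 15), (22, 16))               # prompts 21:45 (unanswered), 22:15
    stand((22, 16), (22, 18))
    step((22, 18), (22, 19), 12)
    sit((22, 19), (22, 45))
    stand((22, 45), (22, 47))
    sit((22, 47), (23, 0))

    frame = pd.DataFrame(
        {
            "posture": postures,
            "steps": steps,
            "device_status": DeviceStatus.WORN.value,
        },
        index=pd.date_range(start, periods=n, freq=EPOCH),
    )
    series = PostureEpochSeries("concept_day", frame, EPOCH, discharge)
    return {"series": series, "setting": PromptSetting(30)}
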