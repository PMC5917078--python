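"""Wear detection, intensity cut-points, valid days and inclusion."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

import seatkit as sk
from seatkit.accelerometry import Intensity, IntensityCutpoints
from seatkit.data_model import ConfigError, DomainError


def _counts(values, start="2016-03-02 08:00", pid="T001", discharge=date(2016, 3, 1)):
    frame = pd.DataFrame(
        {"counts": values, "steps": np.zeros(len(values), dtype=int)},
        index=pd.date_range(start, periods=len(values), freq="60s"),
    )
    return sk.CountsEpochSeries(pid, frame, timedelta(minutes=1), discharge)


class TestDetectNonwear:
    def test_90_consecutive_zeros_flagged(self):
        series = _counts([50] * 10 + [0] * 90 + [50] * 10)
        flags = sk.detect_nonwear(series)
        assert (~flags.worn[10:100]).all()
        assert flags.worn[:10].all() and flags.worn[100:].all()

    def test_59_zeros_flanked_stays_worn(self):
        series = _counts([50] + [0] * 59 + [50])
        assert sk.detect_nonwear(series).worn.all()

    def test_60_zeros_is_the_boundary(self):
        series = _counts([50] + [0] * 60 + [50])
        flags = sk.detect_nonwear(series)
        assert (~flags.worn[1:61]).all()

    def test_alternating_counts_fully_worn(self):
        series = _counts([0, 50] * 100)
        assert sk.detect_nonwear(series).worn.all()

    def test_window_shorter_than_epoch_rejected(self):
        series = _counts([0] * 10)
        with pytest.raises(ConfigError):
            sk.detect_nonwear(series, timedelta(seconds=30))

    def test_idempotent_and_monotone_in_window(self):
        rng = np.random.default_rng(42)
        vals = rng.choice([0, 0, 0, 40], size=2000)
        series = _counts(list(vals))
        w60 = sk.detect_nonwear(series, timedelta(minutes=60)).worn
        w90 = sk.detect_nonwear(series, timedelta(minutes=90)).worn
        # longer window never flags more epochs as not-worn
        assert (~w60 | w90).all() or (w90 >= w60).all()
        # idempotence: re-running on a masked copy changes nothing
        again = sk.detect_nonwear(series, timedelta(minutes=60)).worn
        assert (again == w60).all()


class TestClassifyIntensity:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0, Intensity.STATIONARY),
            (99, Intensity.STATIONARY),
            (100, Intensity.LIGHT),
            (1951, Intensity.LIGHT),
            (1952, Intensity.MVPA),
            (5000, Intensity.MVPA),
        ],
    )
    def test_cutpoint_boundaries(self, value, expected):
        assert sk.classify_intensity(value) is expected

    def test_invalid_cutpoints_rejected(self):
        with pytest.raises(ConfigError):
            IntensityCutpoints(stationary_below=2000, mvpa_at_or_above=100)


class TestValidateDays:
    def test_exactly_480_minutes_is_valid(self):
        series = _counts([50] * 480 + [0] * 100, start="2016-03-02 00:00")
        days = sk.validate_days(sk.detect_nonwear(series))
        assert days[0].wear_min == 480 and days[0].valid

    def test_479_minutes_is_invalid(self):
        series = _counts([50] * 479 + [0] * 100, start="2016-03-02 00:00")
        days = sk.validate_days(sk.detect_nonwear(series))
        assert days[0].wear_min == 479 and not days[0].valid

    def test_zero_wear_day_has_null_percentages(self):
        series = _counts([0] * 1440, start="2016-03-02 00:00")
        days = sk.validate_days(sk.detect_nonwear(series))
        assert not days[0].valid
        assert days[0].pct_stationary is None and days[0].pct_mvpa is None

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([30, 150, 2500], size=600, p=[0.7, 0.25, 0.05])
        days = sk.validate_days(sk.detect_nonwear(_counts(list(vals))))
        d = days[0]
        assert d.pct_stationary + d.pct_light + d.pct_mvpa == pytest.approx(100, abs=0.01)


class TestPatientInclusion:
    @staticmethod
    def _days(valid_by_index: dict[int, bool]):
        return [
            sk.ValidDay(date(2016, 3, 1) + timedelta(days=i), i, 500 if v else 100, v, 0, 100.0, 0.0, 0.0)
            for i, v in valid_by_index.items()
        ]

    def test_four_and_four_included(self):
        days = self._days({i: i in (1, 2, 3, 4, 8, 9, 10, 11) for i in range(1, 15)})
        assert sk.patient_inclusion(days) == {
            "week1_valid_days": 4,
            "week2_valid_days": 4,
            "included": True,
        }

    def test_seven_and_three_excluded(self):
        days = self._days({i: i <= 7 or i in (8, 9, 10) for i in range(1, 15)})
        out = sk.patient_inclusion(days)
        assert out["week1_valid_days"] == 7 and out["week2_valid_days"] == 3
        assert not out["included"]

    def test_no_valid_days_excluded(self):
        days = self._days({i: False for i in range(1, 15)})
        assert not sk.patient_inclusion(days)["included"]

    def test_out_of_range_day_index_rejected(self):
        days = self._days({15: True})
        with pytest.raises(DomainError):
            sk.patient_inclusion(days)

    def test_monotone_in_adding_valid_days(self):
        base = {i: i in (1, 2, 3, 4, 8, 9, 10) for i in range(1, 15)}  # week2 short by one
        assert not sk.patient_inclusion(self._days(base))["included"]
        base[11] = True
        assert sk.patient_inclusion(self._days(base))["included"]


class TestCohortDailyProfile:
    @staticmethod
    def _valid_day(idx, steps, stat=70.0, light=29.0, mvpa=1.0):
        return sk.ValidDay(date(2016, 3, 1) + timedelta(days=idx), idx, 600, True, steps, stat, light, mvpa)

    def test_single_patient_profile_is_identity(self):
        days = [self._valid_day(i, 1000 * i) for i in range(1, 4)]
        profile = sk.cohort_daily_profile({"A": days})
        assert list(profile["mean_steps"]) == [1000, 2000, 3000]
        assert (profile["n"] == 1).all()

    def test_two_patient_means(self):
        profile = sk.cohort_daily_profile(
            {"A": [self._valid_day(1, 1000)], "B": [self._valid_day(1, 3000)]}
        )
        assert profile.loc[1, "mean_steps"] == 2000 and profile.loc[1, "n"] == 2

    def test_monotone_steps_give_monotone_profile(self):
        patients = {
            pid: [self._valid_day(i, base + 500 * i) for i in range(1, 15)]
            for pid, base in [("A", 2000), ("B", 3000)]
        }
        profile = sk.cohort_daily_profile(patients)
        assert profile["mean_steps"].is_monotonic_increasing

    def test_empty_cohort_empty_profile(self):
        assert len(sk.cohort_daily_profile({})) == 0
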