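"""Response adjudication and prompt-outcome summaries."""

from __future__ import annotations

import random
from datetime import date, datetime

import pytest

import seatkit as sk
from seatkit.data_model import DomainError, ManifestError

from helpers import series_from_string


def _single_prompt_series(tail: str):
    """30 min sitting then ``tail``; returns (series, its one prompt)."""
    series = series_from_string("S" * 30 + tail)
    prompts = sk.detect_prompts(series, sk.PromptSetting(30))
    assert len(prompts) >= 1
    return series, prompts


class TestClassifyResponse:
    def test_unbroken_sitting_is_nonresponse(self):
        series, prompts = _single_prompt_series("S" * 15 + "D" * 5)
        # the stand at +15 min falls outside the window
        c = sk.classify_response(series, prompts[0])
        assert not c.responded and c.latency_min is None and not c.within_5min

    def test_stand_then_steps_within_five_minutes(self):
        # stand at +1 min for 2 min, then a stepping minute of 20 steps
        series = series_from_string("S" * 30 + "SDDW" + "S" * 12, steps_per_walk=20)
        prompts = sk.detect_prompts(series, sk.PromptSetting(30))
        c = sk.classify_response(series, prompts[0])
        assert c.responded and c.within_5min
        assert c.latency_min == 2
        assert c.stand_min == 2 and c.walk_min == 1 and c.steps == 20

    def test_late_response_is_not_within_five(self):
        # first standing epoch at +7 min
        series, prompts = _single_prompt_series("S" * 7 + "D" * 3 + "S" * 10)
        c = sk.classify_response(series, prompts[0])
        assert c.responded and not c.within_5min
        assert c.latency_min == 8
        assert c.stand_min == 0 and c.walk_min == 0  # nothing inside the 5-min frame

    def test_unbroken_sitting_run_windows(self):
        # continuous sitting: every prompt is a non-response; the first two
        # windows are full 15-min sitting spells, the last is cut by series end
        series = series_from_string("S" * 90)
        prompts = sk.detect_prompts(series, sk.PromptSetting(30))
        c = sk.classify_all(series, prompts)
        assert all(not x.responded for x in c)
        assert not c[0].window_truncated and c[0].window_worn_epochs == 15
        assert not c[1].window_truncated
        assert c[2].window_truncated and c[2].window_worn_epochs == 0

    def test_nonwear_window_flagged(self):
        series, prompts = _single_prompt_series("N" * 20)
        c = sk.classify_response(series, prompts[0])
        assert not c.responded and c.window_truncated and c.window_worn_epochs == 0

    def test_truncation_only_flips_responded_to_false(self):
        # activity at +10 min: full window sees it, a next-prompt cut at +5 hides it
        series = series_from_string("S" * 30 + "S" * 10 + "D" * 2 + "S" * 10)
        prompts = sk.detect_prompts(series, sk.PromptSetting(30))
        full = sk.classify_response(series, prompts[0])
        assert full.responded
        fake_next = sk.PromptEvent(
            prompts[0].timestamp.replace(minute=35),
            prompts[0].timestamp.replace(minute=5),
            sk.PromptSetting(30),
        )
        cut = sk.classify_response(series, prompts[0], fake_next)
        assert not cut.responded and cut.window_truncated

    def test_prompt_outside_series_is_domain_error(self):
        series = series_from_string("S" * 40)
        stray = sk.PromptEvent(datetime(2016, 3, 3, 9, 0), datetime(2016, 3, 3, 8, 30), sk.PromptSetting(30))
        with pytest.raises(DomainError):
            sk.classify_response(series, stray)


def _make_verdicts(n_prompts: int, n_responded: int, n_within5: int):
    """Synthetic classifications with prompts spread over distinct days."""
    out = []
    for i in range(n_prompts):
        ts = datetime(2016, 3, 2 + i % 14, 10, 0)
        prompt = sk.PromptEvent(ts, ts.replace(hour=9, minute=30), sk.PromptSetting(30), 1 + i % 14)
        responded = i < n_responded
        within5 = i < n_within5
        out.append(
            sk.ResponseClassification(
                prompt=prompt,
                responded=responded,
                latency_min=(3.0 if within5 else 8.0) if responded else None,
                within_5min=within5,
                stand_min=1.0 if within5 else 0.0,
                walk_min=1.0 if within5 else 0.0,
                steps=20 if within5 else 0,
                window_truncated=False,
                window_worn_epochs=15,
            )
        )
    return out


class TestSummarizePrompts:
    def test_trial_headline_response_rate(self):
        # 106 responses out of 325 prompts
        summary = sk.summarize_prompts(_make_verdicts(325, 106, 43), n_days_observed=14)
        assert summary.response_rate_pct == 32.62
        assert summary.pct_nonresponse == 67.38
        assert summary.n_prompts == 325 and summary.n_responded == 106

    def test_empty_input_yields_null_rates(self):
        summary = sk.summarize_prompts([], n_days_observed=14)
        assert summary.n_prompts == 0
        assert summary.response_rate_pct is None
        assert summary.pct_within5_of_responses is None
        assert summary.prompts_per_day == 0

    def test_partition_of_prompt_outcomes(self):
        summary = sk.summarize_prompts(_make_verdicts(50, 20, 9), 14)
        n_after5 = summary.n_responded - summary.n_within5
        assert summary.n_prompts == (summary.n_prompts - summary.n_responded) + summary.n_within5 + n_after5

    def test_order_invariance(self):
        verdicts = _make_verdicts(60, 25, 10)
        shuffled = verdicts[:]
        random.Random(7).shuffle(shuffled)
        assert sk.summarize_prompts(verdicts, 14) == sk.summarize_prompts(shuffled, 14)

    def test_nonwear_exclusion_mode_shrinks_denominator(self):
        verdicts = _make_verdicts(10, 4, 2)
        ghost = sk.ResponseClassification(
            prompt=verdicts[0].prompt,
            responded=False,
            latency_min=None,
            within_5min=False,
            stand_min=0.0,
            walk_min=0.0,
            steps=0,
            window_truncated=True,
            window_worn_epochs=0,
        )
        incl = sk.summarize_prompts(verdicts + [ghost], 14)
        excl = sk.summarize_prompts(verdicts + [ghost], 14, exclude_nonwear_windows=True)
        assert incl.n_prompts == 11 and excl.n_prompts == 10
        assert excl.response_rate_pct == 40.0

    def test_nonpositive_days_rejected(self):
        with pytest.raises(DomainError):
            sk.summarize_prompts([], 0)

    def test_magnitudes_only_over_within5_responses(self):
        summary = sk.summarize_prompts(_make_verdicts(10, 6, 3), 14)
        assert summary.mean_stand_min == 1.0 and summary.mean_steps == 20


class TestStratifyBySetting:
    @staticmethod
    def _summaries_for(settings_by_pid: dict[str, int], sitting_min: int = 600):
        manifest, summaries = [], {}
        for pid, minutes in settings_by_pid.items():
            series = series_from_string("S" * sitting_min, patient_id=pid,
                                        start=datetime(2016, 3, 2, 8, 0))
            prompts = sk.detect_prompts(series, sk.PromptSetting(minutes))
            cl = sk.classify_all(series, prompts)
            summaries[pid] = sk.summarize_prompts(cl, 1)
            manifest.append(
                sk.PatientManifestEntry(pid, sk.Group.EDUCATION_FEEDBACK, date(2016, 3, 1),
                                        sk.PromptSetting(minutes))
            )
        return summaries, manifest

    def test_identical_profiles_30_vs_60_doubles_prompt_rate(self):
        summaries, manifest = self._summaries_for({"A": 30, "B": 60})
        table = sk.stratify_by_setting(summaries, manifest)
        # floor(600/30)=20 vs floor(600/60)=10 prompts on the same sitting day
        assert table.loc[30, "prompts_per_day"] == 2 * table.loc[60, "prompts_per_day"]
        assert table.loc[30, "n_prompts"] == 20 and table.loc[60, "n_prompts"] == 10

    def test_single_setting_single_row(self):
        summaries, manifest = self._summaries_for({"A": 45})
        table = sk.stratify_by_setting(summaries, manifest)
        assert list(table.index) == [45]

    def test_empty_cohort_empty_table(self):
        table = sk.stratify_by_setting({}, [])
        assert len(table) == 0

    def test_unknown_patient_is_manifest_error(self):
        summaries, manifest = self._summaries_for({"A": 30})
        with pytest.raises(ManifestError):
            sk.stratify_by_setting(summaries, [])
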