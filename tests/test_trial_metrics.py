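"""Trial-flow percentages, test selection, and descriptor bands."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

import seatkit as sk
from seatkit.data_model import DomainError
from seatkit.trial_metrics import BmiClass, CategoricalTest, GroupTest, HadsBand


def _flow_frame(n_screened, n_eligible, n_approached, n_consented, n_enrolled, n_completed):
    """Funnel-consistent flow log with the given stage counts."""
    rows = []
    for i in range(n_screened):
        rows.append(
            {
                "patient_id": f"S{i:03d}",
                "screened": True,
                "eligible": i < n_eligible,
                "approached": i < n_approached,
                "consented": i < n_consented,
                "enrolled": i < n_enrolled,
                "completed_followup": i < n_completed,
                "group": ["CONTROL", "EDUCATION", "EDUCATION_FEEDBACK"][i % 3],
            }
        )
    return sk.FlowLog(pd.DataFrame(rows))


class TestFlowMetrics:
    def test_trial_funnel_percentages(self):
        # 300 screened -> 212 eligible -> 111 approached -> 35 consented
        # -> 33 enrolled -> 17 completed
        log = _flow_frame(300, 212, 111, 35, 33, 17)
        m = sk.flow_metrics(log)
        assert m.pct_eligible == 70.7
        assert m.pct_approached == 52.4
        assert m.pct_uptake == 31.5
        assert m.pct_retention == 51.5
        assert sum(g["completed"] for g in m.completion_by_group.values()) == 17

    def test_zero_approached_gives_null_uptake(self):
        log = _flow_frame(10, 5, 0, 0, 0, 0)
        m = sk.flow_metrics(log)
        assert m.pct_uptake is None and m.pct_eligible == 50.0

    def test_percentages_scale_invariant(self):
        small = sk.flow_metrics(_flow_frame(30, 21, 11, 3, 3, 1))
        large = sk.flow_metrics(_flow_frame(90, 63, 33, 9, 9, 3))
        assert small.pct_eligible == large.pct_eligible
        assert small.pct_approached == large.pct_approached
        assert small.pct_uptake == large.pct_uptake
        assert small.pct_retention == large.pct_retention


def fisher_p_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestSelectCategoricalTest:
    def test_homogeneous_table_chi_square_p_one(self):
        out = sk.select_categorical_test([[10, 10], [10, 10]])
        assert out["test"] is CategoricalTest.CHI_SQUARE
        assert out["p_value"] == pytest.approx(1.0)
        assert out["statistic"] == pytest.approx(0.0)

    def test_small_cell_selects_fisher(self):
        out = sk.select_categorical_test([[2, 8], [7, 3]])
        assert out["test"] is CategoricalTest.FISHER_EXACT

    def test_fisher_p_matches_enumeration_on_sharp_table(self):
        out = sk.select_categorical_test([[1, 9], [9, 1]])
        assert out["p_value"] == pytest.approx(fisher_p_by_enumeration(1, 9, 9, 1), rel=1e-9)

    def test_expected_count_mode_can_differ(self):
        # observed cells all >= 5 but an expected cell below 5
        table = [[5, 45], [5, 5]]
        assert sk.select_categorical_test(table)["test"] is CategoricalTest.CHI_SQUARE
        assert (
            sk.select_categorical_test(table, rule="expected")["test"]
            is CategoricalTest.FISHER_EXACT
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError, match="degenerate"):
            sk.select_categorical_test([[0, 0], [3, 4]])


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        out = sk.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["test"] is GroupTest.T_TEST
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_anova_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        t = sk.compare_groups(a, b)
        f_stat, _ = __import__("scipy.stats", fromlist=["f_oneway"]).f_oneway(a, b)
        assert f_stat == pytest.approx(t["statistic"] ** 2, rel=1e-9)

    def test_three_groups_use_anova(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 15) for m in (0, 0, 2)]
        out = sk.compare_groups(*groups)
        assert out["test"] is GroupTest.ANOVA and out["p_value"] < 0.05

    def test_shifted_normals_detected_with_high_power(self):
        rng = np.random.default_rng(10)
        rejections = sum(
            sk.compare_groups(rng.normal(0, 1, 100), rng.normal(0.8, 1, 100))["p_value"] < 0.05
            for _ in range(50)
        )
        assert rejections >= 48  # analytic power at d=0.8, n=100/arm is >0.999

    def test_too_small_group_rejected(self):
        with pytest.raises(DomainError):
            sk.compare_groups([1.0], [2.0, 3.0])


class TestDescriptorBands:
    @pytest.mark.parametrize(
        "score, band",
        [(0, HadsBand.NORMAL), (7, HadsBand.NORMAL), (8, HadsBand.BORDERLINE),
         (10, HadsBand.BORDERLINE), (11, HadsBand.ABNORMAL), (21, HadsBand.ABNORMAL)],
    )
    def test_hads_bands(self, score, band):
        assert sk.classify_descriptors(hads_anxiety=score).hads_anxiety is band

    def test_fatigue_threshold(self):
        assert sk.classify_descriptors(fatigue=29).fatigue_severe
        assert not sk.classify_descriptors(fatigue=30).fatigue_severe

    def test_sppb_threshold(self):
        assert sk.classify_descriptors(sppb=9).sppb_limitation
        assert not sk.classify_descriptors(sppb=10).sppb_limitation

    @pytest.mark.parametrize(
        "bmi, cls",
        [(18.4, BmiClass.UNDERWEIGHT), (18.5, BmiClass.NORMAL), (24.9, BmiClass.NORMAL),
         (25.0, BmiClass.OVERWEIGHT), (30.0, BmiClass.OVERWEIGHT), (30.01, BmiClass.OBESE)],
    )
    def test_bmi_classes(self, bmi, cls):
        assert sk.classify_descriptors(bmi=bmi).bmi_class is cls

    def test_bands_total_over_instrument_ranges(self):
        for score in range(0, 22):
            assert sk.classify_descriptors(hads_depression=score).hads_depression is not None
        for score in range(0, 53):
            assert sk.classify_descriptors(fatigue=score).fatigue_severe is not None
        for score in range(0, 13):
            assert sk.classify_descriptors(sppb=score).sppb_limitation is not None

    @pytest.mark.parametrize("kw", [dict(hads_anxiety=22), dict(fatigue=53), dict(sppb=13), dict(bmi=0)])
    def test_out_of_range_scores_rejected(self, kw):
        with pytest.raises(DomainError):
            sk.classify_descriptors(**kw)
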