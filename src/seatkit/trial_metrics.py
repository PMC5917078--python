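"""CONSORT-style flow percentages, group comparisons, and questionnaire bands.

Flow percentages use the trial's own denominators: eligible of screened,
approached of eligible, consented of approached (uptake), completed of
enrolled (retention), each to one decimal.  Categorical comparisons follow
the small-cell rule — Fisher's exact test when any cell is below 5, Pearson
chi-square otherwise; continuous comparisons use the independent t test for
two groups and one-way ANOVA beyond.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import DomainError, FlowLog

__all__ = [
    "FlowMetrics",
    "flow_metrics",
    "CategoricalTest",
    "GroupTest",
    "select_categorical_test",
    "compare_groups",
    "HadsBand",
    "BmiClass",
    "DescriptorBands",
    "classify_descriptors",
    "ALPHA",
]

ALPHA = 0.05


def _pct1(numer: int, denom: int) -> float | None:
    """Percentage to 1 decimal, ties away from zero; None on empty denominator."""
    if denom == 0:
        return None
    return math.floor(1000.0 * numer / denom + 0.5) / 10.0


# ---------------------------------------------------------------------------
# trial flow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowMetrics:
    n_screened: int
    n_eligible: int
    n_approached: int
    n_consented: int
    n_enrolled: int
    n_completed: int
    pct_eligible: float | None        # of screened
    pct_approached: float | None      # of eligible
    pct_uptake: float | None          # consented of approached
    pct_retention: float | None       # completed of enrolled
    completion_by_group: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def flow_metrics(log: FlowLog) -> FlowMetrics:
    """Compute screening-funnel percentages from a validated flow log."""
    f = log.frame
    n_screened = int(f["screened"].sum())
    n_eligible = int(f["eligible"].sum())
    n_approached = int(f["approached"].sum())
    n_consented = int(f["consented"].sum())
    n_enrolled = int(f["enrolled"].sum())
    n_completed = int(f["completed_followup"].sum())
    by_group: dict[str, dict[str, int]] = {}
    enrolled = f[f["enrolled"]]
    for group, sub in enrolled.groupby("group"):
        by_group[str(group)] = {
            "enrolled": int(len(sub)),
            "completed": int(sub["completed_followup"].sum()),
        }
    return FlowMetrics(
        n_screened=n_screened,
        n_eligible=n_eligible,
        n_approached=n_approached,
        n_consented=n_consented,
        n_enrolled=n_enrolled,
        n_completed=n_completed,
        pct_eligible=_pct1(n_eligible, n_screened),
        pct_approached=_pct1(n_approached, n_eligible),
        pct_uptake=_pct1(n_consented, n_approached),
        pct_retention=_pct1(n_completed, n_enrolled),
        completion_by_group=by_group,
    )


# ---------------------------------------------------------------------------
# statistical test selection
# ---------------------------------------------------------------------------

class CategoricalTest(str, enum.Enum):
    CHI_SQUARE = "CHI_SQUARE"
    FISHER_EXACT = "FISHER_EXACT"


def select_categorical_test(table, *, rule: str = "observed") -> dict:
    """Pick and run the categorical test for a two-way count table.

    Fisher's exact test when any cell count is below 5, Pearson chi-square
    (no continuity correction) otherwise.  ``rule`` may be ``"observed"``
    (default: the rule reads the observed cells) or ``"expected"`` (reads the
    expected cells under independence).  Fisher is only defined here for 2x2
    tables; a larger table triggering the small-cell rule is an error.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise DomainError("table must be a 2-way array of non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("degenerate table: a row or column margin is zero")
    if rule not in ("observed", "expected"):
        raise DomainError(f"unknown rule {rule!r}")
    if rule == "observed":
        small = (t < 5).any()
    else:
        expected = stats.contingency.expected_freq(t)
        small = (expected < 5).any()
    if small:
        if t.shape != (2, 2):
            raise DomainError(
                f"small-cell rule selects Fisher's exact test, undefined for shape {t.shape}"
            )
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return {
            "test": CategoricalTest.FISHER_EXACT,
            "statistic": float(odds),
            "p_value": float(p),
        }
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return {
        "test": CategoricalTest.CHI_SQUARE,
        "statistic": float(chi2),
        "p_value": float(p),
    }


class GroupTest(str, enum.Enum):
    T_TEST = "T_TEST"
    ANOVA = "ANOVA"


def compare_groups(*groups) -> dict:
    """Two-sided independent t test (k=2) or one-way ANOVA (k>2).

    Each group needs at least two values.  Returns the test used, statistic,
    two-sided p, and the trial's alpha (0.05) for reporting alongside.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DomainError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if len(a) < 2:
            raise DomainError(f"group {i} has {len(a)} values; need >= 2")
    if len(arrays) == 2:
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        test = GroupTest.T_TEST
    else:
        stat, p = stats.f_oneway(*arrays)
        test = GroupTest.ANOVA
    if np.isnan(p):  # identical constant groups: no variance anywhere
        stat, p = 0.0, 1.0
    return {"test": test, "statistic": float(stat), "p_value": float(p), "alpha": ALPHA}


# ---------------------------------------------------------------------------
# questionnaire threshold classification
# ---------------------------------------------------------------------------

class HadsBand(str, enum.Enum):
    NORMAL = "NORMAL"            # 0-7
    BORDERLINE = "BORDERLINE"    # 8-10
    ABNORMAL = "ABNORMAL"        # 11-21


class BmiClass(str, enum.Enum):
    UNDERWEIGHT = "UNDERWEIGHT"  # < 18.5
    NORMAL = "NORMAL"            # [18.5, 25)
    OVERWEIGHT = "OVERWEIGHT"    # [25, 30]
    OBESE = "OBESE"              # > 30


@dataclass(frozen=True)
class DescriptorBands:
    hads_anxiety: HadsBand | None = None
    hads_depression: HadsBand | None = None
    fatigue_severe: bool | None = None       # FACIT-Fatigue < 30
    sppb_limitation: bool | None = None      # SPPB < 10
    bmi_class: BmiClass | None = None


def _hads_band(score: float, label: str) -> HadsBand:
    if not (0 <= score <= 21) or int(score) != score:
        raise DomainError(f"{label} score {score} outside 0-21")
    if score <= 7:
        return HadsBand.NORMAL
    if score <= 10:
        return HadsBand.BORDERLINE
    return HadsBand.ABNORMAL


def classify_descriptors(
    *,
    hads_anxiety: float | None = None,
    hads_depression: float | None = None,
    fatigue: float | None = None,
    sppb: float | None = None,
    bmi: float | None = None,
) -> DescriptorBands:
    """Band questionnaire and anthropometric scores by the trial thresholds.

    HADS subscales: 0-7 normal, 8-10 borderline, 11-21 abnormal.
    FACIT-Fatigue below 30 is severe fatigue (instrument range 0-52).
    SPPB below 10 marks mobility limitation (range 0-12).
    BMI: <18.5 underweight, [18.5, 25) normal, [25, 30] overweight, >30 obese.
    Out-of-range scores raise :class:`DomainError`.
    """
    out: dict = {}
    if hads_anxiety is not None:
        out["hads_anxiety"] = _hads_band(hads_anxiety, "HADS anxiety")
    if hads_depression is not None:
        out["hads_depression"] = _hads_band(hads_depression, "HADS depression")
    if fatigue is not None:
        if not (0 <= fatigue <= 52):
            raise DomainError(f"fatigue score {fatigue} outside 0-52")
        out["fatigue_severe"] = fatigue < 30
    if sppb is not None:
        if not (0 <= sppb <= 12) or int(sppb) != sppb:
            raise DomainError(f"SPPB score {sppb} outside 0-12")
        out["sppb_limitation"] = sppb < 10
    if bmi is not None:
        if not (5 < bmi < 100):
            raise DomainError(f"implausible BMI {bmi}")
        if bmi < 18.5:
            out["bmi_class"] = BmiClass.UNDERWEIGHT
        elif bmi < 25.0:
            out["bmi_class"] = BmiClass.NORMAL
        elif bmi <= 30.0:
            out["bmi_class"] = BmiClass.OVERWEIGHT
        else:
            out["bmi_class"] = BmiClass.OBESE
    return DescriptorBands(**out)
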