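"""Delineation-time analysis, paired statistics and the acceptance decision.

The delineation workflow has two steps: a first operation (manual contouring,
or automatic delineation including atlas choice and propagation) taking T1
minutes, and an independent check by a second operator taking T2 minutes; the
total time is TT = T1 + T2.  An auto-delineation system is accepted for
clinical use when at least 2 of 3 criteria are met — median DSC >= 0.75,
mean slicewise Hausdorff <= 1 mm, total-time saving >= 50% — and the
time-saving criterion is mandatory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .metrics import CohortOverlapSummary, OverlapResult, summarise_cohort


class DegenerateTestError(ValueError):
    """Raised when a statistical test is undefined (e.g. zero variance)."""


class WorkflowGroup(str, enum.Enum):
    """Delineation workflow arm: fully manual (A) or atlas-automatic (B)."""

    MANUAL = "A"
    AUTO = "B"


@dataclass(frozen=True)
class TimingRecord:
    """Per-patient, per-workflow timing: first operation + independent check."""

    patient_id: str
    group: WorkflowGroup
    t1_min: float
    t2_min: float

    def __post_init__(self) -> None:
        if self.t1_min < 0 or self.t2_min < 0:
            raise ValueError("times must be non-negative")
        object.__setattr__(self, "group", WorkflowGroup(self.group))

    @property
    def tt_min(self) -> float:
        return self.t1_min + self.t2_min


@dataclass(frozen=True)
class QACriteria:
    """Acceptance thresholds; comparisons are inclusive (>=, <=, >=)."""

    dsc_min: float = 0.75
    mshd_max_mm: float = 1.0
    tt_saving_min_pct: float = 50.0
    required_met: int = 2
    mandatory: str = "tt_saving"  # the time-saving criterion must be among those met

    def __post_init__(self) -> None:
        if not (1 <= self.required_met <= 3):
            raise ValueError("required_met must be between 1 and 3")
        if self.mandatory not in ("dsc", "mshd", "tt_saving", ""):
            raise ValueError(f"unknown mandatory criterion: {self.mandatory}")


@dataclass(frozen=True)
class QADecision:
    """Observed cohort triple evaluated against the acceptance criteria."""

    observed: tuple[float, float, float]  # (mdsc, mshd_mean_mm, tt_saving_pct)
    met: dict[str, bool]
    n_met: int
    mandatory_met: bool
    accepted: bool


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff_min: float
    t_statistic: float
    p_value: float
    ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class GroupTimeSummary:
    group: WorkflowGroup
    n: int
    t1_mean: float
    t1_sd: float
    t2_mean: float
    t2_sd: float
    tt_mean: float
    tt_sd: float
    sd_defined: bool


# ---------------------------------------------------------------------------
# Time analysis
# ---------------------------------------------------------------------------

def group_time_summary(records: Sequence[TimingRecord]) -> GroupTimeSummary:
    """Arithmetic mean and sample SD of T1, T2 and TT for one workflow group."""
    if not records:
        raise ValueError("empty timing group")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError(f"records mix workflow groups: {sorted(g.value for g in groups)}")
    t1 = np.array([r.t1_min for r in records])
    t2 = np.array([r.t2_min for r in records])
    tt = t1 + t2
    sd_defined = len(records) > 1
    sd = (lambda x: float(np.std(x, ddof=1))) if sd_defined else (lambda x: 0.0)
    return GroupTimeSummary(
        group=groups.pop(),
        n=len(records),
        t1_mean=float(t1.mean()), t1_sd=sd(t1),
        t2_mean=float(t2.mean()), t2_sd=sd(t2),
        tt_mean=float(tt.mean()), tt_sd=sd(tt),
        sd_defined=sd_defined,
    )


def time_saving_pct(tt_manual_mean: float, tt_auto_mean: float) -> float:
    """Ratio-of-means total-time saving, percent.

    ``100 * (TT_manual - TT_auto) / TT_manual``; negative when the automatic
    workflow is slower.
    """
    if tt_manual_mean <= 0:
        raise ValueError("manual total time must be positive")
    return 100.0 * (tt_manual_mean - tt_auto_mean) / tt_manual_mean


def per_patient_saving(
    records_manual: Sequence[TimingRecord],
    records_auto: Sequence[TimingRecord],
) -> tuple[dict[str, float], float]:
    """Per-patient saving 100*(TT_A - TT_B)/TT_A matched by patient id.

    Returns the per-patient percentages and their mean.  Offered alongside
    the ratio-of-means estimator because the two can disagree noticeably on
    skewed timing distributions.
    """
    manual = {r.patient_id: r for r in records_manual}
    auto = {r.patient_id: r for r in records_auto}
    unmatched = sorted(set(manual) ^ set(auto))
    if unmatched or not manual:
        raise ValueError(f"patients not present in both groups: {unmatched}")
    savings = {
        pid: time_saving_pct(manual[pid].tt_min, auto[pid].tt_min)
        for pid in sorted(manual)
    }
    return savings, float(np.mean(list(savings.values())))


def paired_t_test(diffs: Sequence[float]) -> PairedTestResult:
    """Classical paired Student t-test on per-patient differences.

    Two-sided p-value with n−1 degrees of freedom and the 95% confidence
    interval of the mean difference.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("zero variance of paired differences")
    n = len(d)
    mean = float(d.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    half = float(stats.t.ppf(0.975, df=n - 1)) * se
    return PairedTestResult(
        mean_diff_min=mean,
        t_statistic=float(t),
        p_value=p,
        ci95=(mean - half, mean + half),
        n=n,
    )


# ---------------------------------------------------------------------------
# Acceptance decision
# ---------------------------------------------------------------------------

def decide(
    mdsc: float, mshd_mean_mm: float, tt_saving_pct_value: float,
    criteria: QACriteria = QACriteria(),
) -> QADecision:
    """Evaluate the observed (MDSC, MSHD, TT-saving) triple.

    Accepted iff at least ``required_met`` criteria hold AND the mandatory
    criterion (time saving, by default) is among those met.  All comparisons
    are inclusive, so a cohort sitting exactly on every threshold meets all
    three criteria.
    """
    observed = (float(mdsc), float(mshd_mean_mm), float(tt_saving_pct_value))
    if not all(np.isfinite(observed)):
        raise ValueError(f"observed values must be finite: {observed}")
    met = {
        "dsc": observed[0] >= criteria.dsc_min,
        "mshd": observed[1] <= criteria.mshd_max_mm,
        "tt_saving": observed[2] >= criteria.tt_saving_min_pct,
    }
    n_met = sum(met.values())
    mandatory_met = met[criteria.mandatory] if criteria.mandatory else True
    return QADecision(
        observed=observed,
        met=met,
        n_met=n_met,
        mandatory_met=mandatory_met,
        accepted=(n_met >= criteria.required_met) and mandatory_met,
    )


def evaluate_acceptance(
    summary: CohortOverlapSummary,
    saving_pct: float,
    criteria: QACriteria = QACriteria(),
) -> QADecision:
    """Acceptance decision from a cohort overlap summary and a TT saving."""
    return decide(summary.mdsc, summary.mshd_mean_mm, saving_pct, criteria)


# ---------------------------------------------------------------------------
# Sensitivity / subgroup analyses
# ---------------------------------------------------------------------------

def worst_patients(results: Sequence[OverlapResult], k_worst: int) -> list[str]:
    """Ids of the k patients with worst combined overlap rank.

    Rank ascending by DSC plus rank descending by MSHD; ties broken by
    patient id.  This is a reproducible stand-in for the qualitative
    "irregular anatomy" outlier identification done by eye in practice.
    """
    if k_worst < 0:
        raise ValueError("k_worst must be non-negative")
    if k_worst >= len(results):
        raise ValueError("k_worst must be smaller than the cohort size")
    by_dsc = sorted(results, key=lambda r: (r.dsc, r.patient_id))
    by_mshd = sorted(results, key=lambda r: (-r.mshd_mm, r.patient_id))
    rank_dsc = {r.patient_id: i for i, r in enumerate(by_dsc)}
    rank_mshd = {r.patient_id: i for i, r in enumerate(by_mshd)}
    combined = sorted(
        results, key=lambda r: (rank_dsc[r.patient_id] + rank_mshd[r.patient_id], r.patient_id)
    )
    return [r.patient_id for r in combined[:k_worst]]


def outlier_sensitivity(
    results: Sequence[OverlapResult], k_worst: int
) -> tuple[CohortOverlapSummary, list[str]]:
    """Re-summarise the cohort after removing the k worst-overlap patients."""
    removed = worst_patients(results, k_worst)
    kept = [r for r in results if r.patient_id not in removed]
    return summarise_cohort(kept), removed


@dataclass(frozen=True)
class SubgroupComparison:
    summaries: dict[float, CohortOverlapSummary]
    t2_means_min: dict[float, float]
    t2_test_t: float | None
    t2_test_p: float | None
    test_skipped: bool


def subgroup_compare(
    results: Sequence[OverlapResult],
    timings: Sequence[TimingRecord],
) -> SubgroupComparison:
    """Overlap summaries per slice-thickness subgroup plus an unpaired
    Student t-test on independent-check time (T2) across the two subgroups.

    The test is unpaired because different patients were scanned at each
    thickness.  With fewer than two thickness subgroups, or a subgroup with
    fewer than two timing records, summaries are still emitted and the test
    is skipped with a flag.
    """
    by_thick: dict[float, list[OverlapResult]] = {}
    for r in results:
        by_thick.setdefault(r.slice_thickness_mm, []).append(r)
    summaries = {t: summarise_cohort(rs) for t, rs in sorted(by_thick.items())}

    thickness_of = {r.patient_id: r.slice_thickness_mm for r in results}
    t2_by_thick: dict[float, list[float]] = {}
    for rec in timings:
        t = thickness_of.get(rec.patient_id)
        if t is not None:
            t2_by_thick.setdefault(t, []).append(rec.t2_min)
    t2_means = {t: float(np.mean(v)) for t, v in sorted(t2_by_thick.items())}

    groups = [np.asarray(v) for _, v in sorted(t2_by_thick.items())]
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        return SubgroupComparison(summaries, t2_means, None, None, True)
    # positive t when the thinner-slice subgroup takes longer to check
    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    return SubgroupComparison(summaries, t2_means, float(t), float(p), False)
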