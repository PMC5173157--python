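"""Study evaluation driver and the QA report (JSON + markdown).

The report mirrors the shape of the study's summary table — an OVERLAPPING
ANALYSIS block (per-group MDSC and MSHD with SDs), a TIME ANALYSIS block
(T1/T2/TT means with SDs, paired t-test, both time-saving estimators) — plus
a DECISION block, an outlier-sensitivity block and a slice-thickness
subgroup block.  The JSON form is validated by pydantic models whose schema
is shipped with the package (``report_schema.json``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from . import metrics, qa
from .metrics import CohortOverlapSummary, OverlapResult
from .qa import QACriteria, WorkflowGroup
from .synthetic import CohortDataset

logger = logging.getLogger("contourqa")


# ---------------------------------------------------------------------------
# Report models
# ---------------------------------------------------------------------------

class _Model(BaseModel):
    model_config = ConfigDict(frozen=True)


class OverlapBlock(_Model):
    mdsc: float
    dsc_sd: float
    mshd_mean_mm: float
    mshd_sd_mm: float
    n_patients: int
    n_unmatched_slices: int


class GroupTimeBlock(_Model):
    n: int
    t1_mean_min: float
    t1_sd_min: float
    t2_mean_min: float
    t2_sd_min: float
    tt_mean_min: float
    tt_sd_min: float


class TimeBlock(_Model):
    manual: GroupTimeBlock
    auto: GroupTimeBlock
    saving_ratio_of_means_pct: float
    saving_per_patient_mean_pct: Optional[float]
    paired_t: Optional[float]
    paired_p: Optional[float]
    paired_ci95_min: Optional[tuple[float, float]]


class DecisionBlock(_Model):
    mdsc: float
    mshd_mean_mm: float
    tt_saving_pct: float
    saving_estimator: Literal["ratio-of-means", "per-patient"]
    met: dict[str, bool]
    n_met: int
    mandatory_met: bool
    accepted: bool


class SensitivityBlock(_Model):
    k_removed: int
    removed_patient_ids: list[str]
    mdsc: float
    mshd_mean_mm: float


class SubgroupBlock(_Model):
    thickness_mm: float
    mdsc: float
    mshd_mean_mm: float
    n_patients: int
    t2_mean_min: Optional[float]


class SubgroupSection(_Model):
    subgroups: list[SubgroupBlock]
    t2_test_t: Optional[float]
    t2_test_p: Optional[float]
    test_skipped: bool


class StudyReport(_Model):
    """Full QA report: overlap, time, decision and sensitivity analyses."""

    overlap: dict[str, OverlapBlock]  # keyed by workflow group "A" / "B"
    time: TimeBlock
    decision: DecisionBlock
    outlier_sensitivity: Optional[SensitivityBlock]
    subgroups: SubgroupSection
    criteria: dict[str, float]
    unmatched_policy: str
    missing_timing_patient_ids: list[str]
    provenance: dict


# ---------------------------------------------------------------------------
# Evaluation driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationOptions:
    criteria: QACriteria = QACriteria()
    unmatched_policy: metrics.UnmatchedPolicy = "exclude"
    saving_estimator: Literal["ratio-of-means", "per-patient"] = "ratio-of-means"
    outliers_k: int = 2
    hausdorff_step_mm: float = metrics.DEFAULT_HAUSDORFF_STEP_MM


@dataclass(frozen=True)
class EvaluationOutput:
    report: StudyReport
    results_manual: tuple[OverlapResult, ...]
    results_auto: tuple[OverlapResult, ...]


def _overlap_block(summary: CohortOverlapSummary, results) -> OverlapBlock:
    return OverlapBlock(
        mdsc=summary.mdsc, dsc_sd=summary.dsc_sd,
        mshd_mean_mm=summary.mshd_mean_mm, mshd_sd_mm=summary.mshd_sd_mm,
        n_patients=summary.n_patients,
        n_unmatched_slices=sum(r.n_unmatched_slices for r in results),
    )


def _time_block(g: qa.GroupTimeSummary) -> GroupTimeBlock:
    return GroupTimeBlock(
        n=g.n, t1_mean_min=g.t1_mean, t1_sd_min=g.t1_sd,
        t2_mean_min=g.t2_mean, t2_sd_min=g.t2_sd,
        tt_mean_min=g.tt_mean, tt_sd_min=g.tt_sd,
    )


def evaluate_study(
    dataset: CohortDataset, options: EvaluationOptions = EvaluationOptions()
) -> EvaluationOutput:
    """Run the full QA analysis on a dataset.

    Both delineation arms are compared against the reference per patient;
    the acceptance decision evaluates the automatic arm's cohort summary
    together with the configured time-saving estimator.  Patients with
    contours but no timing record are flagged and skipped in the time
    analysis rather than failing the run.
    """
    results_a, results_b = [], []
    for pid in dataset.test_ids:
        ref = dataset.references[pid]
        for coll, results in ((dataset.manual, results_a), (dataset.auto, results_b)):
            if pid not in coll:
                logger.warning("patient %s missing from one delineation arm", pid)
                continue
            results.append(
                metrics.compare_delineations(
                    ref, coll[pid],
                    unmatched_policy=options.unmatched_policy,
                    step_mm=options.hausdorff_step_mm,
                )
            )
    summary_a = metrics.summarise_cohort(results_a)
    summary_b = metrics.summarise_cohort(results_b)

    timed_ids = {r.patient_id for r in dataset.timings}
    missing_timing = sorted(set(dataset.test_ids) - timed_ids)
    if missing_timing:
        logger.warning("no timing records for patients: %s", missing_timing)

    rec_a = [r for r in dataset.timings if r.group == WorkflowGroup.MANUAL]
    rec_b = [r for r in dataset.timings if r.group == WorkflowGroup.AUTO]
    tsum_a = qa.group_time_summary(rec_a)
    tsum_b = qa.group_time_summary(rec_b)
    saving_rom = qa.time_saving_pct(tsum_a.tt_mean, tsum_b.tt_mean)

    saving_pp = paired = None
    by_id_a = {r.patient_id: r for r in rec_a}
    by_id_b = {r.patient_id: r for r in rec_b}
    common = sorted(set(by_id_a) & set(by_id_b))
    if common:
        _, saving_pp = qa.per_patient_saving(
            [by_id_a[p] for p in common], [by_id_b[p] for p in common]
        )
        if len(common) >= 2:
            diffs = [by_id_a[p].tt_min - by_id_b[p].tt_min for p in common]
            try:
                paired = qa.paired_t_test(diffs)
            except qa.DegenerateTestError:
                logger.warning("paired t-test degenerate (zero variance)")

    saving_used = saving_rom if options.saving_estimator == "ratio-of-means" else saving_pp
    if saving_used is None:
        raise ValueError("per-patient saving estimator requires paired timing records")
    decision = qa.evaluate_acceptance(summary_b, saving_used, options.criteria)

    sensitivity = None
    if 0 < options.outliers_k < len(results_b):
        sens_summary, removed = qa.outlier_sensitivity(results_b, options.outliers_k)
        sensitivity = SensitivityBlock(
            k_removed=options.outliers_k, removed_patient_ids=removed,
            mdsc=sens_summary.mdsc, mshd_mean_mm=sens_summary.mshd_mean_mm,
        )

    sub = qa.subgroup_compare(results_b, rec_b)
    subgroups = SubgroupSection(
        subgroups=[
            SubgroupBlock(
                thickness_mm=t, mdsc=s.mdsc, mshd_mean_mm=s.mshd_mean_mm,
                n_patients=s.n_patients, t2_mean_min=sub.t2_means_min.get(t),
            )
            for t, s in sub.summaries.items()
        ],
        t2_test_t=sub.t2_test_t, t2_test_p=sub.t2_test_p,
        test_skipped=sub.test_skipped,
    )

    report = StudyReport(
        overlap={
            WorkflowGroup.MANUAL.value: _overlap_block(summary_a, results_a),
            WorkflowGroup.AUTO.value: _overlap_block(summary_b, results_b),
        },
        time=TimeBlock(
            manual=_time_block(tsum_a), auto=_time_block(tsum_b),
            saving_ratio_of_means_pct=saving_rom,
            saving_per_patient_mean_pct=saving_pp,
            paired_t=None if paired is None else paired.t_statistic,
            paired_p=None if paired is None else paired.p_value,
            paired_ci95_min=None if paired is None else paired.ci95,
        ),
        decision=DecisionBlock(
            mdsc=decision.observed[0], mshd_mean_mm=decision.observed[1],
            tt_saving_pct=decision.observed[2],
            saving_estimator=options.saving_estimator,
            met=decision.met, n_met=decision.n_met,
            mandatory_met=decision.mandatory_met, accepted=decision.accepted,
        ),
        outlier_sensitivity=sensitivity,
        subgroups=subgroups,
        criteria={
            "dsc_min": options.criteria.dsc_min,
            "mshd_max_mm": options.criteria.mshd_max_mm,
            "tt_saving_min_pct": options.criteria.tt_saving_min_pct,
        },
        unmatched_policy=options.unmatched_policy,
        missing_timing_patient_ids=missing_timing,
        provenance=dict(dataset.provenance),
    )
    return EvaluationOutput(
        report=report,
        results_manual=tuple(results_a),
        results_auto=tuple(results_b),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def report_to_json(report: StudyReport) -> str:
    """Canonical JSON serialisation (sorted keys, deterministic floats)."""
    return json.dumps(report.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"


def render_markdown(report: StudyReport) -> str:
    """Human-readable report in the two-block summary-table layout."""
    a, b = report.overlap["A"], report.overlap["B"]
    t = report.time
    d = report.decision
    lines = [
        "# Auto-delineation QA report",
        "",
        "## OVERLAPPING ANALYSIS",
        "",
        "| metric | Group A (manual) | Group B (automatic) |",
        "|---|---|---|",
        f"| MDSC ± 1SD | {a.mdsc:.2f} (±{a.dsc_sd:.2f}) | {b.mdsc:.2f} (±{b.dsc_sd:.2f}) |",
        f"| MSHD (mm) ± 1SD | {a.mshd_mean_mm:.2f} (±{a.mshd_sd_mm:.2f}) "
        f"| {b.mshd_mean_mm:.2f} (±{b.mshd_sd_mm:.2f}) |",
        "",
        "## TIME ANALYSIS",
        "",
        "| metric | Group A (manual) | Group B (automatic) |",
        "|---|---|---|",
        f"| T1 (min) | {t.manual.t1_mean_min:.2f} (±{t.manual.t1_sd_min:.2f}) "
        f"| {t.auto.t1_mean_min:.2f} (±{t.auto.t1_sd_min:.2f}) |",
        f"| T2 (min) | {t.manual.t2_mean_min:.2f} (±{t.manual.t2_sd_min:.2f}) "
        f"| {t.auto.t2_mean_min:.2f} (±{t.auto.t2_sd_min:.2f}) |",
        f"| TT (min) | {t.manual.tt_mean_min:.2f} (±{t.manual.tt_sd_min:.2f}) "
        f"| {t.auto.tt_mean_min:.2f} (±{t.auto.tt_sd_min:.2f}) |",
        "",
        f"- TT saving (ratio of means): {t.saving_ratio_of_means_pct:.1f}%",
    ]
    if t.saving_per_patient_mean_pct is not None:
        lines.append(f"- TT saving (per-patient mean): {t.saving_per_patient_mean_pct:.1f}%")
    if t.paired_t is not None:
        lines.append(
            f"- Paired t-test on TT: t = {t.paired_t:.2f}, p = {t.paired_p:.2g}, "
            f"95% CI [{t.paired_ci95_min[0]:.2f}, {t.paired_ci95_min[1]:.2f}] min"
        )
    lines += [
        "",
        "## DECISION",
        "",
        f"- Observed: MDSC {d.mdsc:.2f}, MSHD {d.mshd_mean_mm:.2f} mm, "
        f"TT saving {d.tt_saving_pct:.1f}% ({d.saving_estimator})",
        f"- Criteria met: {d.n_met}/3 "
        f"({', '.join(k for k, v in d.met.items() if v) or 'none'})",
        f"- Mandatory time-saving criterion met: {d.mandatory_met}",
        f"- Verdict: {'ACCEPTED' if d.accepted else 'REJECTED'}",
    ]
    if report.outlier_sensitivity is not None:
        s = report.outlier_sensitivity
        lines += [
            "",
            "## OUTLIER SENSITIVITY",
            "",
            f"- Removed {s.k_removed} worst patients: {', '.join(s.removed_patient_ids)}",
            f"- Group B after removal: MDSC {s.mdsc:.2f}, MSHD {s.mshd_mean_mm:.2f} mm",
        ]
    lines += ["", "## SLICE-THICKNESS SUBGROUPS", ""]
    for sg in report.subgroups.subgroups:
        t2 = "n/a" if sg.t2_mean_min is None else f"{sg.t2_mean_min:.2f} min"
        lines.append(
            f"- {sg.thickness_mm:g} mm (n={sg.n_patients}): MDSC {sg.mdsc:.2f}, "
            f"MSHD {sg.mshd_mean_mm:.2f} mm, mean T2 {t2}"
        )
    if not report.subgroups.test_skipped:
        lines.append(
            f"- Unpaired t-test on T2 across thickness groups: "
            f"t = {report.subgroups.t2_test_t:.2f}, p = {report.subgroups.t2_test_p:.2g}"
        )
    else:
        lines.append("- T2 subgroup test skipped (need two subgroups with n >= 2)")
    return "\n".join(lines) + "\n"
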