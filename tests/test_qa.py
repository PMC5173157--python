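"""Time analysis, paired statistics, acceptance decision, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contourqa import (
    DegenerateTestError,
    QACriteria,
    TimingRecord,
    WorkflowGroup,
    decide,
    group_time_summary,
    outlier_sensitivity,
    paired_t_test,
    per_patient_saving,
    subgroup_compare,
    time_saving_pct,
)
from contourqa.qa import worst_patients
from contourqa.synthetic import GroupTimeTargets, TimeModel, simulate_times

from test_metrics import _result


def _rec(pid, group, t1, t2):
    return TimingRecord(patient_id=pid, group=group, t1_min=t1, t2_min=t2)


class TestTimingRecords:
    def test_tt_is_sum(self):
        r = _rec("P1", "A", 13.12, 10.20)
        assert r.tt_min == pytest.approx(23.32)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            _rec("P1", "A", -1.0, 2.0)


class TestGroupTimeSummary:
    def test_single_record_sd_flagged(self):
        s = group_time_summary([_rec("P1", "A", 13.12, 10.20)])
        assert s.t1_mean == pytest.approx(13.12)
        assert s.t1_sd == 0.0 and not s.sd_defined

    def test_tt_mean_is_sum_of_component_means(self):
        records = [_rec("P1", "A", 12.12, 11.20), _rec("P2", "A", 14.12, 9.20)]
        s = group_time_summary(records)
        assert s.t1_mean == pytest.approx(13.12)
        assert s.t2_mean == pytest.approx(10.20)
        assert s.tt_mean == pytest.approx(23.32)

    def test_identical_records_zero_sd(self):
        s = group_time_summary([_rec("P1", "B", 1.0, 9.0), _rec("P2", "B", 1.0, 9.0)])
        assert s.t1_sd == 0.0 and s.tt_sd == 0.0

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            group_time_summary([_rec("P1", "A", 1, 1), _rec("P2", "B", 1, 1)])


class TestTimeSaving:
    def test_halving_is_fifty_percent(self):
        assert time_saving_pct(20.0, 10.0) == pytest.approx(50.0)

    def test_equal_times_zero(self):
        assert time_saving_pct(17.3, 17.3) == 0.0

    def test_table_means_arithmetic(self):
        assert time_saving_pct(23.32, 12.84) == pytest.approx(44.94, abs=0.01)

    def test_slower_automatic_is_negative(self):
        assert time_saving_pct(10.0, 12.0) < 0

    def test_nonpositive_manual_time_rejected(self):
        with pytest.raises(ValueError):
            time_saving_pct(0.0, 5.0)

    @given(a=st.floats(0.1, 1e3), b=st.floats(0.0, 1e3))
    @settings(max_examples=100, derandomize=True)
    def test_algebraic_identity(self, a, b):
        assert time_saving_pct(a, b) + 100.0 * b / a == pytest.approx(100.0, abs=1e-9)

    def test_per_patient_mean(self):
        manual = [_rec("P1", "A", 10, 10), _rec("P2", "A", 5, 5)]
        auto = [_rec("P1", "B", 5, 5), _rec("P2", "B", 4, 5)]
        savings, mean = per_patient_saving(manual, auto)
        assert savings == {"P1": pytest.approx(50.0), "P2": pytest.approx(10.0)}
        assert mean == pytest.approx(30.0)

    def test_unmatched_patients_listed(self):
        with pytest.raises(ValueError, match="P2"):
            per_patient_saving([_rec("P1", "A", 1, 1)], [_rec("P2", "B", 1, 1)])


class TestPairedTTest:
    def test_hand_computed_example(self):
        r = paired_t_test([2.1, 1.9, 2.0, 2.2, 1.8])
        assert r.mean_diff_min == pytest.approx(2.0)
        assert r.t_statistic == pytest.approx(28.284271, abs=1e-4)
        assert r.p_value < 1e-5
        assert r.ci95[0] < 2.0 < r.ci95[1]

    def test_symmetric_diffs_give_t_zero(self):
        r = paired_t_test([1.0, -1.0, 1.0, -1.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_constant_diffs_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t_test([2.0, 2.0, 2.0, 2.0, 2.0])

    def test_matches_scipy_paired(self, rng):
        from scipy import stats

        a, b = rng.normal(20, 4, 12), rng.normal(12, 3, 12)
        r = paired_t_test(a - b)
        t, p = stats.ttest_rel(a, b)
        assert r.t_statistic == pytest.approx(float(t))
        assert r.p_value == pytest.approx(float(p))


class TestAcceptanceDecision:
    def test_study_observed_triple_accepted_two_of_three(self):
        d = decide(0.75, 2.00, 55.5)
        assert d.met == {"dsc": True, "mshd": False, "tt_saving": True}
        assert d.n_met == 2 and d.mandatory_met and d.accepted

    def test_all_criteria_met(self):
        d = decide(0.84, 0.87, 55.5)
        assert d.n_met == 3 and d.accepted

    def test_mandatory_time_criterion_blocks_acceptance(self):
        d = decide(0.80, 0.90, 40.0)
        assert d.n_met == 2 and not d.mandatory_met and not d.accepted

    def test_thresholds_are_inclusive(self):
        d = decide(0.75, 1.00, 50.0)
        assert d.n_met == 3 and d.accepted

    @given(
        mdsc=st.floats(0, 1), mshd=st.floats(0, 10), saving=st.floats(-100, 100),
        d1=st.floats(0, 0.2), d2=st.floats(0, 5), d3=st.floats(0, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_improvement_never_flips_to_reject(self, mdsc, mshd, saving, d1, d2, d3):
        before = decide(mdsc, mshd, saving)
        after = decide(min(mdsc + d1, 1.0), max(mshd - d2, 0.0), saving + d3)
        assert after.accepted or not before.accepted


class TestOutlierSensitivity:
    def test_single_worst_patient_removed(self):
        results = [_result("P1", 1.0, 0.1), _result("P2", 1.0, 0.1), _result("P3", 0.2, 5.0)]
        summary, removed = outlier_sensitivity(results, 1)
        assert removed == ["P3"]
        assert summary.n_patients == 2 and summary.mdsc == 1.0

    def test_k_zero_identity(self):
        results = [_result("P1", 0.9, 1.0), _result("P2", 0.7, 2.0)]
        with pytest.raises(ValueError):
            worst_patients(results, 2)  # k must stay below n
        summary, removed = outlier_sensitivity(results, 0)
        assert removed == [] and summary.n_patients == 2

    def test_ties_broken_by_patient_id(self):
        results = [_result(p, 0.8, 1.0) for p in ("P2", "P1", "P3")]
        assert worst_patients(results, 2) == ["P1", "P2"]


class TestSubgroupCompare:
    def test_single_thickness_skips_test(self):
        results = [_result("P1", 0.9, 1.0), _result("P2", 0.8, 1.5)]
        timings = [_rec("P1", "B", 1, 9), _rec("P2", "B", 1, 10)]
        cmp = subgroup_compare(results, timings)
        assert cmp.test_skipped and list(cmp.summaries) == [5.0]

    def test_detects_injected_ic_time_difference(self):
        # power check on the machinery: tight T2 spread, +2 min at 2.5 mm
        model = TimeModel(
            auto=GroupTimeTargets(1.12, 0.44, 9.72, 1.5),
            ic_thickness_effect_min=2.0,
        )
        n = 40
        thick = [5.0] * n + [2.5] * n
        ids = [f"P{i:03d}" for i in range(2 * n)]
        timings = simulate_times(
            model, 2 * n, WorkflowGroup.AUTO, seed=7,
            slice_thickness_mm=thick, patient_ids=ids,
        )
        results = [_result(pid, 0.9, 1.0, thickness=t) for pid, t in zip(ids, thick)]
        cmp = subgroup_compare(results, timings)
        assert not cmp.test_skipped
        assert cmp.t2_means_min[2.5] > cmp.t2_means_min[5.0]
        assert cmp.t2_test_t > 0 and cmp.t2_test_p < 0.05

    def test_type_one_error_calibration(self):
        # identical T2 distributions: p-values roughly uniform over replicates
        model = TimeModel(ic_thickness_effect_min=0.0)
        ps = []
        for seed in range(40):
            thick = [5.0] * 10 + [2.5] * 10
            ids = [f"P{i:03d}" for i in range(20)]
            timings = simulate_times(
                model, 20, WorkflowGroup.AUTO, seed=seed,
                slice_thickness_mm=thick, patient_ids=ids,
            )
            results = [_result(pid, 0.9, 1.0, thickness=t) for pid, t in zip(ids, thick)]
            ps.append(subgroup_compare(results, timings).t2_test_p)
        assert 0.25 < float(np.mean(ps)) < 0.75
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2


class TestCriteriaValidation:
    def test_required_met_bounds(self):
        with pytest.raises(ValueError):
            QACriteria(required_met=4)

    def test_unknown_mandatory_rejected(self):
        with pytest.raises(ValueError):
            QACriteria(mandatory="volume")
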