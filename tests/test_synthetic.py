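"""Synthetic cohort generator: shapes, perturbation, timing, determinism."""

import numpy as np
import pytest

from contourqa import (
    GenerationError,
    OutlierBump,
    PerturbModel,
    ShapeParams,
    SyntheticConfig,
    TimeModel,
    WorkflowGroup,
    compare_delineations,
    generate_cohort,
    generate_reference,
    patient_dsc,
    patient_mshd,
    perturb,
    simulate_times,
    summarise_cohort,
)
from contourqa.synthetic import GroupTimeTargets, lognormal_params

CIRCLE = ShapeParams(
    n_slices=6, slice_thickness_mm=5.0, radius_mm=15.0,
    taper=1.0, fourier_amps=(), centre_drift_mm=0.0,
)

SMALL_COHORT = SyntheticConfig(
    n_patients=24, n_atlas=4, n_coarse=14,
    radius_mm_range=(14.0, 18.0), axial_extent_mm_range=(30.0, 50.0),
    taper=0.85, centre_drift_mm=4.0,
)


class TestGenerateReference:
    def test_plain_cylinder_has_constant_vertex_radius(self):
        ref = generate_reference(CIRCLE, seed=1)
        for c in ref.contours:
            assert np.allclose(np.hypot(*c.xy.T), 15.0, atol=1e-9)

    def test_same_seed_identical_vertices(self):
        shape = ShapeParams(n_slices=5, radius_mm=20.0)
        assert generate_reference(shape, 7) == generate_reference(shape, 7)

    def test_different_seed_differs(self):
        shape = ShapeParams(n_slices=5, radius_mm=20.0)
        assert generate_reference(shape, 7) != generate_reference(shape, 8)

    def test_z_grid_arithmetic(self):
        ref = generate_reference(ShapeParams(n_slices=10, slice_thickness_mm=5.0), seed=0)
        z = ref.z_values
        assert z[-1] - z[0] == pytest.approx(45.0)
        assert ref.n_slices == 10

    def test_excessive_harmonics_raise_generation_error(self):
        bad = ShapeParams(n_slices=3, fourier_amps=(1.5,))
        with pytest.raises(GenerationError):
            generate_reference(bad, seed=0)


class TestPerturb:
    def test_null_model_is_identity(self):
        ref = generate_reference(ShapeParams(n_slices=5), seed=3)
        assert perturb(ref, PerturbModel(), seed=99) == ref

    def test_pure_bias_on_cylinder_matches_closed_forms(self):
        ref = generate_reference(CIRCLE, seed=1, patient_id="C")
        pert = perturb(ref, PerturbModel(radial_bias_mm=2.0), seed=2)
        mshd, _, _ = patient_mshd(ref, pert)
        assert mshd == pytest.approx(2.0, abs=1e-9)
        r = 15.0
        assert patient_dsc(ref, pert) == pytest.approx(
            2 * r**2 / (r**2 + (r + 2.0) ** 2), abs=1e-12
        )

    def test_truncation_bookkeeping_downstream(self):
        ref = generate_reference(ShapeParams(n_slices=10), seed=5, patient_id="T")
        model = PerturbModel(truncation_prob=1.0, truncation_max_slices=2)
        pert = perturb(ref, model, seed=6)
        dropped = ref.n_slices - pert.n_slices
        assert 1 <= dropped <= 2
        result = compare_delineations(ref, pert)
        assert result.n_unmatched_slices == dropped

    def test_bump_outlier_degrades_metrics(self):
        ref = generate_reference(ShapeParams(n_slices=8, radius_mm=15.0), seed=9, patient_id="O")
        plain = perturb(ref, PerturbModel(radial_sigma_mm=1.0), seed=10)
        bumped = perturb(
            ref,
            PerturbModel(radial_sigma_mm=1.0, outlier=OutlierBump(amplitude_mm=12.0)),
            seed=10,
        )
        r_plain = compare_delineations(ref, plain)
        r_bump = compare_delineations(ref, bumped)
        assert r_bump.mshd_mm > r_plain.mshd_mm + 3.0
        assert r_bump.dsc < r_plain.dsc

    def test_collapsing_displacement_rejected(self):
        ref = generate_reference(CIRCLE, seed=1)
        with pytest.raises(GenerationError):
            perturb(ref, PerturbModel(radial_bias_mm=-15.0), seed=0)

    def test_determinism(self):
        ref = generate_reference(ShapeParams(n_slices=4), seed=0)
        model = PerturbModel(radial_bias_mm=1.0, radial_sigma_mm=2.0)
        assert perturb(ref, model, 5) == perturb(ref, model, 5)
        assert perturb(ref, model, 5) != perturb(ref, model, 6)


class TestSimulateTimes:
    def test_moment_matching_is_analytic(self):
        mu, sigma = lognormal_params(13.12, 4.84)
        mean = np.exp(mu + sigma**2 / 2)
        sd = mean * np.sqrt(np.expm1(sigma**2))
        assert mean == pytest.approx(13.12, rel=1e-12)
        assert sd == pytest.approx(4.84, rel=1e-12)

    def test_single_draw_positive(self):
        recs = simulate_times(TimeModel(), 1, WorkflowGroup.AUTO, seed=0)
        assert len(recs) == 1 and recs[0].t1_min > 0 and recs[0].t2_min > 0

    def test_thickness_effect_shifts_t2(self):
        model = TimeModel(ic_thickness_effect_min=2.0)
        coarse = simulate_times(model, 4000, WorkflowGroup.AUTO, seed=1,
                                slice_thickness_mm=5.0)
        fine = simulate_times(model, 4000, WorkflowGroup.AUTO, seed=1,
                              slice_thickness_mm=2.5)
        shift = np.mean([r.t2_min for r in fine]) - np.mean([r.t2_min for r in coarse])
        assert shift == pytest.approx(2.0, abs=0.4)

    def test_invalid_targets_rejected(self):
        with pytest.raises(GenerationError):
            GroupTimeTargets(10.0, -1.0, 5.0, 1.0)


class TestGenerateCohort:
    def test_default_layout_counts(self):
        ds = generate_cohort(SyntheticConfig(), seed=123)
        assert len(ds.profiles) == 44
        assert sum(p.role == "atlas" for p in ds.profiles) == 14
        assert len(ds.test_ids) == 30
        for pid in ds.test_ids:
            assert pid in ds.manual and pid in ds.auto
        coarse = [p for p in ds.profiles if p.slice_thickness_mm == 5.0]
        fine = [p for p in ds.profiles if p.slice_thickness_mm == 2.5]
        assert len(coarse) == 29 and len(fine) == 15
        atlas_sex = [p.sex for p in ds.profiles if p.role == "atlas"]
        assert atlas_sex.count("F") == 8 and atlas_sex.count("M") == 6
        assert len(ds.timings) == 60  # paired manual/auto per test patient

    def test_outlier_ids_recorded_and_applied(self):
        ds = generate_cohort(SMALL_COHORT, seed=5)
        outliers = ds.provenance["outlier_patient_ids"]
        assert len(outliers) == SMALL_COHORT.outlier_count
        worst = sorted(
            ds.test_ids,
            key=lambda pid: -compare_delineations(ds.references[pid], ds.auto[pid]).mshd_mm,
        )[: len(outliers)]
        assert sorted(worst) == outliers

    def test_full_determinism(self):
        a = generate_cohort(SMALL_COHORT, seed=77)
        b = generate_cohort(SMALL_COHORT, seed=77)
        assert a.profiles == b.profiles
        assert a.references == b.references
        assert a.manual == b.manual and a.auto == b.auto
        assert a.timings == b.timings and a.provenance == b.provenance

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=10, n_atlas=10)
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=10, n_atlas=4, outlier_count=7)

    def test_profiles_internally_consistent(self):
        ds = generate_cohort(SMALL_COHORT, seed=2)
        for p in ds.profiles:
            implied = p.weight_kg / (p.height_cm / 100.0) ** 2
            assert p.bmi == pytest.approx(implied, rel=0.02)


class TestNearThresholdCohort:
    def test_accept_decision_recovered_at_decision_boundary(self):
        """A cohort tuned so MDSC sits just above 0.75 with MSHD well above
        1 mm and ~55% time saving must be accepted with exactly the DSC and
        time-saving criteria met."""
        from contourqa import EvaluationOptions, evaluate_study
        from contourqa.synthetic import GroupTimeTargets

        config = SyntheticConfig(
            n_patients=24, n_atlas=4, n_coarse=14,
            radius_mm_range=(12.0, 16.0), axial_extent_mm_range=(30.0, 50.0),
            centre_drift_mm=4.0,
            auto_perturb=PerturbModel(radial_bias_mm=3.0, radial_sigma_mm=1.5),
            outlier_count=0,
            time_model=TimeModel(
                manual=GroupTimeTargets(13.12, 2.0, 10.20, 2.0),
                auto=GroupTimeTargets(1.12, 0.44, 9.26, 2.0),
                ic_thickness_effect_min=0.0,
            ),
        )
        ds = generate_cohort(config, seed=11)
        report = evaluate_study(ds, EvaluationOptions(outliers_k=0)).report
        assert 0.75 <= report.overlap["B"].mdsc < 0.85
        assert report.overlap["B"].mshd_mean_mm > 1.0
        assert report.decision.met == {"dsc": True, "mshd": False, "tt_saving": True}
        assert report.decision.accepted


class TestCalibration:
    def test_manual_arm_beats_auto_arm_across_replicates(self):
        """Expert-level noise (bias 0.5/σ1) must outperform auto-level noise
        (bias 1/σ2) in nearly every replicate cohort."""
        config = SMALL_COHORT.model_copy(update={"n_patients": 14, "outlier_count": 0})
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            ds = generate_cohort(config, seed=1000 + rep)
            res_a = [
                compare_delineations(ds.references[p], ds.manual[p]) for p in ds.test_ids
            ]
            res_b = [
                compare_delineations(ds.references[p], ds.auto[p]) for p in ds.test_ids
            ]
            sa, sb = summarise_cohort(res_a), summarise_cohort(res_b)
            if sa.mdsc > sb.mdsc and sa.mshd_mean_mm < sb.mshd_mean_mm:
                wins += 1
        assert wins >= 0.95 * n_rep
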