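"""Seeded synthetic cohort generator for auto-delineation QA studies.

The generator emulates the inputs of a rectal-CTV validation study: for each
test patient a reference delineation (standing in for the expert-agreed
master contour), an "expert manual" and an "auto-segmented" perturbation of
it, patient profiles for atlas matching, and per-patient timing logs.

Shapes are tapered tubes whose axial cross-sections are low-order Fourier
perturbations of a circle — CTV-like in scale (a few cm radius, ~11 cm
cranio-caudal extent) without pretending to be pelvic anatomy.  Boundary
disagreement is modelled as a systematic radial bias plus a spatially
correlated Gaussian radial field (smooth disagreement, not vertex jitter),
optional cranio-caudal truncation, and an optional localized "bump" outlier
emulating grossly irregular anatomy.  Delineation times are lognormal,
moment-matched to target means/SDs in minutes.

Everything is a pure function of the configuration and a master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter1d

from .atlas import STAGE_LEVELS, PatientProfile
from .geometry import (
    DegenerateContourError,
    PlanarContour,
    StructureDelineation,
    clean_contour,
)
from .qa import TimingRecord, WorkflowGroup


class GenerationError(ValueError):
    """Raised when parameters yield an invalid shape or perturbation."""


# ---------------------------------------------------------------------------
# Reference shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Axial-stack shape family: tapered tube with Fourier-irregular sections.

    ``taper`` is the end-slice radius as a fraction of ``radius_mm`` (1.0
    gives a constant-radius cylinder); ``fourier_amps`` are relative
    amplitudes of angular harmonics starting at k=2 (k=1 is mostly a
    translation and is covered by the centre drift); ``centre_drift_mm`` is
    the amplitude of a smooth in-plane path of the slice centres.
    """

    n_slices: int = 22
    slice_thickness_mm: float = 5.0
    radius_mm: float = 32.0
    taper: float = 0.45
    fourier_amps: tuple[float, ...] = (0.08, 0.04, 0.02)
    centre_drift_mm: float = 6.0
    n_vertices: int = 180
    z0_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.radius_mm <= 0 or self.slice_thickness_mm <= 0:
            raise GenerationError("n_slices, radius and thickness must be positive")
        if not (0.0 < self.taper <= 1.0):
            raise GenerationError("taper must be in (0, 1]")
        if self.n_vertices < 8:
            raise GenerationError("need at least 8 boundary vertices")

    def base_radius(self, i: np.ndarray) -> np.ndarray:
        """Smooth axial radius profile with tapered ends, slice index i."""
        u = (np.asarray(i, dtype=float) + 0.5) / self.n_slices
        return self.radius_mm * (self.taper + (1.0 - self.taper) * np.sin(np.pi * u) ** 0.8)

    def centre(self, i: np.ndarray) -> np.ndarray:
        u = (np.asarray(i, dtype=float) + 0.5) / self.n_slices
        return np.stack(
            [self.centre_drift_mm * np.sin(np.pi * u),
             0.5 * self.centre_drift_mm * np.sin(2.0 * np.pi * u)],
            axis=-1,
        )


def generate_reference(
    shape: ShapeParams, seed: int, patient_id: str = "SYN", label: str = "CTV"
) -> StructureDelineation:
    """One closed polygon per slice, r(θ,z) = base(z)·(1 + Σ aₖ cos(kθ+φₖ)).

    The harmonic phases are the only random element; the result is a pure
    function of (shape, seed).
    """
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(shape.fourier_amps))
    theta = 2.0 * np.pi * np.arange(shape.n_vertices) / shape.n_vertices
    modulation = np.ones_like(theta)
    for k, (amp, phi) in enumerate(zip(shape.fourier_amps, phases), start=2):
        modulation += amp * np.cos(k * theta + phi)
    contours = []
    for i in range(shape.n_slices):
        r = shape.base_radius(i) * modulation
        if np.any(r <= 0):
            raise GenerationError(f"non-positive radius on slice index {i}")
        c = shape.centre(i)
        xy = c + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        z = shape.z0_mm + i * shape.slice_thickness_mm
        try:
            contours.append(clean_contour(xy, z_mm=z))
        except DegenerateContourError as exc:  # pragma: no cover - defensive
            raise GenerationError(f"invalid polygon on slice index {i}: {exc}") from exc
    return StructureDelineation(
        patient_id=patient_id, label=label,
        slice_thickness_mm=shape.slice_thickness_mm, contours=tuple(contours),
    )


# ---------------------------------------------------------------------------
# Boundary perturbation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierBump:
    """Localized radial protrusion emulating grossly irregular anatomy."""

    amplitude_mm: float = 12.0
    angular_width_deg: float = 50.0
    slice_span_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise GenerationError("bump amplitude must be non-negative")
        if not (0 < self.slice_span_frac <= 1):
            raise GenerationError("slice_span_frac must be in (0, 1]")


@dataclass(frozen=True)
class PerturbModel:
    """Radial boundary-perturbation model.

    ``radial_bias_mm`` is a systematic over(+)/under(−)-contouring offset;
    ``radial_sigma_mm`` the SD of a correlated Gaussian radial field whose
    smoothness along the boundary and across slices is set by
    ``angular_corr`` and ``axial_corr`` (correlation lengths as fractions of
    the circumference and of the axial extent, both in (0, 1]).
    ``truncation_prob``/``truncation_max_slices`` optionally drop end slices
    (cranio-caudal extent disagreement).
    """

    radial_bias_mm: float = 0.0
    radial_sigma_mm: float = 0.0
    angular_corr: float = 0.2
    axial_corr: float = 0.5
    truncation_prob: float = 0.0
    truncation_max_slices: int = 0
    outlier: OutlierBump | None = None
    min_radius_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.radial_sigma_mm < 0:
            raise GenerationError("radial_sigma_mm must be non-negative")
        for name in ("angular_corr", "axial_corr"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise GenerationError(f"{name} must be in (0, 1]")
        if not (0.0 <= self.truncation_prob <= 1.0):
            raise GenerationError("truncation_prob must be a probability")


_N_THETA_GRID = 256  # angular resolution of the correlated noise field


def _correlated_field(rng: np.random.Generator, n_z: int, model: PerturbModel) -> np.ndarray:
    """(n_z, n_theta) radial noise field with SD radial_sigma_mm.

    Spectral-style synthesis: white Gaussian noise low-pass filtered along
    the (periodic) boundary parameter and across slices, then rescaled to
    the requested standard deviation.
    """
    white = rng.standard_normal((n_z, _N_THETA_GRID))
    if model.radial_sigma_mm == 0.0:
        return np.zeros_like(white)
    sig_theta = max(model.angular_corr * _N_THETA_GRID / 4.0, 1e-9)
    fld = gaussian_filter1d(white, sigma=sig_theta, axis=1, mode="wrap")
    if n_z > 1:
        sig_z = max(model.axial_corr * n_z / 2.0, 1e-9)
        fld = gaussian_filter1d(fld, sigma=sig_z, axis=0, mode="nearest")
    s = fld.std()
    if s == 0.0:  # pragma: no cover - filtered white noise is never constant
        return np.zeros_like(fld)
    return fld * (model.radial_sigma_mm / s)


def perturb(
    reference: StructureDelineation, model: PerturbModel, seed: int
) -> StructureDelineation:
    """Displace every boundary vertex radially about its slice centroid.

    Displacement = bias + correlated noise + optional bump; afterwards end
    slices may be truncated.  With an all-zero model the output vertices are
    bit-identical to the reference.  Raises :class:`GenerationError` when a
    displacement collapses a slice below the minimum radius or produces a
    self-intersecting polygon.
    """
    rng = np.random.default_rng(seed)
    slices = list(reference.slices().items())
    n_z = len(slices)
    noise = _correlated_field(rng, n_z, model)
    theta_grid = 2.0 * np.pi * np.arange(_N_THETA_GRID) / _N_THETA_GRID

    bump_theta0 = rng.uniform(0.0, 2.0 * np.pi)
    bump_centre = 0.5 * (n_z - 1)

    drop_head = drop_tail = 0
    if model.truncation_max_slices > 0 and rng.random() < model.truncation_prob:
        k = int(rng.integers(1, model.truncation_max_slices + 1))
        if rng.random() < 0.5:
            drop_head = k
        else:
            drop_tail = k

    new_contours: list[PlanarContour] = []
    for i, (z, contours) in enumerate(slices):
        if i < drop_head or i >= n_z - drop_tail:
            continue
        for contour in contours:
            xy = contour.xy
            centre = xy.mean(axis=0)
            rel = xy - centre
            r = np.hypot(rel[:, 0], rel[:, 1])
            if np.any(r == 0):
                raise GenerationError(f"vertex at slice centroid on z={z}")
            unit = rel / r[:, None]
            theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
            disp = model.radial_bias_mm + np.interp(
                theta, theta_grid, noise[i], period=2.0 * np.pi
            )
            if model.outlier is not None:
                w = np.deg2rad(model.outlier.angular_width_deg) / 2.0
                dtheta = np.angle(np.exp(1j * (theta - bump_theta0)))
                span = max(model.outlier.slice_span_frac * n_z / 2.0, 0.5)
                envelope = np.exp(-0.5 * ((i - bump_centre) / span) ** 2)
                disp = disp + model.outlier.amplitude_mm * envelope * np.exp(
                    -0.5 * (dtheta / w) ** 2
                )
            if np.any(r + disp < model.min_radius_mm):
                raise GenerationError(
                    f"perturbation collapses slice z={z} below "
                    f"{model.min_radius_mm} mm radius"
                )
            if np.all(disp == 0.0):
                new_contours.append(contour)
                continue
            try:
                new_contours.append(clean_contour(xy + disp[:, None] * unit, z_mm=z))
            except DegenerateContourError as exc:
                raise GenerationError(f"perturbed slice z={z} is degenerate: {exc}") from exc
    return StructureDelineation(
        patient_id=reference.patient_id, label=reference.label,
        slice_thickness_mm=reference.slice_thickness_mm,
        contours=tuple(new_contours),
    )


# ---------------------------------------------------------------------------
# Timing model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTimeTargets:
    """Target mean/SD (minutes) of T1 and T2 for one workflow group."""

    t1_mean: float
    t1_sd: float
    t2_mean: float
    t2_sd: float

    def __post_init__(self) -> None:
        for name in ("t1_mean", "t1_sd", "t2_mean", "t2_sd"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")


@dataclass(frozen=True)
class TimeModel:
    """Lognormal delineation-time model, moment-matched to target moments.

    Defaults reproduce the study conditions: manual contouring 13.12±4.84
    min with a 10.20±5.15 min independent check, automatic delineation
    1.12±0.44 min with a 9.72±8.67 min check.  ``ic_thickness_effect_min``
    shifts the independent-check (T2) target mean for thin-slice (2.5 mm)
    patients, whose contour stacks take longer to review.
    """

    manual: GroupTimeTargets = field(
        default_factory=lambda: GroupTimeTargets(13.12, 4.84, 10.20, 5.15)
    )
    auto: GroupTimeTargets = field(
        default_factory=lambda: GroupTimeTargets(1.12, 0.44, 9.72, 8.67)
    )
    ic_thickness_effect_min: float = 2.0
    fine_thickness_mm: float = 2.5

    def targets(self, group: WorkflowGroup) -> GroupTimeTargets:
        return self.manual if group == WorkflowGroup.MANUAL else self.auto


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and SD (exact)."""
    if mean <= 0 or sd <= 0:
        raise GenerationError("lognormal targets must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def simulate_times(
    model: TimeModel,
    n: int,
    group: WorkflowGroup | str,
    seed: int,
    slice_thickness_mm: float | Sequence[float] = 5.0,
    patient_ids: Sequence[str] | None = None,
) -> list[TimingRecord]:
    """Draw n timing records for one workflow group.

    T1 and T2 are independent lognormal draws whose parameters are matched
    analytically to the target mean/SD; the T2 target mean is shifted by the
    thickness effect for fine-slice patients.
    """
    if n < 1:
        raise GenerationError("n must be >= 1")
    group = WorkflowGroup(group)
    tgt = model.targets(group)
    thick = np.broadcast_to(np.asarray(slice_thickness_mm, dtype=float), (n,))
    if patient_ids is None:
        patient_ids = [f"S{i + 1:03d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    mu1, s1 = lognormal_params(tgt.t1_mean, tgt.t1_sd)
    t1 = np.exp(mu1 + s1 * rng.standard_normal(n))
    t2 = np.empty(n)
    z = rng.standard_normal(n)
    for idx in range(n):
        mean2 = tgt.t2_mean + (
            model.ic_thickness_effect_min if thick[idx] == model.fine_thickness_mm else 0.0
        )
        mu2, s2 = lognormal_params(mean2, tgt.t2_sd)
        t2[idx] = np.exp(mu2 + s2 * z[idx])
    return [
        TimingRecord(patient_id=pid, group=group, t1_min=float(a), t2_min=float(b))
        for pid, a, b in zip(patient_ids, t1, t2)
    ]


# ---------------------------------------------------------------------------
# Cohort configuration and assembly
# ---------------------------------------------------------------------------

class SyntheticConfig(BaseModel):
    """All generator parameters for a full study cohort.

    Defaults lay out the study conditions: 44 patients of which the first 14
    populate the atlas library and 30 are test patients; the first 29
    scanned at 5 mm slice thickness, the remaining 15 at 2.5 mm; per test
    patient one reference plus an expert-manual (group A) and an automatic
    (group B) perturbation, the automatic arm noisier and carrying two
    irregular-anatomy outliers.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = 44
    n_atlas: int = 14
    n_coarse: int = 29  # patients scanned at coarse slice thickness, counted first
    coarse_thickness_mm: float = 5.0
    fine_thickness_mm: float = 2.5
    label: str = "CTV"

    radius_mm_range: tuple[float, float] = (28.0, 40.0)
    axial_extent_mm_range: tuple[float, float] = (100.0, 130.0)
    taper: float = 0.45
    fourier_amps: tuple[float, ...] = (0.08, 0.04, 0.02)
    centre_drift_mm: float = 6.0
    n_vertices: int = 180

    manual_perturb: PerturbModel = PerturbModel(
        radial_bias_mm=0.5, radial_sigma_mm=1.0
    )
    auto_perturb: PerturbModel = PerturbModel(
        radial_bias_mm=1.0, radial_sigma_mm=2.0,
        truncation_prob=0.2, truncation_max_slices=1,
    )
    outlier_count: int = 2
    outlier_bump: OutlierBump = OutlierBump()

    time_model: TimeModel = TimeModel()
    seed: int = 0

    @model_validator(mode="after")
    def _check_layout(self) -> "SyntheticConfig":
        if not (0 < self.n_atlas < self.n_patients):
            raise ValueError("need 0 < n_atlas < n_patients")
        if not (0 <= self.n_coarse <= self.n_patients):
            raise ValueError("n_coarse must be within the cohort")
        if self.outlier_count > self.n_patients - self.n_atlas:
            raise ValueError("more outliers than test patients")
        if self.radius_mm_range[0] > self.radius_mm_range[1] or self.radius_mm_range[0] <= 0:
            raise ValueError("invalid radius range")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class CohortDataset:
    """Everything the analysis consumes, as generated from one seed."""

    profiles: tuple[PatientProfile, ...]
    references: dict[str, StructureDelineation]
    manual: dict[str, StructureDelineation]
    auto: dict[str, StructureDelineation]
    timings: tuple[TimingRecord, ...]
    provenance: dict

    @property
    def test_ids(self) -> list[str]:
        return sorted(self.references)


def _make_profile(pid, role, thickness, rng) -> PatientProfile:
    sex = None  # set by caller for atlas patients; drawn here for test
    age = float(np.round(rng.uniform(40.0, 80.0), 1))
    height = float(np.clip(np.round(rng.normal(168.0, 9.0), 1), 150.0, 195.0))
    bmi = float(np.clip(np.round(rng.normal(26.0, 3.5), 1), 18.0, 38.0))
    weight = float(np.round(bmi * (height / 100.0) ** 2, 1))
    stage = str(rng.choice(STAGE_LEVELS, p=[0.2, 0.6, 0.2]))
    local = str(rng.choice(["low", "mid"]))
    sex = str(rng.choice(["F", "M"]))
    fertile = "fertile" if (sex == "F" and age < 50.0) else "non_fertile"
    return PatientProfile(
        patient_id=pid, role=role, stage=stage, tumor_localization=local,
        sex=sex, age=age, weight_kg=weight, height_cm=height,
        bmi=round(weight / (height / 100.0) ** 2, 2), fertility_state=fertile,
        sacro_coccygeal_mm=float(np.round(rng.normal(120.0, 12.0), 1)),
        inter_iliac_mm=float(np.round(rng.normal(270.0, 18.0), 1)),
        slice_thickness_mm=thickness,
    )


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> CohortDataset:
    """Assemble the full synthetic study from a configuration and seed.

    Every artifact — profiles, reference/manual/auto delineations, timing
    logs, outlier assignment — is a pure function of (config, master seed);
    sub-seeds are derived with ``numpy.random.SeedSequence.spawn``.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    (profile_ss, shape_ss, manual_ss, auto_ss, time_ss, pick_ss) = ss.spawn(6)

    n = config.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]
    thicknesses = [
        config.coarse_thickness_mm if i < config.n_coarse else config.fine_thickness_mm
        for i in range(n)
    ]
    roles = ["atlas" if i < config.n_atlas else "test" for i in range(n)]

    prof_rng = np.random.default_rng(profile_ss)
    profiles = []
    # atlas library sex split fixed at 8 female / 6 male (scaled for other sizes)
    n_female_atlas = round(config.n_atlas * 8 / 14)
    for i, (pid, role, thick) in enumerate(zip(ids, roles, thicknesses)):
        p = _make_profile(pid, role, thick, prof_rng)
        if role == "atlas":
            sex = "F" if i < n_female_atlas else "M"
            fertile = "fertile" if (sex == "F" and p.age < 50.0) else "non_fertile"
            p = dataclasses.replace(p, sex=sex, fertility_state=fertile)
        profiles.append(p)

    test_idx = [i for i, r in enumerate(roles) if r == "test"]
    test_ids = [ids[i] for i in test_idx]
    pick_rng = np.random.default_rng(pick_ss)
    outlier_ids = sorted(
        pick_rng.choice(test_ids, size=config.outlier_count, replace=False).tolist()
    ) if config.outlier_count else []

    shape_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in shape_ss.spawn(len(test_idx))]
    manual_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in manual_ss.spawn(len(test_idx))]
    auto_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in auto_ss.spawn(len(test_idx))]

    shape_rng = np.random.default_rng(shape_ss)
    references, manual, auto = {}, {}, {}
    for j, i in enumerate(test_idx):
        pid, thick = ids[i], thicknesses[i]
        radius = float(shape_rng.uniform(*config.radius_mm_range))
        extent = float(shape_rng.uniform(*config.axial_extent_mm_range))
        shape = ShapeParams(
            n_slices=max(4, round(extent / thick)),
            slice_thickness_mm=thick,
            radius_mm=radius,
            taper=config.taper,
            fourier_amps=config.fourier_amps,
            centre_drift_mm=config.centre_drift_mm,
            n_vertices=config.n_vertices,
        )
        ref = generate_reference(shape, shape_seeds[j], patient_id=pid, label=config.label)
        references[pid] = ref
        manual[pid] = perturb(ref, config.manual_perturb, manual_seeds[j])
        auto_model = config.auto_perturb
        if pid in outlier_ids:
            auto_model = replace(auto_model, outlier=config.outlier_bump)
        auto[pid] = perturb(ref, auto_model, auto_seeds[j])

    t_manual_ss, t_auto_ss = time_ss.spawn(2)
    test_thick = [thicknesses[i] for i in test_idx]
    timings = simulate_times(
        config.time_model, len(test_ids), WorkflowGroup.MANUAL,
        int(t_manual_ss.generate_state(1)[0] % (2**31)),
        slice_thickness_mm=test_thick, patient_ids=test_ids,
    ) + simulate_times(
        config.time_model, len(test_ids), WorkflowGroup.AUTO,
        int(t_auto_ss.generate_state(1)[0] % (2**31)),
        slice_thickness_mm=test_thick, patient_ids=test_ids,
    )

    provenance = {
        "config_sha256": config.config_hash(),
        "master_seed": int(master),
        "outlier_patient_ids": outlier_ids,
        "n_test_patients": len(test_ids),
    }
    return CohortDataset(
        profiles=tuple(profiles),
        references=references, manual=manual, auto=auto,
        timings=tuple(timings),
        provenance=provenance,
    )
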