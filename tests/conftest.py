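"""Shared fixtures: canonical shapes and small delineation builders."""

from __future__ import annotations

import numpy as np
import pytest

from contourqa import PlanarContour, StructureDelineation, clean_contour


def make_disc(
    radius: float,
    n: int = 256,
    centre: tuple[float, float] = (0.0, 0.0),
    z: float = 0.0,
) -> PlanarContour:
    """Regular n-gon approximation of a disc with vertices at fixed angles.

    Two discs built with the same n share vertex angles, so a concentric
    pair has exactly the analytic Hausdorff distance (the radius gap) and
    exactly the analytic area ratio (polygon area is c(n)·r^2).
    """
    theta = 2.0 * np.pi * np.arange(n) / n
    xy = np.stack(
        [centre[0] + radius * np.cos(theta), centre[1] + radius * np.sin(theta)], axis=1
    )
    return clean_contour(xy, z_mm=z)


def make_square(side: float, origin=(0.0, 0.0), z: float = 0.0) -> PlanarContour:
    x0, y0 = origin
    return clean_contour(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)], z_mm=z
    )


def stack(contours, patient_id="T", label="CTV", thickness=5.0) -> StructureDelineation:
    return StructureDelineation(
        patient_id=patient_id, label=label,
        slice_thickness_mm=thickness, contours=tuple(contours),
    )


def cylinder(radius, n_slices, thickness=5.0, patient_id="T", n=256) -> StructureDelineation:
    return stack(
        [make_disc(radius, n=n, z=i * thickness) for i in range(n_slices)],
        patient_id=patient_id, thickness=thickness,
    )


def random_star(rng, radius=8.0, irregularity=0.3, n=40, z=0.0) -> PlanarContour:
    """Random star-shaped simple polygon around the origin."""
    theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    r = radius * (1.0 + irregularity * rng.uniform(-1.0, 1.0, n))
    xy = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return clean_contour(xy, z_mm=z)


def rigid_transform(d: StructureDelineation, angle_rad: float, shift):
    """Apply one in-plane rotation + translation to every contour."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    moved = [
        clean_contour(contour.xy @ rot.T + np.asarray(shift), z_mm=contour.z_mm)
        for contour in d.contours
    ]
    return stack(moved, patient_id=d.patient_id, label=d.label,
                 thickness=d.slice_thickness_mm)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
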