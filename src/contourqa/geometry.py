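"""Planar-contour data model and polygon geometry primitives.

All coordinates are patient-space millimetres.  A structure delineation is a
stack of simple closed polygons grouped by axial slice position ``z``; more
than one polygon on a slice is treated as the union of their interiors (holes
are not modelled).  Areas and intersections are computed with exact polygon
boolean operations (shapely), never by rasterisation, so raster resolution is
not a hidden parameter of any metric built on top of this module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

#: Tolerance for merging consecutive duplicate vertices (mm).
DUPLICATE_TOL_MM = 1e-9
#: Tolerance for snapping slice positions when matching two delineations (mm).
Z_MATCH_TOL_MM = 0.01
#: Tolerance for the common-grid-step invariant on slice positions (mm).
Z_GRID_TOL_MM = 1e-6


class DegenerateContourError(ValueError):
    """Raised when a contour cannot form a simple polygon of nonzero area."""


class DelineationError(ValueError):
    """Raised for structurally invalid delineations (grid, thickness, ...)."""


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

def _signed_area(xy: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as an (n, 2) array."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class PlanarContour:
    """A simple closed polygon on one axial slice.

    Closure is implicit (the last vertex connects back to the first) and the
    orientation is counter-clockwise after :func:`clean_contour`.
    """

    z_mm: float
    vertices: tuple[tuple[float, float], ...]

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_mm2(self) -> float:
        return abs(_signed_area(self.xy))

    @property
    def perimeter_mm(self) -> float:
        xy = self.xy
        return float(np.sum(np.hypot(*(np.roll(xy, -1, axis=0) - xy).T)))


def clean_contour(
    raw_vertices: Sequence[Sequence[float]] | np.ndarray,
    z_mm: float = 0.0,
) -> PlanarContour:
    """Normalise a raw vertex list into a valid :class:`PlanarContour`.

    Consecutive duplicate points (within ``DUPLICATE_TOL_MM``) are removed,
    an explicit closing vertex is dropped, and the orientation is normalised
    to counter-clockwise.  The shape itself is never simplified: collinear
    runs are preserved.

    Raises
    ------
    DegenerateContourError
        If fewer than 3 distinct points remain, the polygon has zero area,
        or the polygon self-intersects.
    """
    xy = np.atleast_2d(np.asarray(raw_vertices, dtype=float))
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise DegenerateContourError("vertices must be an (n, 2) point list")
    if len(xy) >= 2 and np.allclose(xy[0], xy[-1], atol=DUPLICATE_TOL_MM, rtol=0):
        xy = xy[:-1]
    if len(xy) == 0:
        raise DegenerateContourError("empty vertex list")
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.hypot(*(xy[1:] - xy[:-1]).T) > DUPLICATE_TOL_MM
    xy = xy[keep]
    if len(xy) < 3:
        raise DegenerateContourError(
            f"contour needs >=3 distinct points, got {len(xy)}"
        )
    area = _signed_area(xy)
    if abs(area) <= 1e-12:
        raise DegenerateContourError("contour has zero area")
    if area < 0:
        xy = xy[::-1]
    poly = Polygon(xy)
    if not poly.is_valid:
        raise DegenerateContourError(f"contour is not simple: {shapely.is_valid_reason(poly)}")
    return PlanarContour(z_mm=float(z_mm), vertices=tuple(map(tuple, xy)))


# ---------------------------------------------------------------------------
# Delineations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureDelineation:
    """A 3D contour set: planar polygons grouped by axial slice position."""

    patient_id: str
    label: str
    slice_thickness_mm: float
    contours: tuple[PlanarContour, ...]

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise DelineationError("slice_thickness_mm must be positive")
        ordered = tuple(sorted(self.contours, key=lambda c: c.z_mm))
        object.__setattr__(self, "contours", ordered)
        self._check_grid()

    def _check_grid(self) -> None:
        z = np.array(sorted({c.z_mm for c in self.contours}), dtype=float)
        if len(z) < 3:
            return
        steps = np.diff(z)
        step = steps.min()
        if step <= 0:
            return
        ratio = steps / step
        if np.any(np.abs(ratio - np.round(ratio)) * step > Z_GRID_TOL_MM):
            raise DelineationError(
                f"slice positions of {self.patient_id}/{self.label} are not on "
                "a common grid"
            )

    @property
    def z_values(self) -> tuple[float, ...]:
        return tuple(sorted({c.z_mm for c in self.contours}))

    @property
    def n_slices(self) -> int:
        return len(self.z_values)

    def slices(self) -> dict[float, list[PlanarContour]]:
        """Contours grouped by slice position, ascending ``z``."""
        out: dict[float, list[PlanarContour]] = {}
        for c in self.contours:
            out.setdefault(c.z_mm, []).append(c)
        return dict(sorted(out.items()))

    def volume_mm3(self) -> float:
        return sum(slice_region_area(cs) for cs in self.slices().values()) * self.slice_thickness_mm


def match_slices(
    reference: StructureDelineation,
    test: StructureDelineation,
    tol_mm: float = Z_MATCH_TOL_MM,
) -> list[tuple[float, list[PlanarContour], list[PlanarContour] | None]]:
    """Pair every reference slice with the test slice at the same ``z``.

    Matching is by z equality after snapping to the common grid (both
    delineations derive from the same planning CT); a reference slice with no
    test counterpart is paired with ``None``.
    """
    test_slices = test.slices()
    test_z = np.array(list(test_slices), dtype=float)
    out: list[tuple[float, list[PlanarContour], list[PlanarContour] | None]] = []
    for z, ref_cs in reference.slices().items():
        matched: list[PlanarContour] | None = None
        if len(test_z):
            i = int(np.argmin(np.abs(test_z - z)))
            if abs(test_z[i] - z) <= tol_mm:
                matched = test_slices[float(test_z[i])]
        out.append((z, ref_cs, matched))
    return out


# ---------------------------------------------------------------------------
# Planar region geometry
# ---------------------------------------------------------------------------

def _union(contours: Iterable[PlanarContour]):
    return unary_union([c.polygon for c in contours])


def slice_region_area(contours_on_slice: Sequence[PlanarContour]) -> float:
    """Area (mm^2) of the union of polygon interiors on one slice."""
    if not contours_on_slice:
        return 0.0
    z = {c.z_mm for c in contours_on_slice}
    if len(z) > 1:
        raise DelineationError(f"contours span multiple slices: {sorted(z)}")
    return float(_union(contours_on_slice).area)


def slice_intersection_area(
    a: Sequence[PlanarContour], b: Sequence[PlanarContour]
) -> float:
    """Area (mm^2) of the intersection of two union regions on one slice.

    The operands are ordered canonically before the boolean operation so the
    result is exactly symmetric in (a, b) down to the last bit.
    """
    if not a or not b:
        return 0.0
    ga, gb = sorted([_union(a), _union(b)], key=lambda g: g.wkb)
    return float(ga.intersection(gb).area)


def resample_boundary(
    contours_on_slice: Sequence[PlanarContour], step_mm: float
) -> np.ndarray:
    """Sample points along polygon boundaries at arc-length intervals <= step.

    Original vertices are always included; every edge of length L is split
    into ``ceil(L / step_mm)`` equal sub-segments.  Returns an (n, 2) array of
    points lying exactly on the polygon boundaries.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    pts: list[np.ndarray] = []
    for contour in contours_on_slice:
        xy = contour.xy
        nxt = np.roll(xy, -1, axis=0)
        lengths = np.hypot(*(nxt - xy).T)
        for p, q, L in zip(xy, nxt, lengths):
            n = max(1, int(math.ceil(L / step_mm - 1e-12)))
            t = np.arange(n, dtype=float)[:, None] / n
            pts.append(p[None, :] * (1.0 - t) + q[None, :] * t)
    return np.concatenate(pts, axis=0)


def boundary_segments(
    contours_on_slice: Sequence[PlanarContour],
) -> tuple[np.ndarray, np.ndarray]:
    """All boundary edges as (starts, ends) arrays of shape (m, 2)."""
    starts, ends = [], []
    for contour in contours_on_slice:
        xy = contour.xy
        starts.append(xy)
        ends.append(np.roll(xy, -1, axis=0))
    return np.concatenate(starts, axis=0), np.concatenate(ends, axis=0)


@dataclass(frozen=True)
class GridSpec:
    """Raster geometry used only as a cross-check oracle for exact areas.

    The bounds are the union bounding box of the delineations being compared
    plus a fixed margin; the identical grid must be used for both sides of
    any one comparison.
    """

    pixel_spacing_mm: float
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    @classmethod
    def for_comparison(
        cls,
        a: Sequence[PlanarContour],
        b: Sequence[PlanarContour],
        pixel_spacing_mm: float = 0.05,
        margin_mm: float = 2.0,
    ) -> "GridSpec":
        xy = np.concatenate([c.xy for c in [*a, *b]], axis=0)
        xmin, ymin = xy.min(axis=0) - margin_mm
        xmax, ymax = xy.max(axis=0) + margin_mm
        return cls(pixel_spacing_mm, (float(xmin), float(ymin), float(xmax), float(ymax)))

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        xmin, ymin, xmax, ymax = self.bounds
        s = self.pixel_spacing_mm
        xs = np.arange(xmin + s / 2, xmax, s)
        ys = np.arange(ymin + s / 2, ymax, s)
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm**2


# ---------------------------------------------------------------------------
# Canonical JSON exchange format
# ---------------------------------------------------------------------------

def delineation_to_dict(d: StructureDelineation) -> dict:
    """Serialise to the canonical contour-exchange mapping (all numbers mm)."""
    return {
        "patient_id": d.patient_id,
        "label": d.label,
        "slice_thickness_mm": d.slice_thickness_mm,
        "slices": [
            {"z_mm": z, "polygons": [[list(v) for v in c.vertices] for c in cs]}
            for z, cs in d.slices().items()
        ],
    }


def delineation_from_dict(payload: Mapping) -> StructureDelineation:
    contours = [
        clean_contour(poly, z_mm=s["z_mm"])
        for s in payload["slices"]
        for poly in s["polygons"]
    ]
    return StructureDelineation(
        patient_id=payload["patient_id"],
        label=payload["label"],
        slice_thickness_mm=float(payload["slice_thickness_mm"]),
        contours=tuple(contours),
    )


def write_delineation_json(d: StructureDelineation, path) -> None:
    with open(path, "w") as fh:
        json.dump(delineation_to_dict(d), fh, sort_keys=True)


def read_delineation_json(path) -> StructureDelineation:
    with open(path) as fh:
        return delineation_from_dict(json.load(fh))
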