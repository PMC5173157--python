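"""Atlas-library patient ranking by clinical and anthropometric similarity.

Atlas-based auto-segmentation starts by picking the library patient whose
anatomy best matches the new scan.  In the clinical workflow that choice is
manual, guided by stage, tumour localisation, sex, age, weight, height, BMI,
fertility state and two pelvic distances; this module turns the same field
list into a reproducible Gower-style ranking.  Contour propagation itself is
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

#: Ordinal clinical-stage ladder used to scale stage differences.
STAGE_LEVELS: tuple[str, ...] = ("cT2", "cT3", "cT4")

#: Numeric profile fields (compared as |a-b| / cohort range).
NUMERIC_FIELDS = (
    "age", "weight_kg", "height_cm", "bmi",
    "sacro_coccygeal_mm", "inter_iliac_mm",
)
#: Categorical profile fields (compared as 0/1 mismatch).
CATEGORICAL_FIELDS = ("tumor_localization", "sex", "fertility_state")
#: Stage is ordinal: scaled rank difference on STAGE_LEVELS.
ORDINAL_FIELDS = ("stage",)

ALL_MATCH_FIELDS = ORDINAL_FIELDS + CATEGORICAL_FIELDS + NUMERIC_FIELDS


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    role: str  # "atlas" | "test"
    stage: str | None = None
    tumor_localization: str | None = None  # "low" | "mid"
    sex: str | None = None
    age: float | None = None
    weight_kg: float | None = None
    height_cm: float | None = None
    bmi: float | None = None
    fertility_state: str | None = None
    sacro_coccygeal_mm: float | None = None
    inter_iliac_mm: float | None = None
    slice_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("atlas", "test"):
            raise ValueError(f"role must be 'atlas' or 'test', got {self.role!r}")
        for name in NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if None not in (self.bmi, self.weight_kg, self.height_cm):
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(self.bmi - implied) > 0.02 * implied:
                raise ValueError(
                    f"bmi {self.bmi:.2f} inconsistent with weight/height "
                    f"(implied {implied:.2f})"
                )


def cohort_ranges(profiles: Sequence[PatientProfile]) -> dict[str, float]:
    """Range (max - min) of every numeric field over the cohort."""
    out: dict[str, float] = {}
    for name in NUMERIC_FIELDS:
        vals = [getattr(p, name) for p in profiles if getattr(p, name) is not None]
        out[name] = (max(vals) - min(vals)) if vals else 0.0
    return out


def _field_dissimilarity(name, a, b, ranges) -> float | None:
    """Per-field dissimilarity in [0,1]; None when either side is missing."""
    if a is None or b is None:
        return None
    if name in CATEGORICAL_FIELDS:
        return 0.0 if a == b else 1.0
    if name in ORDINAL_FIELDS:
        try:
            ia, ib = STAGE_LEVELS.index(a), STAGE_LEVELS.index(b)
        except ValueError:
            return 0.0 if a == b else 1.0  # unknown level: fall back to nominal
        return abs(ia - ib) / max(1, len(STAGE_LEVELS) - 1)
    rng = ranges.get(name, 0.0)
    if rng <= 0.0:
        return 0.0  # constant field over the cohort carries no signal
    return min(1.0, abs(a - b) / rng)


def profile_distance(
    a: PatientProfile,
    b: PatientProfile,
    ranges: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Gower-style mixed dissimilarity in [0, 1].

    Numeric fields contribute |a−b| divided by the cohort range, ordinal
    stage a scaled rank difference, categoricals a 0/1 mismatch; the score
    is the weighted mean over fields present on both sides (missing fields
    are skipped and the weights renormalised).  Uniform weights by default.
    """
    w = {name: 1.0 for name in ALL_MATCH_FIELDS}
    if weights:
        w.update(weights)
    num = den = 0.0
    for name in ALL_MATCH_FIELDS:
        d = _field_dissimilarity(name, getattr(a, name), getattr(b, name), ranges)
        if d is None or w[name] == 0.0:
            continue
        num += w[name] * d
        den += w[name]
    if den == 0.0:
        raise ValueError(
            f"profiles {a.patient_id} and {b.patient_id} share no comparable fields"
        )
    return num / den


def rank_atlas(
    test: PatientProfile,
    library: Sequence[PatientProfile],
    weights: Mapping[str, float] | None = None,
    ranges: Mapping[str, float] | None = None,
) -> list[tuple[str, float]]:
    """Rank atlas-library patients by ascending profile distance to `test`.

    Ranges default to the numeric-field ranges of the library plus the test
    patient.  Ties are broken by patient id, so the ranking is deterministic.
    Returns ``[(atlas_id, distance), ...]`` best first.
    """
    if not library:
        raise ValueError("atlas library is empty")
    bad = [p.patient_id for p in library if p.role != "atlas"]
    if bad:
        raise ValueError(f"library contains non-atlas profiles: {bad}")
    if ranges is None:
        ranges = cohort_ranges([test, *library])
    scored = [(p.patient_id, profile_distance(test, p, ranges, weights)) for p in library]
    return sorted(scored, key=lambda kv: (kv[1], kv[0]))
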