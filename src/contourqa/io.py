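"""File I/O: dataset layout on disk, CSV tables, DICOM RT-STRUCT ingest.

A dataset directory holds the canonical contour JSON files plus flat CSV
tables::

    dataset/
      reference/<patient_id>.json     canonical contour format
      manual/<patient_id>.json        group A delineations
      auto/<patient_id>.json          group B delineations
      profiles.csv                    patient profiles for atlas matching
      timing.csv                      patient_id, group, t1_min, t2_min
      provenance.json                 config hash, seed, outlier ids
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import PatientProfile
from .geometry import (
    DelineationError,
    StructureDelineation,
    clean_contour,
    read_delineation_json,
    write_delineation_json,
)
from .qa import TimingRecord, WorkflowGroup
from .synthetic import CohortDataset

PROFILE_COLUMNS = [
    "patient_id", "role", "stage", "tumor_localization", "sex", "age",
    "weight_kg", "height_cm", "bmi", "fertility_state",
    "sacro_coccygeal_mm", "inter_iliac_mm", "slice_thickness_mm",
]
TIMING_COLUMNS = ["patient_id", "group", "t1_min", "t2_min"]


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_profiles_csv(profiles: Sequence[PatientProfile], path) -> None:
    rows = [dataclasses.asdict(p) for p in profiles]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles_csv(path) -> list[PatientProfile]:
    df = pd.read_csv(path)
    out = []
    for row in df.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        out.append(PatientProfile(**clean))
    return out


def write_timing_csv(records: Sequence[TimingRecord], path) -> None:
    rows = [
        {"patient_id": r.patient_id, "group": r.group.value,
         "t1_min": r.t1_min, "t2_min": r.t2_min}
        for r in records
    ]
    pd.DataFrame(rows, columns=TIMING_COLUMNS).to_csv(path, index=False)


def read_timing_csv(path) -> list[TimingRecord]:
    df = pd.read_csv(path)
    return [
        TimingRecord(
            patient_id=str(r["patient_id"]), group=WorkflowGroup(r["group"]),
            t1_min=float(r["t1_min"]), t2_min=float(r["t2_min"]),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# Dataset directories
# ---------------------------------------------------------------------------

def write_dataset(dataset: CohortDataset, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sub, coll in (
        ("reference", dataset.references),
        ("manual", dataset.manual),
        ("auto", dataset.auto),
    ):
        d = out / sub
        d.mkdir(exist_ok=True)
        for pid, delineation in sorted(coll.items()):
            write_delineation_json(delineation, d / f"{pid}.json")
    write_profiles_csv(dataset.profiles, out / "profiles.csv")
    write_timing_csv(dataset.timings, out / "timing.csv")
    with open(out / "provenance.json", "w") as fh:
        json.dump(dataset.provenance, fh, indent=2, sort_keys=True)
    return out


def _read_delineation_dir(d: Path) -> dict[str, StructureDelineation]:
    return {p.stem: read_delineation_json(p) for p in sorted(d.glob("*.json"))}


def read_dataset(indir) -> CohortDataset:
    root = Path(indir)
    provenance = {}
    if (root / "provenance.json").exists():
        provenance = json.loads((root / "provenance.json").read_text())
    profiles = (
        read_profiles_csv(root / "profiles.csv")
        if (root / "profiles.csv").exists() else []
    )
    return CohortDataset(
        profiles=tuple(profiles),
        references=_read_delineation_dir(root / "reference"),
        manual=_read_delineation_dir(root / "manual"),
        auto=_read_delineation_dir(root / "auto"),
        timings=tuple(read_timing_csv(root / "timing.csv")),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT
# ---------------------------------------------------------------------------

def read_rtstruct(path, roi_label: str) -> StructureDelineation:
    """Read one ROI of a DICOM RT structure set as a StructureDelineation.

    Planar contour points are taken from ``ContourData`` (mm); the slice
    position is the third coordinate, which must be constant per contour
    within 0.01 mm.  Slice thickness is inferred from the z spacing (1.0 mm
    is assumed when only one slice is present).
    """
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    if not hasattr(ds, "StructureSetROISequence"):
        raise DelineationError(f"{path} is not an RT structure set")
    names = {roi.ROIName: roi.ROINumber for roi in ds.StructureSetROISequence}
    if roi_label not in names:
        raise DelineationError(
            f"ROI {roi_label!r} not found; available: {sorted(names)}"
        )
    number = names[roi_label]
    contours = []
    for roi_contour in ds.ROIContourSequence:
        if roi_contour.ReferencedROINumber != number:
            continue
        for item in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            z = pts[:, 2]
            if np.ptp(z) > 0.01:
                raise DelineationError(
                    f"non-coplanar contour points in ROI {roi_label!r} "
                    f"(z spread {np.ptp(z):.3f} mm)"
                )
            contours.append(clean_contour(pts[:, :2], z_mm=float(z.mean())))
    if not contours:
        raise DelineationError(f"ROI {roi_label!r} has no contour data")
    zs = sorted({c.z_mm for c in contours})
    thickness = float(np.min(np.diff(zs))) if len(zs) > 1 else 1.0
    return StructureDelineation(
        patient_id=str(getattr(ds, "PatientID", "") or "UNKNOWN"),
        label=roi_label,
        slice_thickness_mm=thickness,
        contours=tuple(contours),
    )


# ---------------------------------------------------------------------------
# Per-patient metric table
# ---------------------------------------------------------------------------

def overlap_results_frame(results) -> pd.DataFrame:
    """Per-patient metric table in the canonical CSV column order."""
    rows = [
        {
            "patient_id": r.patient_id,
            "dsc": r.dsc,
            "mshd_mm": r.mshd_mm,
            "n_reference_slices": r.n_reference_slices,
            "n_unmatched_slices": r.n_unmatched_slices,
            "slice_thickness_mm": r.slice_thickness_mm,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "dsc", "mshd_mm", "n_reference_slices",
            "n_unmatched_slices", "slice_thickness_mm",
        ],
    )
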