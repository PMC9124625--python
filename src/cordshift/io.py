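"""Fixture and DICOM-RT readers, report writers.

The native fixture format ("cordshift-fixture-v1") is a course directory:
``course.json`` holds all metadata (structures as vertex lists, the region
partition, per-fraction shift/SSA/dose records) and ``grids.npz`` the dose
arrays.  Writing then reading a fixture is lossless.

DICOM RTDOSE/RTSTRUCT reading maps the standard patient coordinate system
(LPS: x left, y posterior, z superior) onto the internal (LR, SI, AP)
convention: x stays, internal y = DICOM z, internal z = -DICOM y.  The
mapping is logged; DICOM is never written.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .geometry import (
    Contour,
    DoseGrid,
    RegionPartition,
    ShiftVector,
    Structure,
)
from .pipeline import FractionRecord, RegressionFit

__all__ = [
    "FIXTURE_SCHEMA",
    "write_fixture",
    "read_fixture",
    "Course",
    "read_dicom_rt",
    "write_report",
]

log = logging.getLogger("cordshift")

FIXTURE_SCHEMA = "cordshift-fixture-v1"


# ---------------------------------------------------------------------------
# native fixture
# ---------------------------------------------------------------------------


class Course:
    """In-memory course object graph loaded from (or written to) a fixture."""

    def __init__(
        self,
        plan: DoseGrid,
        external: Structure,
        sc: Structure,
        partition: RegionPartition,
        records: list[FractionRecord],
        planning_ssa: Mapping[str, float],
        planned_dmax: Mapping[str, float],
        n_fractions: int,
    ):
        self.plan = plan
        self.external = external
        self.sc = sc
        self.partition = partition
        self.records = records
        self.planning_ssa = dict(planning_ssa)
        self.planned_dmax = dict(planned_dmax)
        self.n_fractions = n_fractions


def _structure_to_json(s: Structure) -> dict:
    return {
        "name": s.name,
        "role": s.role,
        "contours": [
            {"y_slice": c.y_slice, "points": [list(p) for p in c.points]}
            for c in s.contours
        ],
    }


def _structure_from_json(d: dict) -> Structure:
    contours = tuple(
        Contour(c["y_slice"], tuple(map(tuple, c["points"])))
        for c in d["contours"]
    )
    return Structure(d["name"], contours, role=d.get("role", "other"))


def _record_to_json(r: FractionRecord) -> dict:
    return {
        "patient": r.patient,
        "fraction_index": r.fraction_index,
        "shifts": {k: [v.dx, v.dy, v.dz] for k, v in r.shifts.items()},
        "ssa": dict(r.ssa),
        "dose_metrics": {k: dict(v) for k, v in r.dose_metrics.items()},
    }


def _record_from_json(d: dict) -> FractionRecord:
    shifts = {}
    for k, v in d["shifts"].items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"non-finite shift for region '{k}'")
        shifts[k] = ShiftVector(*arr)
    return FractionRecord(
        patient=d["patient"],
        fraction_index=d["fraction_index"],
        shifts=shifts,
        ssa=d.get("ssa", {}),
        dose_metrics=d.get("dose_metrics", {}),
    )


def write_fixture(path: str | Path, course: Course) -> Path:
    """Write a course to a fixture directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema": FIXTURE_SCHEMA,
        "partition": {k: list(v) for k, v in course.partition.regions.items()},
        "structures": [
            _structure_to_json(course.external),
            _structure_to_json(course.sc),
        ],
        "records": [_record_to_json(r) for r in course.records],
        "planning_ssa": course.planning_ssa,
        "planned_dmax": course.planned_dmax,
        "n_fractions": course.n_fractions,
        "plan_grid": {
            "origin": list(course.plan.origin),
            "spacing": list(course.plan.spacing),
        },
    }
    (path / "course.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.savez_compressed(path / "grids.npz", plan=course.plan.values)
    return path


def _require(meta: dict, key: str):
    if key not in meta:
        raise ValidationError(f"fixture is missing required key '{key}'")
    return meta[key]


def read_fixture(path: str | Path) -> Course:
    """Load a ``cordshift-fixture-v1`` course directory.

    Raises ValidationError naming the offending field for version
    mismatches, missing keys or non-finite numbers.
    """
    path = Path(path)
    meta_path = path / "course.json"
    if not meta_path.exists():
        raise ValidationError(f"no course.json under {path}")
    meta = json.loads(meta_path.read_text())
    schema = _require(meta, "schema")
    if schema != FIXTURE_SCHEMA:
        raise ValidationError(
            f"unsupported fixture schema '{schema}' (expected {FIXTURE_SCHEMA})"
        )
    partition = RegionPartition(
        {k: tuple(v) for k, v in _require(meta, "partition").items()}
    )
    structures = {
        d["role"]: _structure_from_json(d) for d in _require(meta, "structures")
    }
    if "external" not in structures or "spinal_cord" not in structures:
        raise ValidationError("fixture must contain external and spinal_cord structures")
    records = [_record_from_json(d) for d in _require(meta, "records")]
    grid_meta = _require(meta, "plan_grid")
    with np.load(path / "grids.npz") as grids:
        plan_values = grids["plan"]
    if not np.all(np.isfinite(plan_values)):
        raise ValidationError("plan dose grid contains non-finite values")
    plan = DoseGrid(
        origin=tuple(grid_meta["origin"]),
        spacing=tuple(grid_meta["spacing"]),
        values=plan_values,
    )
    return Course(
        plan=plan,
        external=structures["external"],
        sc=structures["spinal_cord"],
        partition=partition,
        records=records,
        planning_ssa=_require(meta, "planning_ssa"),
        planned_dmax=_require(meta, "planned_dmax"),
        n_fractions=_require(meta, "n_fractions"),
    )


# ---------------------------------------------------------------------------
# DICOM-RT (read only)
# ---------------------------------------------------------------------------


def read_dicom_rt(rtdose_path: str | Path, rtstruct_path: str | Path):
    """Read RTDOSE + RTSTRUCT into a (DoseGrid, {name: Structure}) pair.

    Doses are scaled to Gy via DoseGridScaling.  Axis mapping (logged):
    internal (x, y, z) = (DICOM x, DICOM z, -DICOM y); the AP axis flips
    sign because DICOM y increases posteriorly while internal z increases
    anteriorly.
    """
    import pydicom

    ds = pydicom.dcmread(str(rtdose_path))
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise ValidationError("RTDOSE is missing DoseGridScaling")
    arr = ds.pixel_array.astype(float) * float(scaling)  # (frames, rows, cols)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    diffs = np.diff(offsets)
    if len(offsets) != arr.shape[0] or not np.allclose(diffs, diffs[0]):
        raise ValidationError("unsupported RTDOSE multi-frame layout")
    frame_sp = float(diffs[0])
    if frame_sp <= 0:
        raise ValidationError("RTDOSE frames must ascend in patient z")

    # internal axes: x = DICOM x, y = DICOM z, z = -DICOM y (rows reversed)
    log.info(
        "DICOM axis mapping: internal (x, y, z) = (x_dicom, z_dicom, -y_dicom)"
    )
    nrows = arr.shape[1]
    values = np.transpose(arr, (2, 0, 1))[:, :, ::-1]
    origin = (
        ipp[0],
        ipp[2] + offsets[0],
        -(ipp[1] + (nrows - 1) * row_sp),
    )
    grid = DoseGrid(origin=origin, spacing=(col_sp, frame_sp, row_sp), values=values)

    st = pydicom.dcmread(str(rtstruct_path))
    dose_for = getattr(ds, "FrameOfReferenceUID", None)
    struct_for = None
    ref_seq = getattr(st, "ReferencedFrameOfReferenceSequence", None)
    if ref_seq:
        struct_for = getattr(ref_seq[0], "FrameOfReferenceUID", None)
    if dose_for and struct_for and dose_for != struct_for:
        log.warning(
            "frame-of-reference mismatch between RTDOSE (%s) and RTSTRUCT (%s); "
            "loading anyway",
            dose_for,
            struct_for,
        )

    names = {
        int(roi.ROINumber): roi.ROIName
        for roi in getattr(st, "StructureSetROISequence", [])
    }
    structures: dict[str, Structure] = {}
    for roi in getattr(st, "ROIContourSequence", []):
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        contours = []
        for c in getattr(roi, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            pts = tuple((x, -y) for x, y, _ in data)
            contours.append(Contour(float(data[0, 2]), pts))
        if contours:
            structures[name] = Structure(name, tuple(contours))
    return grid, structures


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _fit_to_json(fit: RegressionFit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "residual_mean": fit.residual_mean,
        "residual_sd": fit.residual_sd,
        "n": fit.n,
    }


def write_report(
    outdir: str | Path,
    setup_table=None,
    contour_summary=None,
    dose_diffs=None,
    contour_fits: Mapping[str, RegressionFit] | None = None,
    displaced_fit: RegressionFit | None = None,
    flags: Mapping[str, bool] | None = None,
) -> list[Path]:
    """Emit the standard course report files (CSV + JSON), deterministically.

    Writes whichever of table1.csv (setup errors), table2.csv (SSA),
    dose_diffs.csv and regressions.json the caller provides, plus a short
    human-readable summary.txt.  Floats are serialized at full precision
    with '.' decimal separator; row order is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    lines: list[str] = []

    if setup_table is not None:
        p = outdir / "table1.csv"
        setup_table.to_csv(p, index=False)
        written.append(p)
        lines.append("3D setup errors written to table1.csv")
    if contour_summary is not None:
        p = outdir / "table2.csv"
        contour_summary.ssa.to_csv(p, index=False)
        written.append(p)
        for region, pct in sorted(contour_summary.average_change_pct.items()):
            lines.append(f"average contour change {region}: {pct:.2f}%")
    if dose_diffs is not None:
        p = outdir / "dose_diffs.csv"
        dose_diffs.sort_values(
            ["patient", "fraction", "region", "variant"]
        ).to_csv(p, index=False)
        written.append(p)
    fits_json = {}
    if contour_fits:
        fits_json["contour_dose"] = {
            r: _fit_to_json(f) for r, f in sorted(contour_fits.items())
        }
        for r, f in sorted(contour_fits.items()):
            lines.append(
                f"contour-dose fit {r}: slope {f.slope:.4f}, R^2 {f.r_squared:.3f}"
            )
    if displaced_fit is not None:
        fits_json["displaced_vs_setup"] = _fit_to_json(displaced_fit)
        lines.append(
            "displaced-vs-setup fit: "
            f"slope {displaced_fit.slope:.4f}, R^2 {displaced_fit.r_squared:.3f}, "
            f"residual {displaced_fit.residual_mean:.2f} +/- "
            f"{displaced_fit.residual_sd:.2f} Gy"
        )
    if fits_json:
        p = outdir / "regressions.json"
        p.write_text(json.dumps(fits_json, indent=1, sort_keys=True))
        written.append(p)
    if flags is not None:
        flagged = sorted(r for r, f in flags.items() if f)
        lines.append(
            "replanning trigger: " + (", ".join(flagged) if flagged else "none")
        )
    p = outdir / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
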