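"""Contour and voxel-mask geometry for neck organ-at-risk analysis.

The spinal cord and the body surface ("external") are represented as stacks
of planar polygons on axial slices (x-z planes at constant y, with y the
inferior-superior axis).  This module provides the geometric primitives the
longitudinal analysis is built on:

* polygon areas and the per-region median slice surface area (SSA) of the
  external contour, whose fractional decrease is the contour-change metric;
* the 3D setup-error magnitude of a per-region rigid registration shift;
* rasterization of a structure onto a dose grid (voxel-center membership);
* the cranio-caudal region partition of the cord (C1-C3, C4-C5, C6-C7);
* area-preserving "clipping" of the external contour that emulates
  progressive neck shrinkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import DomainError, EmptyRegionError, GeometryError
from .units import mm2_to_cm2, mm3_to_cc

__all__ = [
    "DoseGrid",
    "Contour",
    "Structure",
    "RegionPartition",
    "ShiftVector",
    "polygon_area",
    "region_ssa",
    "contour_change",
    "three_d_error",
    "rasterize",
    "split_by_region",
    "clip_external",
    "translate_structure",
]

REGIONS = ("C1_C3", "C4_C5", "C6_C7")
HEAD = "HEAD"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseGrid:
    """Regular 3D scalar dose field (Gy) with spatial metadata.

    ``values`` has shape ``(nx, ny, nz)`` in (LR, SI, AP) axis order;
    ``origin`` is the centre of voxel (0, 0, 0) in mm and ``spacing`` the
    voxel pitch in mm along each axis.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise DomainError("dose grid values must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise DomainError("grid spacing must be strictly positive")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise DomainError("dose values must be finite and non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return mm3_to_cc(sx * sy * sz)


@dataclass(frozen=True)
class Contour:
    """One closed planar polygon on an axial slice.

    ``y_slice`` is the SI coordinate of the plane (mm); ``points`` the
    ordered (x, z) vertices (mm) of a simple polygon, implicitly closed.
    """

    y_slice: float
    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = tuple((float(x), float(z)) for x, z in self.points)
        if len(pts) < 3:
            raise GeometryError(f"contour at y={self.y_slice} has <3 vertices")
        if not np.all(np.isfinite(np.asarray(pts))):
            raise GeometryError(f"contour at y={self.y_slice} has non-finite vertices")
        object.__setattr__(self, "points", pts)

    def polygon(self) -> Polygon:
        poly = Polygon(self.points)
        if not poly.is_valid or poly.area == 0.0:
            raise GeometryError(
                f"contour at y={self.y_slice} is not a simple polygon"
            )
        return poly


@dataclass(frozen=True)
class Structure:
    """Named stack of per-slice contours (body external, spinal cord, PRV).

    Contours are kept sorted by ``y_slice``; at most one polygon per slice
    (multi-island slices are rejected).
    """

    name: str
    contours: tuple[Contour, ...]
    role: str = "other"

    def __post_init__(self):
        cts = tuple(sorted(self.contours, key=lambda c: c.y_slice))
        ys = [c.y_slice for c in cts]
        if len(set(ys)) != len(ys):
            raise GeometryError(
                f"structure '{self.name}' has multiple polygons on one slice"
            )
        object.__setattr__(self, "contours", cts)

    @property
    def y_slices(self) -> np.ndarray:
        return np.array([c.y_slice for c in self.contours])

    def slice_spacing(self) -> float | None:
        """Median inter-slice spacing (mm); None for a single slice."""
        ys = self.y_slices
        if len(ys) < 2:
            return None
        return float(np.median(np.diff(ys)))


@dataclass(frozen=True)
class RegionPartition:
    """Ordered cranio-caudal partition: region name -> half-open [y_min, y_max).

    Must name the three cord regions C1_C3, C4_C5 and C6_C7; a HEAD window
    is optional (the head is the registration reference, not a cord region).
    """

    regions: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        regs = dict(self.regions)
        for name in REGIONS:
            if name not in regs:
                raise DomainError(f"partition must define region {name}")
        ivals = sorted(regs.values())
        for lo, hi in ivals:
            if not lo < hi:
                raise DomainError("each region interval needs y_min < y_max")
        for (_, hi0), (lo1, _) in zip(ivals, ivals[1:]):
            if lo1 < hi0:
                raise DomainError("region intervals overlap")
        object.__setattr__(self, "regions", regs)

    def region_of(self, y: float) -> str | None:
        """Region owning coordinate y under the half-open convention."""
        for name, (lo, hi) in self.regions.items():
            if lo <= y < hi:
                return name
        return None

    def cord_regions(self) -> tuple[str, ...]:
        return REGIONS


@dataclass(frozen=True)
class ShiftVector:
    """Per-region rigid setup error (mm) in (LR, SI, AP) axes.

    Convention: anatomy position at treatment minus planned position, in the
    plan coordinate frame.  The rapid estimator adds this vector to the
    planned cord contour.
    """

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.dx, self.dy, self.dz)):
            raise DomainError("shift components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])

    def __neg__(self) -> "ShiftVector":
        return ShiftVector(-self.dx, -self.dy, -self.dz)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def polygon_area(contour: Contour) -> float:
    """Area of a slice polygon in cm^2 (orientation-independent)."""
    return mm2_to_cm2(contour.polygon().area)


def region_ssa(external: Structure, region: tuple[float, float]) -> float:
    """Median slice surface area (cm^2) of the external contour in a region.

    The SSA of a neck region is the median over its axial slices of the body
    cross-sectional area; its relative decrease over the course is the
    contour-change metric.  ``region`` is a half-open (y_min, y_max) window.
    """
    y_min, y_max = region
    areas = [
        polygon_area(c) for c in external.contours if y_min <= c.y_slice < y_max
    ]
    if not areas:
        raise EmptyRegionError(
            f"no external slices of '{external.name}' in [{y_min}, {y_max})"
        )
    return float(np.median(areas))


def contour_change(ssa_ct: float, ssa_cbct: float) -> float:
    """Fractional contour change (SSA_ct - SSA_cbct) / SSA_ct.

    Positive = shrinkage relative to the planning CT; negative = swelling.
    """
    if ssa_ct <= 0:
        raise DomainError("planning SSA must be positive")
    return (ssa_ct - ssa_cbct) / ssa_ct


def three_d_error(shift: ShiftVector) -> float:
    """Euclidean magnitude sqrt(dx^2 + dy^2 + dz^2) of a setup error (mm)."""
    return float(np.linalg.norm(shift.as_array()))


def _owned_planes(structure: Structure, grid: DoseGrid) -> dict[int, Contour]:
    """Map grid y-plane index -> owning contour (nearest in y, within half
    a slice spacing)."""
    ycoords = grid.axis_coords(1)
    spacing = structure.slice_spacing()
    half = 0.5 * (spacing if spacing is not None else grid.spacing[1])
    ys = structure.y_slices
    owned: dict[int, Contour] = {}
    for j, y in enumerate(ycoords):
        k = int(np.argmin(np.abs(ys - y)))
        if abs(ys[k] - y) <= half + 1e-9:
            owned[j] = structure.contours[k]
    return owned


def rasterize(structure: Structure, grid: DoseGrid) -> np.ndarray:
    """Boolean voxel mask of a structure on a dose grid.

    A voxel belongs to the mask iff its centre lies inside the slice polygon
    nearest in y (within half a slice spacing); even-odd membership, no
    partial-volume weighting.  Returns an array of ``grid.shape``; an empty
    mask is returned (not raised) when the structure misses the grid.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    zs = grid.axis_coords(2)
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    for j, contour in _owned_planes(structure, grid).items():
        inside = shapely.contains_xy(contour.polygon(), xx.ravel(), zz.ravel())
        mask[:, j, :] = inside.reshape(xx.shape)
    return mask


def mask_volume_cc(mask: np.ndarray, grid: DoseGrid) -> float:
    """Volume (cc) of a boolean mask: voxel count x voxel volume."""
    return int(mask.sum()) * grid.voxel_volume_cc


def split_by_region(
    sc: Structure, partition: RegionPartition
) -> dict[str, Structure]:
    """Assign each contour of the cord to the region containing its slice.

    Contours outside every region window are dropped.  Ties at a boundary
    follow the half-open convention: y == y_min belongs to that region.
    """
    buckets: dict[str, list[Contour]] = {name: [] for name in partition.regions}
    for c in sc.contours:
        region = partition.region_of(c.y_slice)
        if region is not None:
            buckets[region].append(c)
    return {
        name: Structure(name=f"{sc.name}:{name}", contours=tuple(cts), role=sc.role)
        for name, cts in buckets.items()
    }


def _scale_contour(contour: Contour, factor: float) -> Contour:
    if factor == 1.0:  # keep bit-exact identity for zero shrink
        return contour
    poly = contour.polygon()
    cx, cz = poly.centroid.x, poly.centroid.y
    pts = np.asarray(contour.points)
    scaled = np.column_stack(
        [cx + factor * (pts[:, 0] - cx), cz + factor * (pts[:, 1] - cz)]
    )
    return Contour(contour.y_slice, tuple(map(tuple, scaled)))


def clip_external(
    external: Structure,
    shrink: float | Mapping[str, float],
    partition: RegionPartition | None = None,
) -> Structure:
    """Shrink the external contour to emulate neck soft-tissue loss.

    Each slice polygon is scaled radially about its own centroid by
    sqrt(1 - shrink) so its area becomes (1 - shrink) x the original, i.e.
    ``contour_change`` of the result against the input equals the requested
    fraction.  ``shrink`` is either a single fraction or a per-region map
    (requiring ``partition``); slices outside mapped regions are unchanged.
    Negative fractions (> -1) express swelling.
    """

    def factor(f: float) -> float:
        if not -1.0 < f < 1.0:
            raise DomainError(f"shrink fraction {f} outside (-1, 1)")
        return math.sqrt(1.0 - f)

    if isinstance(shrink, Mapping):
        if partition is None:
            raise DomainError("per-region shrink requires a partition")
        factors = {name: factor(f) for name, f in shrink.items()}
        out = []
        for c in external.contours:
            region = partition.region_of(c.y_slice)
            if region is not None and region in factors:
                out.append(_scale_contour(c, factors[region]))
            else:
                out.append(c)
    else:
        k = factor(float(shrink))
        out = [_scale_contour(c, k) for c in external.contours]
    return replace(external, contours=tuple(out))


def translate_structure(structure: Structure, shift: ShiftVector) -> Structure:
    """Rigidly translate a structure by a shift vector (areas preserved)."""
    moved = tuple(
        Contour(
            c.y_slice + shift.dy,
            tuple((x + shift.dx, z + shift.dz) for x, z in c.points),
        )
        for c in structure.contours
    )
    return replace(structure, contours=moved)
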