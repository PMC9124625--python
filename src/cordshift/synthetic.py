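"""Synthetic neck phantom, toy dose engine and course sampler.

Clinical CBCT/CT courses are not shippable, so every pipeline stage is
exercised on a synthetic stand-in with the same statistical structure:

* a neck phantom -- elliptical body cross-sections sized to the planning-CT
  slice surface areas of each region and tapering smoothly between regions,
  with the spinal cord as a posterior cylinder;
* a declared toy dose engine -- a sum of coplanar exponential-attenuation
  beams with anterior weighting, a plan-carved Gaussian dose valley around
  the planned cord axis (deep near the high-dose target cranially,
  flattening caudally) and a cranio-caudal fluence profile calibrated so
  the planned per-region cord D(0.1cc) equals configured targets.  This is
  an explicit analytic model, not a treatment planning system;
* an uncertainty model -- per-region, per-axis Gaussian setup errors with a
  late-course inflation of the lower neck and a posterior drift, and a
  monotone per-region shrinkage schedule -- from which whole courses are
  sampled: for each imaging timepoint a "delivered" (shift + shrink),
  "setup-only" (shift) and "contour-only" (shrink) dose variant is computed
  per region, mirroring a univariate simulation design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dvh import dmax_from_doses, dmax_vol, scale_to_course
from .errors import DomainError, GeometryError
from .estimator import dmax_displaced
from .geometry import (
    REGIONS,
    HEAD,
    Contour,
    DoseGrid,
    RegionPartition,
    ShiftVector,
    Structure,
    _owned_planes,
    clip_external,
    rasterize,
    region_ssa,
    split_by_region,
    translate_structure,
)
from .pipeline import FractionRecord

__all__ = [
    "PhantomSpec",
    "EngineParams",
    "UncertaintyModel",
    "Phantom",
    "GridSpec",
    "ToyDoseEngine",
    "toy_dose_engine",
    "make_phantom",
    "sample_course",
    "CourseSample",
    "default_uncertainty_model",
    "shift_only_model",
    "null_model",
    "linear_contour_response",
]

DOSE_VARIANTS = ("planned", "delivered", "setup", "contour", "displaced")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular grid layout: voxel-centre origin (mm), spacing (mm), shape."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def empty_grid(self) -> DoseGrid:
        return DoseGrid(self.origin, self.spacing, np.zeros(self.shape))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and prescription of the synthetic neck phantom.

    Body cross-sections are ellipses whose areas at the region midpoints
    match typical planning-CT slice surface areas, tapering linearly in
    between; the cord is a straight posterior cylinder.  y increases
    cranially; region windows are half-open.
    """

    region_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "C6_C7": (0.0, 60.0),
            "C4_C5": (60.0, 100.0),
            "C1_C3": (100.0, 160.0),
        }
    )
    # target median slice surface area (cm^2) of the body per region; the
    # mid-neck (C4-C5) narrowing lives in the LR width while the AP
    # semi-axis stays fixed, as in a real neck
    region_ssa_cm2: Mapping[str, float] = field(
        default_factory=lambda: {"C1_C3": 192.7, "C4_C5": 133.0, "C6_C7": 171.4}
    )
    body_ap_semi_axis_mm: float = 57.0
    cord_radius_mm: float = 5.0
    cord_center_z_mm: float = -38.0  # posterior offset of the cord axis
    slice_spacing_mm: float = 2.5
    grid_spacing_mm: float = 2.5
    # finer in-plane sampling: the 5 mm cord needs sub-voxel resolution for
    # a stable D(0.1cc) under sub-voxel displacements
    inplane_spacing_mm: float = 1.25
    prescription_gy: float = 70.0
    n_fractions: int = 33
    # course-scale planned per-region cord D(0.1cc) the plan is tuned to
    planned_dmax_targets_gy: Mapping[str, float] = field(
        default_factory=lambda: {"C1_C3": 37.4, "C4_C5": 36.2, "C6_C7": 33.2}
    )
    n_body_vertices: int = 64
    n_cord_vertices: int = 32

    def __post_init__(self):
        for r in REGIONS:
            if r not in self.region_windows or r not in self.region_ssa_cm2:
                raise DomainError(f"phantom spec must cover region {r}")
        b = self.body_ap_semi_axis_mm
        if b <= 0 or any(a <= 0 for a in self.region_ssa_cm2.values()):
            raise DomainError("body dimensions must be positive")
        if abs(self.cord_center_z_mm) + self.cord_radius_mm >= b:
            raise GeometryError("cord cylinder not strictly inside the body")
        for r, area in self.region_ssa_cm2.items():
            a_lr = area * 100.0 / (math.pi * b)
            # the cord sits on the midline: the AP check above binds, the LR
            # width only needs to clear the cord radius
            if self.cord_radius_mm >= a_lr:
                raise GeometryError(
                    f"cord cylinder not strictly inside the body in {r}"
                )

    def partition(self) -> RegionPartition:
        return RegionPartition(dict(self.region_windows))

    @property
    def y_range(self) -> tuple[float, float]:
        los, his = zip(*self.region_windows.values())
        return min(los), max(his)

    def region_midpoints(self) -> dict[str, float]:
        return {r: 0.5 * (lo + hi) for r, (lo, hi) in self.region_windows.items()}


@dataclass
class EngineParams:
    """Declared parameters of the toy dose engine.

    ``mu`` is the effective linear attenuation (about 6 MV in water);
    ``anterior_weight`` skews beam weights 1 + a*cos(phi) toward anterior
    entry.  ``dip_depth`` gives the fractional depth of the plan-carved
    dose valley around the planned cord axis at each region midpoint and
    ``region_fluence`` the cranio-caudal plan fluence factors there; both
    profiles interpolate linearly between midpoints (clamped beyond) so the
    dose field is continuous along the cord.
    """

    n_beams: int = 36
    mu_per_mm: float = 0.005
    anterior_weight: float = 0.5
    dip_depth: Mapping[str, float] = field(
        default_factory=lambda: {"C1_C3": 0.25, "C4_C5": 0.12, "C6_C7": 0.05}
    )
    dip_sigma_mm: float = 8.0
    dip_center_xz: tuple[float, float] = (0.0, -38.0)
    region_fluence: Mapping[str, float] = field(default_factory=dict)
    norm_constant: float = 1.0
    ref_point: tuple[float, float, float] = (0.0, 130.0, 30.0)


def default_uncertainty_model() -> "UncertaintyModel":
    return UncertaintyModel()


@dataclass(frozen=True)
class UncertaintyModel:
    """Statistical model of per-fraction geometric uncertainties.

    Per-axis Gaussian setup errors per region, with an early phase
    (fractions before ``phase_break``) and an inflated late phase for the
    lower neck; anterior-posterior means are negative (posterior drift).
    Shrinkage grows linearly in fraction index from zero to a per-patient
    end value drawn around the per-region course-end means.  Per-axis
    parameters are assumptions chosen to reproduce typical 3D-error means
    approximately (no per-axis decomposition is available to copy).
    """

    # region -> phase -> ((mx, sx), (my, sy), (mz, sz)) in mm
    setup_params: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: {
            HEAD: {
                "early": ((0.0, 1.25), (0.0, 1.25), (0.0, 1.25)),
                "late": ((0.0, 1.25), (0.0, 1.25), (0.0, 1.25)),
            },
            "C1_C3": {
                "early": ((0.0, 1.3), (0.0, 1.3), (-0.3, 1.3)),
                "late": ((0.0, 1.65), (0.0, 1.65), (-0.6, 1.65)),
            },
            "C4_C5": {
                "early": ((0.0, 1.55), (0.0, 1.55), (-0.4, 1.55)),
                "late": ((0.0, 2.4), (0.0, 2.4), (-1.0, 2.4)),
            },
            "C6_C7": {
                "early": ((0.0, 1.75), (0.0, 1.75), (-0.5, 1.75)),
                "late": ((0.0, 2.55), (0.0, 2.55), (-1.2, 2.55)),
            },
        }
    )
    phase_break: int = 23  # late phase from the 23rd fraction on
    # course-end shrink fractions per region (cohort mean and patient SD)
    end_shrink_mean: Mapping[str, float] = field(
        default_factory=lambda: {"C1_C3": 0.0669, "C4_C5": 0.1293, "C6_C7": 0.1791}
    )
    end_shrink_sd: Mapping[str, float] = field(
        default_factory=lambda: {"C1_C3": 0.0725, "C4_C5": 0.121, "C6_C7": 0.156}
    )
    shrink_clip: tuple[float, float] = (-0.10, 0.32)
    ssa_noise_sd_cm2: float = 1.0
    shift_clip_mm: float = 8.0
    imaging_fractions: tuple[int, ...] = (1, 10, 17, 23, 28, 33)

    def __post_init__(self):
        for region in ("C4_C5", "C6_C7"):
            for ax in range(3):
                early = self.setup_params[region]["early"][ax][1]
                late = self.setup_params[region]["late"][ax][1]
                if late < early:
                    raise DomainError(
                        "late-phase lower-neck spread must not shrink below "
                        "the early phase"
                    )
        for r, f in self.end_shrink_mean.items():
            if not 0.0 <= f < 1.0:
                raise DomainError(f"end shrink for {r} must be in [0, 1)")
        for r, s in self.end_shrink_sd.items():
            if s < 0:
                raise DomainError("shrink SDs must be >= 0")

    def phase_of(self, fraction: int) -> str:
        return "late" if fraction >= self.phase_break else "early"


def null_model() -> UncertaintyModel:
    """Zero-perturbation model: no shifts, no shrinkage, no noise."""
    zero = ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0))
    params = {r: {"early": zero, "late": zero} for r in (HEAD,) + REGIONS}
    zeros = {r: 0.0 for r in REGIONS}
    return UncertaintyModel(
        setup_params=params,
        end_shrink_mean=zeros,
        end_shrink_sd=zeros,
        ssa_noise_sd_cm2=0.0,
    )


def shift_only_model(base: UncertaintyModel | None = None) -> UncertaintyModel:
    """Setup errors as in ``base`` but with the shrink schedule switched off."""
    base = base or default_uncertainty_model()
    zeros = {r: 0.0 for r in REGIONS}
    return UncertaintyModel(
        setup_params=base.setup_params,
        phase_break=base.phase_break,
        end_shrink_mean=zeros,
        end_shrink_sd=zeros,
        ssa_noise_sd_cm2=base.ssa_noise_sd_cm2,
        shift_clip_mm=base.shift_clip_mm,
        imaging_fractions=base.imaging_fractions,
    )


# ---------------------------------------------------------------------------
# toy dose engine
# ---------------------------------------------------------------------------


def _convex_edges(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertices -> (edge base points, outward unit normals), convex only.

    Raises GeometryError for non-convex slices (engine limitation)."""
    pts = np.asarray(points, dtype=float)
    edges = np.roll(pts, -1, axis=0) - pts
    nxt = np.roll(edges, -1, axis=0)
    cross = edges[:, 0] * nxt[:, 1] - edges[:, 1] * nxt[:, 0]
    if np.all(cross >= -1e-9):  # CCW
        normals = np.column_stack([edges[:, 1], -edges[:, 0]])
    elif np.all(cross <= 1e-9):  # CW
        normals = np.column_stack([-edges[:, 1], edges[:, 0]])
    else:
        raise GeometryError("toy dose engine requires convex body slices")
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return pts, normals


def _interp_profile(
    y, midpoints: dict[str, float], values: Mapping[str, float], empty: float
):
    """Piecewise-linear profile through region midpoints, clamped outside."""
    if not values:
        return np.full_like(np.asarray(y, dtype=float), empty)
    ys = np.array(sorted(midpoints[r] for r in values))
    vs = np.array([values[r] for r in sorted(values, key=lambda r: midpoints[r])])
    return np.interp(y, ys, vs)


class ToyDoseEngine:
    """Analytic beam-sum dose model on per-slice convex body polygons.

    Dose at an interior point p = (x, y, z):

        D(p) = A * g(y) * (1 - beta(y) * exp(-r_dip(x,z)^2 / 2 sigma^2)) *
               sum_b w_b * exp(-mu * depth_b(p))

    with depth_b the distance from p to the body surface along beam b's
    source direction, w_b = 1 + a*cos(phi_b) the anterior weighting, the
    Gaussian factor a room-fixed dose valley carved around the planned cord
    axis whose depth beta(y) and the plan fluence g(y) interpolate linearly
    between region midpoints, and A the normalization constant fixed by the
    plan (the reference target point receives the per-fraction
    prescription).  Points outside the body receive zero dose.  The dose at
    a fixed interior point strictly increases when the body shrinks.
    """

    def __init__(self, params: EngineParams, partition: RegionPartition):
        self.params = params
        self.partition = partition
        self._midpoints = {
            r: 0.5 * (lo + hi) for r, (lo, hi) in partition.regions.items()
        }
        phi = 2.0 * math.pi * np.arange(params.n_beams) / params.n_beams
        # source directions in the (x, z) plane; phi = 0 is an anterior source
        self._sources = np.column_stack([np.sin(phi), np.cos(phi)])
        self._weights = 1.0 + params.anterior_weight * np.cos(phi)
        if np.any(self._weights <= 0):
            raise DomainError("anterior_weight must keep beam weights positive")

    # -- continuous cranio-caudal profiles --------------------------------

    def fluence(self, y):
        return _interp_profile(y, self._midpoints, self.params.region_fluence, 1.0)

    def dip_depth(self, y):
        return _interp_profile(
            y, self._midpoints, dict(self.params.dip_depth), 0.0
        )

    # -- per-slice physics -------------------------------------------------

    def _beam_sum(self, pts_xz: np.ndarray, polygon_points) -> np.ndarray:
        """sum_b w_b exp(-mu depth_b) at in-plane points; 0 outside body."""
        verts, normals = _convex_edges(np.asarray(polygon_points))
        p = np.atleast_2d(np.asarray(pts_xz, dtype=float))
        rel = p[:, None, :] - verts[None, :, :]  # (P, E, 2)
        sd = np.einsum("pez,ez->pe", rel, normals)
        inside = np.all(sd <= 1e-9, axis=1)
        denom = normals @ self._sources.T  # (E, B)
        numer = -sd  # (P, E): n . (v - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = numer[:, :, None] / denom[None, :, :]  # (P, E, B)
        t = np.where(denom[None, :, :] > 1e-12, t, np.inf)
        depth = t.min(axis=1)  # (P, B)
        dose = np.einsum(
            "pb,b->p", np.exp(-self.params.mu_per_mm * depth), self._weights
        )
        return np.where(inside, dose, 0.0)

    def _dip_radial(self, pts_xz: np.ndarray) -> np.ndarray:
        cx, cz = self.params.dip_center_xz
        d2 = (pts_xz[:, 0] - cx) ** 2 + (pts_xz[:, 1] - cz) ** 2
        return np.exp(-d2 / (2.0 * self.params.dip_sigma_mm**2))

    # -- public API --------------------------------------------------------

    def point_dose(self, external: Structure, point) -> float:
        """Dose (per fraction, Gy) at a single 3D point."""
        x, y, z = point
        ys = external.y_slices
        contour = external.contours[int(np.argmin(np.abs(ys - y)))]
        pts = np.array([[x, z]])
        raw = self._beam_sum(pts, contour.points)[0]
        dip = 1.0 - float(self.dip_depth(y)) * self._dip_radial(pts)[0]
        return self.params.norm_constant * float(self.fluence(y)) * dip * raw

    def normalize_to_reference(self, external: Structure, rx_per_fraction: float):
        """Fix the normalization constant so the reference target point of
        the (plan) anatomy receives the per-fraction prescription under an
        unmodulated (unit) fluence profile."""
        saved = self.params.region_fluence
        self.params.region_fluence = {}
        self.params.norm_constant = 1.0
        try:
            raw = self.point_dose(external, self.params.ref_point)
        finally:
            self.params.region_fluence = saved
        if raw <= 0:
            raise GeometryError("reference point receives zero dose")
        self.params.norm_constant = rx_per_fraction / raw

    def dose_grid(
        self,
        external: Structure,
        anatomy_shift: ShiftVector | None,
        grid_spec: GridSpec,
        mask: np.ndarray | None = None,
    ) -> DoseGrid:
        """Per-fraction dose grid with the anatomy rigidly shifted.

        Beams, the dose valley and the fluence profile stay fixed in the
        plan frame; only the body (attenuation geometry) moves.  With a
        boolean ``mask`` only the masked voxels are evaluated (the rest of
        the grid is zero) -- used when only structure doses are needed.
        """
        if anatomy_shift is not None and (
            anatomy_shift.dx or anatomy_shift.dy or anatomy_shift.dz
        ):
            external = translate_structure(external, anatomy_shift)
        xs = grid_spec.axis_coords(0)
        ys = grid_spec.axis_coords(1)
        zs = grid_spec.axis_coords(2)
        xx, zz = np.meshgrid(xs, zs, indexing="ij")
        full_pts = np.column_stack([xx.ravel(), zz.ravel()])

        owned = _owned_planes(external, grid_spec.empty_grid())
        cache: dict[bytes, np.ndarray] = {}
        values = np.zeros(grid_spec.shape)
        dip_full = self._dip_radial(full_pts)
        for j in range(grid_spec.shape[1]):
            contour = owned.get(j)
            if contour is None:
                continue
            scale = self.params.norm_constant * float(self.fluence(ys[j]))
            beta = float(self.dip_depth(ys[j]))
            if mask is None:
                key = np.asarray(contour.points).tobytes()
                if key not in cache:
                    cache[key] = self._beam_sum(full_pts, contour.points)
                plane = scale * (1.0 - beta * dip_full) * cache[key]
                values[:, j, :] = plane.reshape(xx.shape)
            else:
                sel = mask[:, j, :].ravel()
                if not sel.any():
                    continue
                pts = full_pts[sel]
                raw = self._beam_sum(pts, contour.points)
                plane = scale * (1.0 - beta * dip_full[sel]) * raw
                buf = np.zeros(sel.shape)
                buf[sel] = plane
                values[:, j, :] = buf.reshape(xx.shape)
        return DoseGrid(
            origin=grid_spec.origin, spacing=grid_spec.spacing, values=values
        )


def toy_dose_engine(
    external: Structure,
    anatomy_shift: ShiftVector,
    grid_spec: GridSpec,
    partition: RegionPartition,
    params: EngineParams | None = None,
) -> DoseGrid:
    """Functional wrapper over :class:`ToyDoseEngine` (see its docstring)."""
    engine = ToyDoseEngine(params or EngineParams(), partition)
    return engine.dose_grid(external, anatomy_shift, grid_spec)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _ellipse_contour(y: float, a: float, b: float, n: int) -> Contour:
    t = 2.0 * math.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    return Contour(y, tuple(map(tuple, pts)))


def _circle_contour(y: float, cx: float, cz: float, r: float, n: int) -> Contour:
    t = 2.0 * math.pi * np.arange(n) / n
    pts = np.column_stack([cx + r * np.cos(t), cz + r * np.sin(t)])
    return Contour(y, tuple(map(tuple, pts)))


@dataclass
class Phantom:
    """A fully built synthetic course baseline (plan state)."""

    spec: PhantomSpec
    engine: ToyDoseEngine
    partition: RegionPartition
    external: Structure
    sc: Structure
    sc_by_region: dict[str, Structure]
    grid_spec: GridSpec
    plan: DoseGrid  # per-fraction planned dose
    planning_ssa: dict[str, float]  # cm^2, measured on the phantom polygons
    planned_dmax: dict[str, float]  # Gy, course scale
    region_masks: dict[str, np.ndarray]

    def region_grid_spec(self, region: str, pad_mm: float = 10.0) -> GridSpec:
        """Grid window of one region (padded in y for displaced anatomy)."""
        lo, hi = self.partition.regions[region]
        ys = self.grid_spec.axis_coords(1)
        j = np.where((ys >= lo - pad_mm) & (ys < hi + pad_mm))[0]
        return GridSpec(
            origin=(
                self.grid_spec.origin[0],
                float(ys[j[0]]),
                self.grid_spec.origin[2],
            ),
            spacing=self.grid_spec.spacing,
            shape=(self.grid_spec.shape[0], len(j), self.grid_spec.shape[2]),
        )


def _default_grid_spec(spec: PhantomSpec) -> GridSpec:
    s = spec.grid_spacing_mm
    ip = spec.inplane_spacing_mm
    y_lo, y_hi = spec.y_range
    ny = int(round((y_hi - y_lo) / s)) + 8  # one pad slab each end
    n_ip = int(round(40.0 / ip)) + 1  # +/- 20 mm about the cord axis
    return GridSpec(
        origin=(-20.0, y_lo - 3.5 * s, spec.cord_center_z_mm - 20.0),
        spacing=(ip, s, ip),
        shape=(n_ip, ny, n_ip),
    )


def make_phantom(
    spec: PhantomSpec | None = None,
    seed: int = 0,
    engine_params: EngineParams | None = None,
    grid_spec: GridSpec | None = None,
) -> Phantom:
    """Build the phantom anatomy and its calibrated planned dose.

    Deterministic given its arguments (``seed`` is accepted for interface
    symmetry with the samplers; the phantom itself is not random).  The
    cranio-caudal fluence profile of the engine is calibrated by fixed-point
    iteration so the planned per-region cord D(0.1cc), at course scale,
    lands on the configured targets.
    """
    spec = spec or PhantomSpec()
    partition = spec.partition()
    grid_spec = grid_spec or _default_grid_spec(spec)
    params = engine_params or EngineParams(
        dip_center_xz=(0.0, spec.cord_center_z_mm)
    )
    engine = ToyDoseEngine(params, partition)

    mids = spec.region_midpoints()
    order = sorted(mids, key=mids.get)
    mid_y = np.array([mids[r] for r in order])
    ys = grid_spec.axis_coords(1)
    y_lo, y_hi = spec.y_range

    # calibrate the cranio-caudal area profile: the slice area interpolates
    # linearly between region-midpoint nodes, so the per-region *median*
    # slice area differs from the node value wherever the profile kinks
    # (the mid-neck narrowing); fixed-point-adjust the nodes until the
    # measured medians equal the configured SSAs
    b_ap = spec.body_ap_semi_axis_mm
    poly_factor = (  # regular n-gon underestimates the ellipse area
        spec.n_body_vertices / (2 * math.pi) * math.sin(2 * math.pi / spec.n_body_vertices)
    )
    nodes = {r: spec.region_ssa_cm2[r] * 100.0 for r in REGIONS}  # mm^2
    for _ in range(60):
        node_arr = np.array([nodes[r] for r in order])
        worst = 0.0
        for r in REGIONS:
            lo, hi = spec.region_windows[r]
            in_win = ys[(ys >= lo) & (ys < hi)]
            median = poly_factor * float(
                np.median(np.interp(in_win, mid_y, node_arr))
            )
            target = spec.region_ssa_cm2[r] * 100.0
            worst = max(worst, abs(median - target) / target)
            nodes[r] *= target / median
        if worst < 1e-12:
            break
    node_arr = np.array([nodes[r] for r in order])

    ext_contours, sc_contours = [], []
    for y in ys:
        area_mm2 = float(np.interp(y, mid_y, node_arr))
        a_lr = area_mm2 / (math.pi * b_ap)
        ext_contours.append(
            _ellipse_contour(float(y), a_lr, b_ap, spec.n_body_vertices)
        )
        if y_lo <= y < y_hi:
            sc_contours.append(
                _circle_contour(
                    float(y), 0.0, spec.cord_center_z_mm, spec.cord_radius_mm,
                    spec.n_cord_vertices,
                )
            )
    external = Structure("external", tuple(ext_contours), role="external")
    sc = Structure("spinal_cord", tuple(sc_contours), role="spinal_cord")
    sc_by_region = split_by_region(sc, partition)

    engine.normalize_to_reference(
        external, spec.prescription_gy / spec.n_fractions
    )

    # calibrate the fluence profile on the cord voxels only (fixed-point:
    # regional D(0.1cc) couples mildly to neighbouring nodes via the
    # interpolated profile)
    region_masks = {
        r: rasterize(sub, grid_spec.empty_grid())
        for r, sub in sc_by_region.items()
    }
    union = np.zeros(grid_spec.shape, dtype=bool)
    for m in region_masks.values():
        union |= m
    fluence = {r: 1.0 for r in REGIONS}
    for _ in range(20):
        engine.params.region_fluence = dict(fluence)
        masked = engine.dose_grid(external, None, grid_spec, mask=union)
        err = 0.0
        for r in REGIONS:
            d = scale_to_course(
                dmax_vol(masked, region_masks[r]), spec.n_fractions
            )
            target = spec.planned_dmax_targets_gy[r]
            err = max(err, abs(d - target) / target)
            fluence[r] *= target / d
        if err < 1e-9:
            break
    engine.params.region_fluence = dict(fluence)
    plan = engine.dose_grid(external, None, grid_spec)

    planned_dmax = {
        r: scale_to_course(dmax_vol(plan, region_masks[r]), spec.n_fractions)
        for r in REGIONS
    }
    planning_ssa = {
        r: region_ssa(external, partition.regions[r]) for r in REGIONS
    }
    return Phantom(
        spec=spec,
        engine=engine,
        partition=partition,
        external=external,
        sc=sc,
        sc_by_region=sc_by_region,
        grid_spec=grid_spec,
        plan=plan,
        planning_ssa=planning_ssa,
        planned_dmax=planned_dmax,
        region_masks=region_masks,
    )


# ---------------------------------------------------------------------------
# course sampling
# ---------------------------------------------------------------------------


@dataclass
class CourseSample:
    """A sampled synthetic course: phantom baseline plus fraction records."""

    phantom: Phantom
    model: UncertaintyModel
    records: list[FractionRecord]
    seed: int


def _sample_shift(rng: np.random.Generator, params, clip: float) -> ShiftVector:
    comps = []
    for mean, sd in params:
        val = rng.normal(mean, sd) if sd > 0 else mean
        comps.append(float(np.clip(val, -clip, clip)))
    return ShiftVector(*comps)


def _schedule(fraction: int, n_fractions: int) -> float:
    return (fraction - 1) / (n_fractions - 1)


def sample_course(
    model: UncertaintyModel | None = None,
    spec: PhantomSpec | None = None,
    n_patients: int = 10,
    seed: int = 0,
    compute_doses: bool = True,
    phantom: Phantom | None = None,
) -> CourseSample:
    """Sample a complete synthetic treatment course for a cohort.

    For every patient and imaging timepoint, per-region setup errors are
    drawn from the model's phase-dependent Gaussians (clipped at the
    plausible maximum) and the body shrinkage follows the patient's linear
    schedule.  When ``compute_doses`` is true, each (timepoint, region)
    receives course-scale D(0.1cc) values for the planned, delivered
    (shift + shrink), setup-only and contour-only variants computed with
    the toy engine on the displaced/clipped anatomy, plus the rapid
    ``displaced`` estimate read off the fixed planned dose grid.  Fully
    reproducible from ``seed``.
    """
    model = model or default_uncertainty_model()
    phantom = phantom or make_phantom(spec, seed)
    spec = phantom.spec
    rng = np.random.default_rng(seed)
    nfx = spec.n_fractions

    region_specs = {r: phantom.region_grid_spec(r) for r in REGIONS}
    region_grids = {r: g.empty_grid() for r, g in region_specs.items()}
    records: list[FractionRecord] = []
    for p in range(n_patients):
        patient = f"SYN{p + 1:02d}"
        end_shrink = {
            r: float(
                np.clip(
                    rng.normal(model.end_shrink_mean[r], model.end_shrink_sd[r])
                    if model.end_shrink_sd[r] > 0
                    else model.end_shrink_mean[r],
                    *model.shrink_clip,
                )
            )
            for r in REGIONS
        }
        for fraction in model.imaging_fractions:
            phase = model.phase_of(fraction)
            shifts = {
                r: _sample_shift(
                    rng, model.setup_params[r][phase], model.shift_clip_mm
                )
                for r in (HEAD,) + REGIONS
            }
            shrink = {
                r: end_shrink[r] * _schedule(fraction, nfx) for r in REGIONS
            }
            ssa = {}
            for r in REGIONS:
                noise = (
                    rng.normal(0.0, model.ssa_noise_sd_cm2)
                    if model.ssa_noise_sd_cm2 > 0
                    else 0.0
                )
                ssa[r] = max(
                    phantom.planning_ssa[r] * (1.0 - shrink[r]) + noise, 1e-6
                )

            dose_metrics: dict[str, dict[str, float]] = {}
            if compute_doses:
                any_shrink = any(shrink[r] != 0.0 for r in REGIONS)
                clipped = (
                    clip_external(phantom.external, shrink, phantom.partition)
                    if any_shrink
                    else phantom.external
                )
                for r in REGIONS:
                    gspec = region_specs[r]
                    s = shifts[r]
                    cord = phantom.sc_by_region[r]
                    cord_moved = translate_structure(cord, s)
                    mask_moved = rasterize(cord_moved, region_grids[r])
                    mask_plan = rasterize(cord, region_grids[r])
                    metrics = {"planned": phantom.planned_dmax[r]}

                    def engine_dmax(ext, mask, shift_vec):
                        grid = phantom.engine.dose_grid(
                            ext, shift_vec, gspec, mask=mask
                        )
                        return scale_to_course(dmax_vol(grid, mask), nfx)

                    metrics["delivered"] = engine_dmax(clipped, mask_moved, s)
                    metrics["setup"] = engine_dmax(
                        phantom.external, mask_moved, s
                    )
                    metrics["contour"] = engine_dmax(clipped, mask_plan, None)
                    est = dmax_displaced(
                        phantom.plan, cord, s, course_scale=nfx
                    )
                    metrics["displaced"] = est.dmax_displaced
                    dose_metrics[r] = metrics
            records.append(
                FractionRecord(
                    patient=patient,
                    fraction_index=fraction,
                    shifts=shifts,
                    ssa=ssa,
                    dose_metrics=dose_metrics,
                )
            )
    return CourseSample(phantom=phantom, model=model, records=records, seed=seed)


# ---------------------------------------------------------------------------
# linear-response generator for regression validation
# ---------------------------------------------------------------------------


def linear_contour_response(
    beta: float,
    change_pct: Sequence[float],
    noise_sd_pct: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (contour change %, D(0.1cc) change %) pairs with known slope.

    A declared validation mode: the dose response is exactly linear,
    ``y = beta * x + noise``, so regression recovery can be checked against
    ground truth.  Returns the (x, y) arrays.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(change_pct, dtype=float)
    noise = rng.normal(0.0, noise_sd_pct, size=x.shape) if noise_sd_pct > 0 else 0.0
    return x, beta * x + noise
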