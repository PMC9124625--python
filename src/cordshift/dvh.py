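"""Dose-volume metrics on masked dose grids.

The monitored statistic is the near-maximum dose D(0.1cc): the highest dose
received by at least 0.1 cm^3 of the structure.  The definition used here is
discrete voxel accumulation -- sort in-mask voxel doses descending,
accumulate voxel volumes, and report the dose of the voxel at which the
cumulative volume first reaches the threshold -- with no sub-voxel DVH
interpolation.  Per-fraction metrics are scaled linearly to the course total
before any comparison against planned values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyStructureError, InsufficientVolumeError
from .geometry import DoseGrid

__all__ = [
    "DoseMetric",
    "DVHCurve",
    "dmax_vol",
    "dmax_from_doses",
    "dvh",
    "scale_to_course",
    "percent_diff",
]

DEFAULT_VOLUME_CC = 0.1
DEFAULT_N_FRACTIONS = 33


@dataclass(frozen=True)
class DoseMetric:
    """A named dose statistic of one structure/region (value in Gy)."""

    name: str
    value: float
    volume_threshold: float = DEFAULT_VOLUME_CC
    structure: str = ""
    region: str = ""

    def __post_init__(self):
        if self.value < 0 or self.volume_threshold < 0:
            raise DomainError("dose metric value/threshold must be >= 0")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: volume (cc) receiving at least each bin dose (Gy)."""

    dose_bins: np.ndarray
    volume_ge: np.ndarray


def _masked_doses(grid: DoseGrid, mask: np.ndarray) -> np.ndarray:
    doses = grid.values[np.asarray(mask, dtype=bool)]
    if doses.size == 0:
        raise EmptyStructureError("empty mask: no in-structure voxels")
    return doses


def dmax_from_doses(doses: np.ndarray, voxel_volume_cc: float, v: float) -> float:
    """D(v) from a flat list of equal-volume voxel doses (see ``dmax_vol``)."""
    if v < 0:
        raise DomainError("volume threshold must be >= 0")
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise EmptyStructureError("empty mask: no in-structure voxels")
    vol = doses.size * voxel_volume_cc
    if vol < v:
        raise InsufficientVolumeError(
            f"mask volume {vol:.4f} cc below threshold {v} cc"
        )
    order = np.sort(doses)[::-1]
    if v == 0:
        return float(order[0])
    cum = voxel_volume_cc * np.arange(1, order.size + 1)
    idx = int(np.searchsorted(cum, v))
    return float(order[idx])


def dmax_vol(grid: DoseGrid, mask: np.ndarray, v: float = DEFAULT_VOLUME_CC) -> float:
    """Near-maximum dose D(v): the highest dose received by >= v cc.

    v = 0 returns the plain voxel maximum.  Ties are resolved by a stable
    descending dose sort, which is immaterial for the returned dose value.
    """
    return dmax_from_doses(_masked_doses(grid, mask), grid.voxel_volume_cc, v)


def dvh(grid: DoseGrid, mask: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative dose-volume histogram of the masked voxels."""
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    doses = _masked_doses(grid, mask)
    top = float(doses.max())
    bins = np.arange(0.0, top + bin_width, bin_width)
    volume = np.array(
        [grid.voxel_volume_cc * int((doses >= b).sum()) for b in bins]
    )
    return DVHCurve(dose_bins=bins, volume_ge=volume)


def scale_to_course(fraction_metric: float, n_fractions: int = DEFAULT_N_FRACTIONS) -> float:
    """Convert a per-fraction dose metric to the course total (x n_fractions)."""
    if n_fractions < 1:
        raise DomainError("n_fractions must be >= 1")
    return fraction_metric * n_fractions


def percent_diff(metric: float, planned: float) -> float:
    """Signed percentage difference 100 * (metric - planned) / planned."""
    if planned <= 0:
        raise DomainError("planned dose must be positive")
    return 100.0 * (metric - planned) / planned
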