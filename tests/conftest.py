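"""Shared fixtures: small analytic grids and session-scoped synthetic courses.

The phantom and the two 10-patient courses are expensive (seconds each), so
they are built once per session and shared; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cordshift import (
    Contour,
    DoseGrid,
    RegionPartition,
    Structure,
    make_phantom,
    sample_course,
    shift_only_model,
)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def default_course(phantom):
    """Default uncertainty model, 10 patients, 6 timepoints, with doses."""
    return sample_course(n_patients=10, seed=0, phantom=phantom)


@pytest.fixture(scope="session")
def shift_only_course(phantom):
    """Setup errors only (no shrinkage): the univariate shift simulation."""
    return sample_course(
        model=shift_only_model(), n_patients=10, seed=0, phantom=phantom
    )


# -- small geometry helpers -------------------------------------------------


def square_contour(y: float, side_mm: float, cx: float = 0.0, cz: float = 0.0):
    h = side_mm / 2.0
    return Contour(
        y, ((cx - h, cz - h), (cx + h, cz - h), (cx + h, cz + h), (cx - h, cz + h))
    )


def circle_contour(y: float, r_mm: float, cx: float = 0.0, cz: float = 0.0, n: int = 180):
    t = 2.0 * np.pi * np.arange(n) / n
    pts = tuple(zip(cx + r_mm * np.cos(t), cz + r_mm * np.sin(t)))
    return Contour(y, pts)


def uniform_grid(value: float, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return DoseGrid(origin=origin, spacing=spacing, values=np.full(shape, float(value)))


@pytest.fixture
def simple_partition():
    return RegionPartition(
        {"C6_C7": (0.0, 60.0), "C4_C5": (60.0, 100.0), "C1_C3": (100.0, 160.0)}
    )
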