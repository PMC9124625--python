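"""Course-level longitudinal analysis.

Aggregates the per-fraction imaging records of a treatment course into the
standard summaries: per-timepoint 3D setup-error statistics per neck region,
per-timepoint slice-surface-area (SSA) statistics with the average contour
change, paired head-vs-region Wilcoxon comparisons per direction, and the
linear regression of the cord D(0.1cc) change on the contour change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DomainError, ValidationError
from .geometry import HEAD, REGIONS, ShiftVector, contour_change, three_d_error

__all__ = [
    "FractionRecord",
    "RegressionFit",
    "WilcoxonResult",
    "ContourSummary",
    "summarize_setup_errors",
    "summarize_contour_changes",
    "compare_head_vs_region",
    "fit_contour_dose_regression",
    "estimate_contour_effect",
    "ols_fit",
    "dose_difference_table",
    "contour_regressions",
    "displaced_setup_pairs",
]

_AXIS_ATTR = {"x": "dx", "y": "dy", "z": "dz"}


@dataclass(frozen=True)
class FractionRecord:
    """One imaging timepoint of one patient.

    ``shifts`` maps region (HEAD, C1_C3, C4_C5, C6_C7) to its rigid setup
    error; ``ssa`` maps cord region to the measured external SSA (cm^2);
    ``dose_metrics`` optionally maps region -> {variant -> course-scale Gy}
    with variants such as planned/delivered/setup/contour/displaced.
    """

    patient: str
    fraction_index: int
    shifts: Mapping[str, ShiftVector] = field(default_factory=dict)
    ssa: Mapping[str, float] = field(default_factory=dict)
    dose_metrics: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.fraction_index < 1:
            raise DomainError("fraction_index must be >= 1")
        for region, a in self.ssa.items():
            if a <= 0:
                raise DomainError(f"SSA for {region} must be positive")


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares fit summary used by both estimation models."""

    slope: float
    intercept: float
    r_squared: float
    residual_mean: float
    residual_sd: float
    n: int

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(x) + self.intercept


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided Wilcoxon signed-rank comparison of paired setup errors."""

    p_value: float
    median_diff: float
    n: int


@dataclass(frozen=True)
class ContourSummary:
    """Per-timepoint SSA statistics and per-region average contour change."""

    ssa: pd.DataFrame
    average_change_pct: dict[str, float]


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares line fit with R^2 and residual summary.

    Raises DegenerateInputError for fewer than 3 points or a constant
    regressor.  A fit with (numerically) zero residual variance reports
    R^2 = 1 even when the response is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need >= 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise DegenerateInputError("regressor has zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    r2 = res.rvalue**2
    if not np.isfinite(r2):  # constant response
        ss_res = float(np.sum(resid**2))
        r2 = 1.0 if ss_res < 1e-24 * max(1.0, float(np.sum(y**2))) else 0.0
    sd = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        residual_mean=float(np.mean(resid)),
        residual_sd=sd,
        n=int(x.size),
    )


def _shift_or_raise(record: FractionRecord, region: str) -> ShiftVector:
    try:
        return record.shifts[region]
    except KeyError:
        raise ValidationError(
            f"record (patient={record.patient}, fraction={record.fraction_index}) "
            f"is missing a shift for region {region}"
        ) from None


def summarize_setup_errors(
    records: Iterable[FractionRecord],
    regions: Sequence[str] = (HEAD,) + REGIONS,
) -> pd.DataFrame:
    """Per-timepoint mean +/- SD of the 3D setup error per region.

    Returns a long-format table with columns [fraction, region, mean_mm,
    sd_mm, n] plus one "Average" row per region.  The grand mean is the mean
    of per-timepoint means (identical to the pooled mean for equal group
    sizes); the grand SD pools all observations.
    """
    records = list(records)
    if not records:
        raise ValidationError("no fraction records")
    rows = []
    for rec in records:
        for region in regions:
            rows.append(
                {
                    "fraction": rec.fraction_index,
                    "region": region,
                    "error_mm": three_d_error(_shift_or_raise(rec, region)),
                }
            )
    df = pd.DataFrame(rows)
    per_tp = (
        df.groupby(["region", "fraction"])["error_mm"]
        .agg(mean_mm="mean", sd_mm=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
        .reset_index()
    )
    grand = []
    for region in regions:
        sub = per_tp[per_tp.region == region]
        pooled = df[df.region == region]["error_mm"]
        grand.append(
            {
                "region": region,
                "fraction": "Average",
                "mean_mm": sub["mean_mm"].mean(),
                "sd_mm": pooled.std(ddof=1) if len(pooled) > 1 else 0.0,
                "n": int(sub["n"].sum()),
            }
        )
    out = pd.concat([per_tp, pd.DataFrame(grand)], ignore_index=True)
    out["region"] = pd.Categorical(out["region"], categories=regions, ordered=True)
    return out.sort_values(["region", "fraction"], key=_fraction_sort_key).reset_index(
        drop=True
    )


def _fraction_sort_key(col):
    if col.name == "fraction":
        return col.map(lambda v: np.inf if v == "Average" else float(v))
    return col


def summarize_contour_changes(
    records: Iterable[FractionRecord],
    planning_ssa: Mapping[str, float | Mapping[str, float]],
    regions: Sequence[str] = REGIONS,
    mode: str = "cohort",
) -> ContourSummary:
    """Per-timepoint SSA summary and the average contour change per region.

    ``planning_ssa`` gives the planning-CT SSA per region, either as a
    cohort value or as a per-patient map.  The average change (in %) is:

    * ``mode="cohort"``: mean over timepoints of the change of the cohort-
      mean SSA against the cohort planning SSA;
    * ``mode="per_patient"``: each patient's change against their own
      planning SSA, averaged over timepoints and then over patients.

    The two coincide for equal cohorts with a common planning SSA.
    """
    if mode not in ("cohort", "per_patient"):
        raise DomainError(f"unknown mode {mode!r}")
    records = list(records)
    rows = []
    for rec in records:
        for region in regions:
            if region not in rec.ssa:
                raise ValidationError(
                    f"record (patient={rec.patient}, fraction={rec.fraction_index}) "
                    f"is missing SSA for region {region}"
                )
            rows.append(
                {
                    "fraction": rec.fraction_index,
                    "region": region,
                    "patient": rec.patient,
                    "ssa_cm2": rec.ssa[region],
                }
            )
    df = pd.DataFrame(rows)

    def plan_for(region: str, patient: str) -> float:
        ref = planning_ssa[region]
        if isinstance(ref, Mapping):
            ref = ref[patient]
        if ref <= 0:
            raise DomainError(f"planning SSA for {region} must be positive")
        return float(ref)

    ssa_tab = (
        df.groupby(["region", "fraction"])["ssa_cm2"]
        .agg(mean_cm2="mean", sd_cm2=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
        .reset_index()
    )
    avg: dict[str, float] = {}
    for region in regions:
        if mode == "cohort":
            ref = planning_ssa[region]
            if isinstance(ref, Mapping):
                ref = float(np.mean(list(ref.values())))
            sub = ssa_tab[ssa_tab.region == region]
            changes = [contour_change(ref, m) for m in sub["mean_cm2"]]
        else:
            sub = df[df.region == region]
            changes = (
                sub.groupby("patient")
                .apply(
                    lambda g: np.mean(
                        [
                            contour_change(plan_for(region, g.name), a)
                            for a in g["ssa_cm2"]
                        ]
                    ),
                    include_groups=False,
                )
                .tolist()
            )
        avg[region] = 100.0 * float(np.mean(changes))
    return ContourSummary(ssa=ssa_tab, average_change_pct=avg)


def compare_head_vs_region(
    records: Iterable[FractionRecord],
    direction: str,
    regions: Sequence[str] = REGIONS,
) -> dict[str, WilcoxonResult]:
    """Paired Wilcoxon signed-rank test of region vs head setup errors.

    Pairs are the per-record (patient, fraction) signed errors along one
    axis (``direction`` in {"x", "y", "z"}).  Two-sided; zero differences
    are dropped (Wilcoxon's rule); the exact null is used for small
    tie-free samples, the tie-corrected normal approximation otherwise.
    A comparison whose differences are all zero reports p = 1 (no evidence
    of a difference) rather than failing.
    """
    if direction not in _AXIS_ATTR:
        raise DomainError("direction must be one of 'x', 'y', 'z'")
    attr = _AXIS_ATTR[direction]
    records = list(records)
    out: dict[str, WilcoxonResult] = {}
    for region in regions:
        head = np.array(
            [getattr(_shift_or_raise(r, HEAD), attr) for r in records]
        )
        reg = np.array(
            [getattr(_shift_or_raise(r, region), attr) for r in records]
        )
        diffs = reg - head
        median = float(np.median(diffs))
        if np.all(diffs == 0):
            out[region] = WilcoxonResult(1.0, 0.0, len(diffs))
            continue
        res = stats.wilcoxon(
            reg, head, zero_method="wilcox", alternative="two-sided"
        )
        out[region] = WilcoxonResult(float(res.pvalue), median, len(diffs))
    return out


def fit_contour_dose_regression(
    per_fraction_mean_change_pct: Sequence[float],
    per_fraction_mean_dmax_change_pct: Sequence[float],
) -> RegressionFit:
    """OLS fit of the cohort-mean D(0.1cc) change (%) on the cohort-mean
    contour change (%) across imaging timepoints (one point per timepoint)."""
    return ols_fit(per_fraction_mean_change_pct, per_fraction_mean_dmax_change_pct)


def estimate_contour_effect(fit: RegressionFit, change_pct: float) -> float:
    """Predicted D(0.1cc) change (%) for a given contour change (%)."""
    return float(fit.predict(change_pct))


# ---------------------------------------------------------------------------
# course-level dose analyses (records carrying dose metrics)
# ---------------------------------------------------------------------------


def dose_difference_table(
    records: Iterable[FractionRecord],
    regions: Sequence[str] = REGIONS,
) -> pd.DataFrame:
    """Long table of course-scale Dmax values and percent differences.

    One row per (patient, fraction, region, variant) for every dose variant
    present in the records; percentages are against the same region's own
    planned value.
    """
    from .dvh import percent_diff  # local import to avoid cycle at import time

    rows = []
    for rec in records:
        for region in regions:
            metrics = rec.dose_metrics.get(region)
            if not metrics:
                continue
            planned = metrics["planned"]
            for variant, value in metrics.items():
                if variant == "planned":
                    continue
                rows.append(
                    {
                        "patient": rec.patient,
                        "fraction": rec.fraction_index,
                        "region": region,
                        "variant": variant,
                        "dmax_gy": value,
                        "planned_gy": planned,
                        "pct_vs_planned": percent_diff(value, planned),
                    }
                )
    if not rows:
        raise ValidationError("no dose metrics present in the records")
    return pd.DataFrame(rows)


def contour_regressions(
    records: Iterable[FractionRecord],
    planning_ssa: Mapping[str, float],
    regions: Sequence[str] = REGIONS,
) -> dict[str, RegressionFit]:
    """Per-region fit of mean Dmax change (%) on mean contour change (%).

    For each imaging timepoint the cohort-mean contour change (from the SSA
    records against the planning SSA) is paired with the cohort-mean
    contour-only Dmax change; one OLS fit per region across timepoints.
    """
    records = list(records)
    fits = {}
    for region in regions:
        by_tp: dict[int, list[tuple[float, float]]] = {}
        for rec in records:
            metrics = rec.dose_metrics.get(region)
            if not metrics or "contour" not in metrics:
                raise ValidationError(
                    f"record (patient={rec.patient}, fraction={rec.fraction_index}) "
                    f"lacks a contour-only dose metric for {region}"
                )
            from .dvh import percent_diff

            x = 100.0 * contour_change(planning_ssa[region], rec.ssa[region])
            y = percent_diff(metrics["contour"], metrics["planned"])
            by_tp.setdefault(rec.fraction_index, []).append((x, y))
        xs = [float(np.mean([p[0] for p in pts])) for pts in by_tp.values()]
        ys = [float(np.mean([p[1] for p in pts])) for pts in by_tp.values()]
        fits[region] = fit_contour_dose_regression(xs, ys)
    return fits


def displaced_setup_pairs(
    records: Iterable[FractionRecord],
    regions: Sequence[str] = REGIONS,
) -> np.ndarray:
    """Pooled (Dmax_setup, Dmax_displaced) pairs (Gy) across regions."""
    pairs = []
    for rec in records:
        for region in regions:
            metrics = rec.dose_metrics.get(region)
            if metrics and "setup" in metrics and "displaced" in metrics:
                pairs.append((metrics["setup"], metrics["displaced"]))
    if not pairs:
        raise ValidationError("no setup/displaced metric pairs in the records")
    return np.asarray(pairs)
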