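# cordshift

Quantifies how neck **setup errors** and progressive **body-contour
shrinkage** change the spinal-cord near-maximum dose during fractionated
head-and-neck (nasopharyngeal) radiotherapy, and provides a **rapid
estimator** of the cord dose that needs no dose recalculation — for medical
physicists studying adaptive re-planning triggers and for anyone who needs
a fully synthetic, reproducible testbed for organ-at-risk dose-of-the-day
analyses.

## The problem and the method

During a 33-fraction course the cervical anatomy is not static: rigid
registration of in-room CBCT to the planning CT shows region-dependent
setup errors (cervical levels C1–C3, C4–C5, C6–C7 behave differently, and
the lower neck drifts posteriorly and inflates late in the course), while
the external contour shrinks as soft tissue is lost. Both move the spinal
cord relative to the planned dose distribution and can push its
near-maximum dose

> D(0.1cc) — the highest dose received by at least 0.1 cm³ of the cord

above the 40 Gy cord constraint (45 Gy for the 5 mm planning organ-at-risk
volume, SC-PRV).

`cordshift` implements the two univariate analyses and the estimator:

* **Contour change.** Per region, the slice surface area
  SSA = median over axial slices of the body cross-section, and the change
  (SSA_CT − SSA_CBCT)/SSA_CT. The cohort-mean D(0.1cc) change regresses
  linearly on the cohort-mean contour change (one OLS fit per region).
* **Setup error.** The measured per-region shift (Δx, Δy, Δz), its 3D
  magnitude √(Δx²+Δy²+Δz²), and the rapid index **Dmax_displaced**: displace
  the *planned* cord contour by the shift and re-read the *fixed planned*
  dose grid (trilinear interpolation at the displaced voxel centres). If the
  dose distribution is unchanged by a small rigid setup error,
  Dmax_displaced tracks a full recalculation — the package verifies this on
  synthetic courses (pooled R² ≈ 0.99, residuals ≈ 0.0 ± 0.2 Gy).
* **Trigger.** Estimates above the constraint flag the region for adaptive
  re-planning review.

Because clinical CBCT/CT courses cannot be shipped, the package includes a
first-class synthetic module: a neck phantom (elliptical body sized to the
per-region planning SSAs, cord as a posterior cylinder), a declared toy
dose engine (coplanar exponential-attenuation beams, anterior weighting, a
plan-carved dose valley around the cord, per-region D(0.1cc) calibration),
and an uncertainty model reproducing the per-phase setup-error statistics
and the monotone shrinkage schedule.

## Worked example

```python
from cordshift import ShiftVector, dmax_displaced, make_phantom, trigger_replan

phantom = make_phantom()          # calibrated synthetic plan
shifts = {"C1_C3": ShiftVector(2.0, 0.0, -3.0),   # mm, (LR, SI, AP)
          "C4_C5": ShiftVector(0.5, 0.0, -1.5),
          "C6_C7": ShiftVector(0.0, 0.0, -2.0)}
estimates = []
for region, shift in shifts.items():
    est = dmax_displaced(phantom.plan, phantom.sc_by_region[region], shift,
                         course_scale=phantom.spec.n_fractions)
    estimates.append(est)
    print(f"{region}: planned {est.dmax_planned:.1f} Gy -> "
          f"displaced {est.dmax_displaced:.1f} Gy ({est.percent_change:+.1f}%)")
report = trigger_replan(estimates, constraint=40.0)
print("flagged:", report.flagged_regions)
```

prints

```
C1_C3: planned 37.4 Gy -> displaced 40.5 Gy (+8.3%)
C4_C5: planned 36.2 Gy -> displaced 36.8 Gy (+1.7%)
C6_C7: planned 33.2 Gy -> displaced 33.5 Gy (+0.8%)
flagged: ('spinal_cord:C1_C3',)
```

A 3 mm posterior + 2 mm lateral error at C1–C3 — where the cord sits in the
steepest dose gradient below the target — raises the estimated cord
D(0.1cc) from 37.4 Gy past the 40 Gy constraint, so that region is flagged;
the same-day lower-neck errors barely matter because the surrounding dose
is flat there.

The same flow is available from the shell:

```bash
cordshift simulate --seed 1 --patients 10 --out course/
cordshift analyze  --fixture course/ --out report/
cordshift estimate --fixture course/ --shift C1_C3 2.0 0.0 -3.0
cordshift report   --fixture course/ --out report/
```

`analyze`/`report` emit the per-timepoint setup-error table, the SSA table
with average contour changes, per-fraction percent dose differences, both
regression fits (JSON) and the re-planning screen. DICOM RTDOSE/RTSTRUCT
can be read in place of the native fixture format (`read_dicom_rt`).

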