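"""Unit conventions, centralized.

All lengths are millimetres, areas cm^2, volumes cm^3 (cc), doses Gy.
Axes follow the IGRT registration convention for the head-and-neck site:
x = left-right (LR), y = inferior-superior (SI, increasing cranially),
z = anterior-posterior (AP, increasing anteriorly).  Axial contour planes
are x-z polygons at constant y.
"""

MM2_PER_CM2 = 100.0
MM3_PER_CC = 1000.0


def mm2_to_cm2(a: float) -> float:
    return a / MM2_PER_CM2


def mm3_to_cc(v: float) -> float:
    return v / MM3_PER_CC
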