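"""Fit the virtual-origin calibration to distorted 24-point gazing data.

The 24 screen targets are pushed through a known distortion (shift, shear,
rotation, per-semi-axis scaling) to emulate what the raw signal-integral
features of a cross-shaped electrode recording look like; the nine-parameter
fit then has to undo it.
"""

import numpy as np

from eogcal import (
    DistortionSpec,
    apply_proposed,
    fit_proposed,
    make_simulation_pattern,
    make_target_grid,
    pixel_distance_error,
)

grid = make_target_grid()  # 8 directions x 100/200/300 px, centered on (0,0)

distortion = DistortionSpec(
    pattern="d",                     # dilatation + rotation + shear + translation
    scales=(0.8, 1.3, 1.1, 0.9),     # s1..s4 for the +y/-y/+x/-x semi-axes
    rotation=np.radians(20.0),       # cross-shaped electrodes rotate the cloud
    shear=(0.15, -0.10),
    translation=(40.0, -25.0),       # virtual-origin offset in feature units
    noise_sd=2.0,                    # 2 px of raw-feature noise
    seed=42,
)
data = make_simulation_pattern(grid, distortion)

params = fit_proposed(data)
corrected = apply_proposed(params, data.raw)
report = pixel_distance_error(corrected, grid)

print("fitted parameters (canonical gauge):")
print(f"  virtual origin (Tx, Ty) = ({params.tx:+7.2f}, {params.ty:+7.2f})")
print(f"  shear (m1, m2)          = ({params.m1:+.4f}, {params.m2:+.4f})")
print(f"  rotation theta          = {np.degrees(params.theta):+.2f} deg")
print(f"  dilatations s1..s4      = {params.s1:.4f}, {params.s2:.4f}, "
      f"{params.s3:.4f}, {params.s4:.4f}")
print(f"residual error: mean |dx| = {report.mean[0]:.2f} px, "
      f"mean |dy| = {report.mean[1]:.2f} px (2 px noise floor)")
print(
    "With noise_sd=0 the residuals drop to ~1e-13 px: the model family\n"
    "contains the exact inverse of the generating distortion."
)
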