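"""Target grids, simulated distortion patterns and error metrics.

The comparative experiment distorts a symmetric 24-point target grid with
known dilatation/rotation/shear/translation (patterns a-d of increasing
complexity), fits both calibration methods to the resulting (target, raw)
pairs and scores them with per-axis pixel-distance errors and gaze-angle
errors at a fixed viewing geometry (35 cm eye-screen distance by default).

Distorted raw data are produced with the *exact inverse* of the proposed
piecewise model, so the proposed fit has a zero-error optimum by
construction; any error it shows is estimation error, while the quadrant
baseline additionally suffers from polarity disruption when the rotation
moves raw points across sign-quadrant boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    AffineParams,
    GazeDataset,
    apply_proposed,
    apply_quadrant,
    fit_proposed,
    fit_quadrant,
    inverse_proposed,
)

__all__ = [
    "TargetGrid",
    "DistortionSpec",
    "ViewingGeometry",
    "ErrorReport",
    "make_target_grid",
    "make_simulation_pattern",
    "pixel_distance_error",
    "gaze_angle_error",
    "run_comparison",
    "PATTERNS",
]

PATTERNS = ("a", "b", "c", "d")

COMPARISON_COLUMNS = [
    "pattern",
    "method",
    "mean_abs_dx_px",
    "mean_abs_dy_px",
    "sd_dx_px",
    "sd_dy_px",
    "mean_angle_x_deg",
    "mean_angle_y_deg",
    "sd_angle_x_deg",
    "sd_angle_y_deg",
]


def _label_for_angle(angle: float) -> str:
    """Semi-axis or quadrant label for a grid direction (radians)."""
    deg = np.degrees(angle) % 360.0
    axis = {0.0: "+x", 90.0: "+y", 180.0: "-x", 270.0: "-y"}
    for a, lbl in axis.items():
        if np.isclose(deg, a, atol=1e-9):
            return lbl
    if deg < 90:
        return "Q1"
    if deg < 180:
        return "Q2"
    if deg < 270:
        return "Q3"
    return "Q4"


@dataclass(frozen=True)
class TargetGrid:
    """24 screen targets, point-symmetric about the screen center (0, 0)."""

    points: np.ndarray
    labels: tuple[str, ...]
    n_directions: int
    eccentricities: tuple[float, ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (24, 2):
            raise ValueError(f"a target grid holds exactly 24 points, got shape {pts.shape}")
        if not np.allclose(pts.mean(axis=0), 0.0, atol=1e-9):
            raise ValueError("target grid must be symmetric about (0, 0)")
        object.__setattr__(self, "points", pts)


def make_target_grid(
    n_directions: int = 8, eccentricities: tuple[float, ...] = (100.0, 200.0, 300.0)
) -> TargetGrid:
    """Radial 24-point grid: equally spaced directions x eccentricities.

    The direction count must be divisible by 4 so the four screen semi-axes
    are each populated (needed by both calibration methods), and
    ``n_directions * len(eccentricities)`` must equal 24.
    """
    eccentricities = tuple(float(e) for e in eccentricities)
    if n_directions * len(eccentricities) != 24:
        raise ValueError(
            f"{n_directions} directions x {len(eccentricities)} eccentricities != 24 points"
        )
    if n_directions % 4 != 0:
        raise ValueError("n_directions must be divisible by 4 to cover all four semi-axes")
    if min(eccentricities) <= 0:
        raise ValueError("eccentricities must be positive")
    angles = 2.0 * np.pi * np.arange(n_directions) / n_directions
    pts, labels = [], []
    for ang in angles:
        for ecc in eccentricities:
            pts.append([ecc * np.cos(ang), ecc * np.sin(ang)])
            labels.append(_label_for_angle(ang))
    pts = np.asarray(pts)
    # snap the on-axis coordinates that are analytically zero
    pts[np.abs(pts) < 1e-9] = 0.0
    return TargetGrid(
        points=pts, labels=tuple(labels), n_directions=n_directions, eccentricities=eccentricities
    )


@dataclass(frozen=True)
class DistortionSpec:
    """A known distortion applied (inversely) to targets to fake raw data.

    Patterns mirror the simulation experiment: (a) dilatation+rotation,
    (b) adds translation, (c) adds shear instead, (d) all four. The
    constraints are validated, e.g. pattern "a" must have zero shear and
    translation.
    """

    pattern: str = "d"
    scales: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)  # s1..s4
    rotation: float = 0.0  # radians
    shear: tuple[float, float] = (0.0, 0.0)  # (m1, m2)
    translation: tuple[float, float] = (0.0, 0.0)  # (tx, ty), feature units
    noise_sd: float = 0.0  # isotropic, raw-space
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        no_shear = self.shear == (0.0, 0.0)
        no_translation = self.translation == (0.0, 0.0)
        if self.pattern == "a" and not (no_shear and no_translation):
            raise ValueError("pattern 'a' allows only dilatation and rotation")
        if self.pattern == "b" and not no_shear:
            raise ValueError("pattern 'b' allows dilatation, rotation and translation only")
        if self.pattern == "c" and not no_translation:
            raise ValueError("pattern 'c' allows dilatation, rotation and shear only")

    def affine_params(self) -> AffineParams:
        return AffineParams(
            tx=self.translation[0],
            ty=self.translation[1],
            m1=self.shear[0],
            m2=self.shear[1],
            theta=self.rotation,
            s1=self.scales[0],
            s2=self.scales[1],
            s3=self.scales[2],
            s4=self.scales[3],
        )


def make_simulation_pattern(grid: TargetGrid, spec: DistortionSpec) -> GazeDataset:
    """Push targets through the inverse distortion model to simulate raw data.

    ``raw = InversePiecewiseModel(target) + N(0, noise_sd²)``; the proposed
    calibration can therefore in principle achieve exactly zero error on
    noiseless data. Identical spec (including seed) gives identical data.
    """
    params = spec.affine_params()
    raw = inverse_proposed(params, grid.points)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        raw = raw + rng.normal(0.0, spec.noise_sd, raw.shape)
    return GazeDataset(targets=grid.points.copy(), raw=raw, labels=list(grid.labels))


@dataclass(frozen=True)
class ViewingGeometry:
    """Eye-to-screen distance and pixel pitch, for the angle metric."""

    distance_cm: float = 35.0
    pixel_pitch_mm: float = 0.25

    def __post_init__(self) -> None:
        if self.distance_cm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("viewing distance and pixel pitch must be positive")

    def angle_deg(self, coords_px: np.ndarray) -> np.ndarray:
        """Visual angle (degrees) subtended by a per-axis pixel coordinate."""
        return np.degrees(
            np.arctan(np.asarray(coords_px, dtype=float) * self.pixel_pitch_mm
                      / (self.distance_cm * 10.0))
        )


@dataclass(frozen=True)
class ErrorReport:
    """Per-point absolute errors per axis with their means and SDs.

    ``units`` is "px" for pixel-distance errors or "deg" for gaze-angle
    errors. SDs are population SDs by default (``ddof=0``).
    """

    abs_err: np.ndarray  # (n, 2): |error| per point for x and y
    units: str
    ddof: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.abs_err.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.abs_err.std(axis=0, ddof=self.ddof)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abs_err, columns=[f"abs_err_x_{self.units}", f"abs_err_y_{self.units}"]
        )


def pixel_distance_error(corrected: np.ndarray, grid: TargetGrid, ddof: int = 0) -> ErrorReport:
    """Per-axis absolute pixel error of corrected points vs their targets."""
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != grid.points.shape:
        raise ValueError(
            f"corrected points shape {corrected.shape} != grid shape {grid.points.shape}"
        )
    return ErrorReport(abs_err=np.abs(corrected - grid.points), units="px", ddof=ddof)


def gaze_angle_error(
    corrected: np.ndarray,
    grid: TargetGrid,
    geom: ViewingGeometry | None = None,
    ddof: int = 0,
) -> ErrorReport:
    """Per-axis gaze-angle error (degrees) at the given viewing geometry.

    Each axis coordinate is converted to a visual angle with the exact
    atan form before differencing, so large offsets are not overstated by
    the small-angle approximation.
    """
    geom = geom if geom is not None else ViewingGeometry()
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != grid.points.shape:
        raise ValueError(
            f"corrected points shape {corrected.shape} != grid shape {grid.points.shape}"
        )
    err = np.abs(geom.angle_deg(corrected) - geom.angle_deg(grid.points))
    return ErrorReport(abs_err=err, units="deg", ddof=ddof)


def run_comparison(
    grid: TargetGrid,
    specs: list[DistortionSpec],
    geom: ViewingGeometry | None = None,
) -> pd.DataFrame:
    """Fit both methods on each distortion pattern and tabulate their errors.

    Returns one row per (pattern, method) with mean and SD of the per-axis
    pixel and angle errors over the 24 points.
    """
    geom = geom if geom is not None else ViewingGeometry()
    rows = []
    for spec in specs:
        data = make_simulation_pattern(grid, spec)
        corrected = {
            "proposed": apply_proposed(fit_proposed(data), data.raw),
            "quadrant": apply_quadrant(fit_quadrant(data), data.raw),
        }
        for method, pts in corrected.items():
            pe = pixel_distance_error(pts, grid)
            ae = gaze_angle_error(pts, grid, geom)
            rows.append(
                {
                    "pattern": spec.pattern,
                    "method": method,
                    "mean_abs_dx_px": pe.mean[0],
                    "mean_abs_dy_px": pe.mean[1],
                    "sd_dx_px": pe.sd[0],
                    "sd_dy_px": pe.sd[1],
                    "mean_angle_x_deg": ae.mean[0],
                    "mean_angle_y_deg": ae.mean[1],
                    "sd_angle_x_deg": ae.sd[0],
                    "sd_angle_y_deg": ae.sd[1],
                }
            )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
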