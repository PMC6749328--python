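"""Virtual-origin 24-point affine calibration and the quadrant baseline.

Raw gaze features (signal-integral pairs) are related to the on-screen
target coordinates by an affine distortion: the measured cloud is shifted,
sheared (its axes are not perpendicular), rotated (markedly so for the
cross-shaped electrode arrangement) and anisotropically scaled. The
proposed calibration treats all 24 calibration points simultaneously:

1. translate a *virtual origin* — an imaginary 25th point estimated from
   the data — to (0, 0);
2. shear by (m1, m2) to restore perpendicular axes;
3. rotate by θ to align with the screen axes;
4. dilate per semi-axis: s1 scales the +y side, s2 the −y side, s3 the +x
   side, s4 the −x side.

In homogeneous coordinates the first three steps compose into a single
3x3 matrix [Rotation][Shear][Translation]; with a common (sx, sy)
dilatation the full product [Dilatation][Rotation][Shear][Translation]
is returned by :func:`homogeneous_matrix`. Nine scalars parametrize the
method (Tx, Ty, m1, m2, θ, s1..s4).

The conventional baseline instead splits the 24 points into the four
sign-quadrants of the raw data and fits an independent 7-parameter
transform (translation 2, shear 2, rotation 1, dilatation 2) per quadrant,
28 parameters in total. Because quadrant membership is decided by the raw
coordinate signs, a large rotation moves points across quadrant
boundaries ("polarity disruption") and degrades the fit; this failure
mode is exactly what the proposed method removes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationError",
    "GazePoint",
    "GazeDataset",
    "AffineParams",
    "QuadrantTransform",
    "QuadrantParams",
    "translation_matrix",
    "shear_matrix",
    "rotation_matrix",
    "dilatation_matrix",
    "homogeneous_matrix",
    "canonicalize",
    "apply_proposed",
    "inverse_proposed",
    "fit_proposed",
    "quadrant_index",
    "apply_quadrant",
    "fit_quadrant",
    "count_parameters",
]

SEMI_AXIS_LABELS = ("+x", "-x", "+y", "-y")
QUADRANT_LABELS = ("Q1", "Q2", "Q3", "Q4")


class CalibrationError(ValueError):
    """Raised when a calibration fit is infeasible or degenerate."""


@dataclass(frozen=True)
class GazePoint:
    """One calibration pair: screen target (px) and raw measured feature."""

    target: tuple[float, float]
    raw: tuple[float, float]
    label: str = "interior"

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.target)) or not all(np.isfinite(self.raw)):
            raise ValueError("gaze point coordinates must be finite")


class GazeDataset:
    """A set of (target, raw) gaze pairs with semi-axis/quadrant labels.

    Calibration fits require exactly 24 points whose target set is
    symmetric about (0, 0), with at least two points on each semi-axis.
    """

    def __init__(self, targets: np.ndarray, raw: np.ndarray, labels: list[str]):
        self.targets = np.asarray(targets, dtype=float)
        self.raw = np.asarray(raw, dtype=float)
        self.labels = list(labels)
        if self.targets.shape != self.raw.shape or self.targets.ndim != 2 or self.targets.shape[1] != 2:
            raise ValueError("targets and raw must both have shape (n, 2)")
        if len(self.labels) != len(self.targets):
            raise ValueError("one label per point is required")
        if not (np.isfinite(self.targets).all() and np.isfinite(self.raw).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.targets)

    @classmethod
    def from_points(cls, points: list[GazePoint]) -> "GazeDataset":
        return cls(
            targets=np.array([p.target for p in points]),
            raw=np.array([p.raw for p in points]),
            labels=[p.label for p in points],
        )

    def points(self) -> list[GazePoint]:
        return [
            GazePoint(target=tuple(t), raw=tuple(r), label=l)
            for t, r, l in zip(self.targets, self.raw, self.labels)
        ]

    def semi_axis_mask(self, label: str) -> np.ndarray:
        if label not in SEMI_AXIS_LABELS:
            raise ValueError(f"unknown semi-axis label {label!r}")
        return np.array([l == label for l in self.labels])

    def validate_for_calibration(self) -> None:
        if len(self) != 24:
            raise CalibrationError(f"calibration requires exactly 24 points, got {len(self)}")
        centroid = self.targets.mean(axis=0)
        if not np.allclose(centroid, 0.0, atol=1e-6):
            raise CalibrationError("target grid must be symmetric about (0, 0)")
        for label in SEMI_AXIS_LABELS:
            if self.semi_axis_mask(label).sum() < 2:
                raise CalibrationError(f"need at least 2 points on semi-axis {label}")


@dataclass(frozen=True)
class AffineParams:
    """The nine parameters of the virtual-origin calibration.

    tx, ty: virtual-origin coordinates in raw feature units; m1, m2:
    shear factors (row 1, row 2); theta: rotation in radians; s1..s4:
    dilatation factors for the +y, −y, +x, −x semi-axes.
    """

    tx: float = 0.0
    ty: float = 0.0
    m1: float = 0.0
    m2: float = 0.0
    theta: float = 0.0
    s1: float = 1.0
    s2: float = 1.0
    s3: float = 1.0
    s4: float = 1.0

    def __post_init__(self) -> None:
        if min(self.s1, self.s2, self.s3, self.s4) <= 0:
            raise ValueError("dilatation factors s1..s4 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "AffineParams":
        return cls(*(float(v) for v in a))

    @property
    def n_free(self) -> int:
        return 9


@dataclass(frozen=True)
class QuadrantTransform:
    """The seven parameters of one quadrant's transform in the baseline."""

    tx: float = 0.0
    ty: float = 0.0
    m1: float = 0.0
    m2: float = 0.0
    theta: float = 0.0
    sx: float = 1.0
    sy: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.m1, self.m2, self.theta, self.sx, self.sy])

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix of this quadrant's full transform."""
        return (
            dilatation_matrix(self.sx, self.sy, validate=False)
            @ rotation_matrix(self.theta)
            @ shear_matrix(self.m1, self.m2)
            @ translation_matrix(self.tx, self.ty)
        )


@dataclass(frozen=True)
class QuadrantParams:
    """Four independent 7-parameter transforms, one per sign-quadrant."""

    quadrants: tuple[QuadrantTransform, QuadrantTransform, QuadrantTransform, QuadrantTransform]

    def __post_init__(self) -> None:
        if len(self.quadrants) != 4:
            raise ValueError("exactly four quadrant transforms are required")

    @property
    def n_free(self) -> int:
        return 28


# ---------------------------------------------------------------------------
# elementary transforms and the homogeneous matrix


def translation_matrix(tx: float, ty: float) -> np.ndarray:
    """Move the virtual origin (tx, ty) to (0, 0): translate by (−tx, −ty)."""
    return np.array([[1.0, 0.0, -tx], [0.0, 1.0, -ty], [0.0, 0.0, 1.0]])


def shear_matrix(m1: float, m2: float) -> np.ndarray:
    return np.array([[1.0, m1, 0.0], [m2, 1.0, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def dilatation_matrix(sx: float, sy: float, validate: bool = True) -> np.ndarray:
    if validate and (sx <= 0 or sy <= 0):
        raise ValueError(f"dilatation factors must be positive, got ({sx}, {sy})")
    return np.diag([sx, sy, 1.0])


def homogeneous_matrix(
    tx: float, ty: float, m1: float, m2: float, theta: float, sx: float, sy: float
) -> np.ndarray:
    """Closed form of [Dilatation][Rotation][Shear][Translation].

    Written out entrywise (rather than as a matrix product) so that tests
    can verify it against an independently composed elementary product.
    """
    if sx <= 0 or sy <= 0:
        raise ValueError(f"dilatation factors must be positive, got ({sx}, {sy})")
    c, s = np.cos(theta), np.sin(theta)
    f1 = sx * (-tx * c + tx * m2 * s - ty * m1 * c + ty * s)
    f2 = sy * (-tx * s - tx * m2 * c - ty * m1 * s - ty * c)
    return np.array(
        [
            [sx * (c - m2 * s), sx * (m1 * c - s), f1],
            [sy * (s + m2 * c), sy * (m1 * s + c), f2],
            [0.0, 0.0, 1.0],
        ]
    )


# ---------------------------------------------------------------------------
# proposed method: piecewise forward / inverse maps


def _rot_shear(params: AffineParams) -> np.ndarray:
    """2x2 linear part Rotation·Shear shared by all four dilatation branches."""
    c, s = np.cos(params.theta), np.sin(params.theta)
    return np.array(
        [[c - params.m2 * s, params.m1 * c - s], [s + params.m2 * c, params.m1 * s + c]]
    )


def apply_proposed(params: AffineParams, raw: np.ndarray) -> np.ndarray:
    """Correct raw point(s): translate, shear, rotate, then dilate per side.

    After u = Rotation·Shear·(raw − (tx, ty)), the x coordinate is scaled
    by s3 when u_x ≥ 0 and s4 otherwise, the y coordinate by s1 when
    u_y ≥ 0 and s2 otherwise (boundary samples take the positive branch).
    Accepts a single point of shape (2,) or a stack of shape (n, 2).
    """
    p = np.asarray(raw, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    u = (pts - np.array([params.tx, params.ty])) @ _rot_shear(params).T
    sx = np.where(u[:, 0] >= 0.0, params.s3, params.s4)
    sy = np.where(u[:, 1] >= 0.0, params.s1, params.s2)
    out = np.column_stack([sx * u[:, 0], sy * u[:, 1]])
    return out[0] if single else out


def inverse_proposed(params: AffineParams, corrected: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`apply_proposed`.

    The dilatation factors are positive, so the branch of a corrected point
    matches the branch of its pre-dilatation image and the piecewise map is
    a bijection.
    """
    q = np.asarray(corrected, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    ux = np.where(pts[:, 0] >= 0.0, pts[:, 0] / params.s3, pts[:, 0] / params.s4)
    uy = np.where(pts[:, 1] >= 0.0, pts[:, 1] / params.s1, pts[:, 1] / params.s2)
    u = np.column_stack([ux, uy])
    raw = np.linalg.solve(_rot_shear(params), u.T).T + np.array([params.tx, params.ty])
    return raw[0] if single else raw


# ---------------------------------------------------------------------------
# gauge fixing
#
# The nine-parameter model is overparametrized by exactly one degree of
# freedom: replacing Rotation·Shear by D0^-1·Rotation'·Shear' for a positive
# diagonal D0 (whenever the product stays in the rotation-shear family) and
# multiplying (s3, s4) by D0_xx and (s1, s2) by D0_yy leaves the piecewise
# map pointwise unchanged. Parameter vectors are therefore identified only
# up to this scale gauge.
#
# The gauge-invariant content of (θ, m1, m2) is the *pair of raw-space
# directions* that map onto the +x and +y screen semi-axes. Conversely a
# shear aligns those directions with the screen axes iff it makes them
# perpendicular; the perpendicularity-restoring shears (m1, m2) form a
# conic, and orientation is preserved exactly where m1·m2 < 1. The
# canonical representative picks the minimal-norm shear on that conic (the
# smallest shear that restores perpendicular axes), the rotation that then
# carries the sheared +x direction onto the +x axis, and dilatations that
# absorb the compensating scales.


def _axes_to_rot_shear(d_x: np.ndarray, d_y: np.ndarray) -> tuple[float, float, float]:
    """Canonical (θ, m1, m2) sending raw axis directions d_x, d_y onto the
    +x and +y screen semi-axes (minimal-norm shear convention)."""
    d_x = np.asarray(d_x, float) / np.linalg.norm(d_x)
    d_y = np.asarray(d_y, float) / np.linalg.norm(d_y)
    if d_x[0] * d_y[1] - d_x[1] * d_y[0] <= 1e-12:
        raise CalibrationError(
            "raw axis directions are degenerate or orientation-reversing"
        )
    p_ = float(d_x[0] * d_y[0])
    q_ = float(d_x[1] * d_y[1])
    s_ = float(d_x[0] * d_y[1] + d_x[1] * d_y[0])

    def conic(m1: float, m2: float) -> float:
        # dot(Shear·d_x, Shear·d_y): zero iff the shear restores
        # perpendicularity of the two axis directions
        return q_ * m1 * m1 + p_ * m2 * m2 + s_ * (m1 + m2) + (p_ + q_)

    candidates: list[tuple[float, float]] = []
    if abs(p_ + q_) < 1e-14:  # axes already perpendicular: no shear needed
        candidates.append((0.0, 0.0))
    else:
        # Lagrange stationarity of m1^2+m2^2 on the conic gives
        # m1 = μs/(1-2μq), m2 = μs/(1-2μp); clearing denominators in the
        # conic equation leaves a quartic polynomial in μ.
        a_pol = np.poly1d([-2.0 * q_, 1.0])  # 1 - 2 μ q
        b_pol = np.poly1d([-2.0 * p_, 1.0])  # 1 - 2 μ p
        u_pol = np.poly1d([s_, 0.0])  # μ s
        poly = (
            q_ * u_pol * u_pol * b_pol * b_pol
            + p_ * u_pol * u_pol * a_pol * a_pol
            + s_ * u_pol * a_pol * b_pol * b_pol
            + s_ * u_pol * a_pol * a_pol * b_pol
            + (p_ + q_) * a_pol * a_pol * b_pol * b_pol
        )
        for mu in np.roots(poly.coeffs):
            if abs(mu.imag) > 1e-9 * (1.0 + abs(mu.real)):
                continue
            mu = float(mu.real)
            den1, den2 = 1.0 - 2.0 * mu * q_, 1.0 - 2.0 * mu * p_
            if min(abs(den1), abs(den2)) < 1e-12:
                continue
            m1, m2 = mu * s_ / den1, mu * s_ / den2
            if abs(conic(m1, m2)) < 1e-8 * (1.0 + m1 * m1 + m2 * m2):
                candidates.append((m1, m2))
        if abs(s_) < 1e-14:  # degenerate stationarity branches
            for m1sq, m2sq in ((0.0, -(p_ + q_) / p_ if p_ else -1.0),
                               (-(p_ + q_) / q_ if q_ else -1.0, 0.0)):
                if m2sq >= 0.0:
                    candidates.extend([(0.0, np.sqrt(m2sq)), (0.0, -np.sqrt(m2sq))])
                if m1sq >= 0.0:
                    candidates.extend([(np.sqrt(m1sq), 0.0), (-np.sqrt(m1sq), 0.0)])

    admissible = [
        (m1, m2) for m1, m2 in candidates
        if m1 * m2 < 1.0 and abs(conic(m1, m2)) < 1e-8 * (1.0 + m1 * m1 + m2 * m2)
    ]
    if not admissible:
        raise CalibrationError("no orientation-preserving shear aligns the gaze axes")
    m1, m2 = min(admissible, key=lambda m: (m[0] ** 2 + m[1] ** 2, m))
    sheared_x = (d_x[0] + m1 * d_x[1], m2 * d_x[0] + d_x[1])
    theta = -float(np.arctan2(sheared_x[1], sheared_x[0]))
    return theta, float(m1), float(m2)


def canonicalize(params: AffineParams) -> AffineParams:
    """Map a parameter vector to the canonical representative of its gauge
    orbit; the piecewise transformation is unchanged to machine precision."""
    a = _rot_shear(params)
    d_x = np.linalg.solve(a, [1.0, 0.0])
    d_y = np.linalg.solve(a, [0.0, 1.0])
    d_x /= np.linalg.norm(d_x)
    d_y /= np.linalg.norm(d_y)
    theta, m1, m2 = _axes_to_rot_shear(d_x, d_y)
    a_c = _rot_shear(AffineParams(m1=m1, m2=m2, theta=theta))
    d0 = a @ np.linalg.inv(a_c)  # diagonal by construction
    d1, d2 = float(d0[0, 0]), float(d0[1, 1])
    if d1 <= 0 or d2 <= 0 or max(abs(d0[0, 1]), abs(d0[1, 0])) > 1e-8 * max(d1, d2):
        raise CalibrationError("gauge normalization failed; linear part is degenerate")
    return AffineParams(
        tx=params.tx, ty=params.ty, m1=m1, m2=m2, theta=theta,
        s1=params.s1 * d2, s2=params.s2 * d2, s3=params.s3 * d1, s4=params.s4 * d1,
    )


# ---------------------------------------------------------------------------
# proposed method: fitting


def _tls_line(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: (centroid, unit direction)."""
    c = pts.mean(axis=0)
    centered = pts - c
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[0] <= 0:
        raise CalibrationError("axis points are coincident; cannot estimate a direction")
    return c, vt[0]


def _line_intersection(c1: np.ndarray, v1: np.ndarray, c2: np.ndarray, v2: np.ndarray) -> np.ndarray:
    a = np.column_stack([v1, -v2])
    det = np.linalg.det(a)
    if abs(det) < 1e-10:
        raise CalibrationError("estimated gaze axes are near-parallel; virtual origin undefined")
    ts = np.linalg.solve(a, c2 - c1)
    return c1 + ts[0] * v1


def fit_proposed(data: GazeDataset, refine: bool = True) -> AffineParams:
    """Fit the nine-parameter virtual-origin calibration to 24 point pairs.

    Closed-form geometric initialization followed by joint least-squares
    refinement:

    1. The raw images of the x-axis targets lie on one line, those of the
       y-axis targets on another; both pass through the virtual origin, so
       (tx, ty) is their intersection (total-least-squares lines).
    2. Unit directions toward the +x and +y semi-axes are estimated from
       the same on-axis points.
    3. θ is initialized so the +x raw direction rotates onto the +x screen
       axis; m1, m2 then solve the two linear alignment conditions that
       Rotation·Shear maps both raw axis directions onto the screen axes.
    4. Each semi-axis scale is the ratio of mean target coordinate to mean
       pre-dilatation coordinate over that semi-axis's points.
    5. All nine parameters are refined jointly by Levenberg–Marquardt on
       the pixel residuals (scales log-parametrized to stay positive) and
       the result is reported in canonical gauge (see :func:`canonicalize`;
       the model carries one exact scale-gauge degree of freedom, so only
       the canonical representative of a parameter vector is identifiable).

    On data generated exactly by the inverse model the fit reproduces the
    generating transformation to near machine precision, and the generating
    parameters themselves when they are in canonical gauge.
    """
    data.validate_for_calibration()
    raw = data.raw
    targets = data.targets

    mx = data.semi_axis_mask("+x") | data.semi_axis_mask("-x")
    my = data.semi_axis_mask("+y") | data.semi_axis_mask("-y")

    cx, vx = _tls_line(raw[mx])
    cy, vy = _tls_line(raw[my])
    origin = _line_intersection(cx, vx, cy, vy)

    def _oriented(v: np.ndarray, positive_mask: np.ndarray) -> np.ndarray:
        ref = raw[positive_mask].mean(axis=0) - origin
        return v if float(v @ ref) >= 0 else -v

    d_x = _oriented(vx, data.semi_axis_mask("+x"))
    d_y = _oriented(vy, data.semi_axis_mask("+y"))

    theta0, m1, m2 = _axes_to_rot_shear(d_x, d_y)

    start = AffineParams(
        tx=float(origin[0]), ty=float(origin[1]), m1=float(m1), m2=float(m2), theta=theta0
    )
    u0 = (raw - origin) @ _rot_shear(start).T
    scales = []
    for label, coord in (("+y", 1), ("-y", 1), ("+x", 0), ("-x", 0)):
        m = data.semi_axis_mask(label)
        denom = float(u0[m, coord].mean())
        numer = float(targets[m, coord].mean())
        if denom == 0 or numer / denom <= 0:
            raise CalibrationError(f"cannot estimate a positive scale for semi-axis {label}")
        scales.append(numer / denom)
    s1, s2, s3, s4 = scales

    params = AffineParams(
        tx=start.tx, ty=start.ty, m1=start.m1, m2=start.m2, theta=start.theta,
        s1=s1, s2=s2, s3=s3, s4=s4,
    )
    if not refine:
        return params

    def pack(p: AffineParams) -> np.ndarray:
        return np.array(
            [p.tx, p.ty, p.m1, p.m2, p.theta,
             np.log(p.s1), np.log(p.s2), np.log(p.s3), np.log(p.s4)]
        )

    def unpack(v: np.ndarray) -> AffineParams:
        return AffineParams(
            tx=v[0], ty=v[1], m1=v[2], m2=v[3], theta=v[4],
            s1=float(np.exp(v[5])), s2=float(np.exp(v[6])),
            s3=float(np.exp(v[7])), s4=float(np.exp(v[8])),
        )

    def residuals(v: np.ndarray) -> np.ndarray:
        return (apply_proposed(unpack(v), raw) - targets).ravel()

    sol = least_squares(
        residuals, pack(params), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000
    )
    # the refinement may drift along the flat gauge direction; report the
    # canonical representative so parameter vectors are comparable
    return canonicalize(unpack(sol.x))


# ---------------------------------------------------------------------------
# conventional quadrant baseline


def quadrant_index(points: np.ndarray) -> np.ndarray:
    """Quadrant of each point by coordinate signs; boundaries go positive.

    0 = (+, +), 1 = (−, +), 2 = (−, −), 3 = (+, −).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    xpos = p[:, 0] >= 0.0
    ypos = p[:, 1] >= 0.0
    return np.select(
        [xpos & ypos, ~xpos & ypos, ~xpos & ~ypos], [0, 1, 2], default=3
    )


def apply_quadrant(params: QuadrantParams, raw: np.ndarray) -> np.ndarray:
    """Correct raw point(s) with the transform of their raw sign-quadrant."""
    p = np.asarray(raw, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    qi = quadrant_index(pts)
    out = np.empty_like(pts)
    for q in range(4):
        mask = qi == q
        if not mask.any():
            continue
        m = params.quadrants[q].matrix()
        out[mask] = pts[mask] @ m[:2, :2].T + m[:2, 2]
    return out[0] if single else out


def _decompose_affine(a: np.ndarray, b: np.ndarray) -> QuadrantTransform:
    """Write target = A·raw + b as Dilatation·Rotation·Shear·Translation.

    The 7-parameter family covers the orientation-preserving 2-D affine
    with one spare degree of freedom; the decomposition is made unique and
    exact with the same minimal-shear gauge convention used for the
    proposed model, applied to the directions A maps onto the screen axes.
    """
    if np.linalg.det(a) <= 0:
        raise CalibrationError("affine fit is singular or orientation-reversing")
    d_x = np.linalg.solve(a, [1.0, 0.0])
    d_y = np.linalg.solve(a, [0.0, 1.0])
    theta, m1, m2 = _axes_to_rot_shear(d_x, d_y)
    a_c = _rot_shear(AffineParams(m1=m1, m2=m2, theta=theta))
    d0 = a @ np.linalg.inv(a_c)  # diagonal: the dilatation factors
    sx, sy = float(d0[0, 0]), float(d0[1, 1])
    tc = -np.linalg.solve(a, b)
    return QuadrantTransform(
        tx=float(tc[0]), ty=float(tc[1]), m1=m1, m2=m2, theta=theta, sx=sx, sy=sy
    )


def fit_quadrant(data: GazeDataset) -> QuadrantParams:
    """Fit the conventional baseline: one 7-parameter transform per quadrant.

    Each quadrant's points (membership by the signs of the *raw*
    coordinates — the mechanism that breaks under large rotation) get an
    independent least-squares affine fit, decomposed into translation,
    shear, rotation and dilatation. An empty quadrant is a fitting error;
    a quadrant with fewer than 3 points (large rotations push borderline
    points across quadrant boundaries) leaves its transform
    underdetermined, and the minimal-norm deviation fit keeps the
    unconstrained directions at their neutral values.
    """
    qi = quadrant_index(data.raw)
    transforms = []
    for q in range(4):
        mask = qi == q
        n = int(mask.sum())
        if n == 0:
            raise CalibrationError(
                f"quadrant {QUADRANT_LABELS[q]} contains no raw points; cannot fit a transform"
            )
        x = np.column_stack([data.raw[mask], np.ones(n)])
        # fit the deviation from the identity map; the minimal-norm lstsq
        # solution keeps underdetermined quadrants (e.g. 3 collinear points)
        # at neutral parameters while well-determined quadrants are exact
        # rcond truncates the noise-level singular values a collinear point
        # set produces, which would otherwise blow up the deviation fit
        coef, *_ = np.linalg.lstsq(
            x, data.targets[mask] - data.raw[mask], rcond=1e-10
        )
        a = np.eye(2) + coef[:2].T
        b = coef[2]
        transforms.append(_decompose_affine(a, b))
    return QuadrantParams(quadrants=tuple(transforms))


# ---------------------------------------------------------------------------


def count_parameters(method: str, arrangement: str = "cross") -> int:
    """Free-parameter count of a calibration method.

    The proposed method needs 9 parameters for the cross-shaped electrode
    arrangement and 8 for the plus-shaped one (its rotation is negligible
    and fixed at zero); the conventional quadrant method always needs
    4 x 7 = 28.
    """
    if method not in ("proposed", "conventional"):
        raise ValueError(f"unknown method {method!r}")
    if arrangement not in ("cross", "plus"):
        raise ValueError(f"unknown electrode arrangement {arrangement!r}")
    if method == "conventional":
        return 28
    return 9 if arrangement == "cross" else 8
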