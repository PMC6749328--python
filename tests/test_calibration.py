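"""Affine calibration: homogeneous matrix, proposed fit, quadrant baseline."""

import numpy as np
import pytest

from eogcal import (
    AffineParams,
    CalibrationError,
    GazeDataset,
    QuadrantParams,
    QuadrantTransform,
    apply_proposed,
    apply_quadrant,
    count_parameters,
    fit_proposed,
    fit_quadrant,
    homogeneous_matrix,
    inverse_proposed,
    make_simulation_pattern,
    quadrant_index,
)
from eogcal.calibration import (
    canonicalize,
    dilatation_matrix,
    rotation_matrix,
    shear_matrix,
    translation_matrix,
)

from conftest import random_affine_params


def elementary_product(tx, ty, m1, m2, theta, sx, sy):
    """Independent oracle: compose the four elementary matrices explicitly."""
    return (
        dilatation_matrix(sx, sy)
        @ rotation_matrix(theta)
        @ shear_matrix(m1, m2)
        @ translation_matrix(tx, ty)
    )


def forward_dataset(grid, params: AffineParams) -> GazeDataset:
    """Noiseless data whose exact correction is `params`."""
    return GazeDataset(
        targets=grid.points.copy(),
        raw=inverse_proposed(params, grid.points),
        labels=list(grid.labels),
    )


class TestHomogeneousMatrix:
    def test_neutral_parameters_give_identity(self):
        assert np.allclose(homogeneous_matrix(0, 0, 0, 0, 0, 1, 1), np.eye(3), atol=1e-15)

    def test_pure_quarter_rotation(self):
        m = homogeneous_matrix(0, 0, 0, 0, np.pi / 2, 1, 1)
        expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        assert np.allclose(m, expected, atol=1e-12)

    def test_matches_elementary_product_on_random_draws(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            args = (
                rng.uniform(-100, 100),
                rng.uniform(-100, 100),
                rng.uniform(-0.5, 0.5),
                rng.uniform(-0.5, 0.5),
                rng.uniform(-np.pi, np.pi),
                rng.uniform(0.5, 2.0),
                rng.uniform(0.5, 2.0),
            )
            assert np.abs(homogeneous_matrix(*args) - elementary_product(*args)).max() < 1e-12

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            homogeneous_matrix(0, 0, 0, 0, 0, -1.0, 1.0)


class TestApplyProposed:
    def test_identity_params_is_identity_map(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-400, 400, (1000, 2))
        assert np.allclose(apply_proposed(AffineParams(), pts), pts, atol=1e-12)

    def test_dilatation_branch_selection(self):
        params = AffineParams(s1=2.0)
        assert np.allclose(apply_proposed(params, np.array([0.0, 5.0])), [0.0, 10.0])
        assert np.allclose(apply_proposed(params, np.array([0.0, -5.0])), [0.0, -5.0])

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            params = random_affine_params(rng)
            pts = rng.uniform(-400, 400, (30, 2))
            assert np.abs(apply_proposed(params, inverse_proposed(params, pts)) - pts).max() < 1e-9

    def test_nonpositive_dilatation_rejected(self):
        with pytest.raises(ValueError):
            AffineParams(s2=0.0)


class TestGauge:
    """The nine-parameter model carries one exact scale-gauge freedom."""

    def test_canonicalize_preserves_the_map(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(-500, 500, (500, 2))
        for _ in range(50):
            params = random_affine_params(rng)
            canon = canonicalize(params)
            dev = np.abs(apply_proposed(params, pts) - apply_proposed(canon, pts)).max()
            assert dev < 1e-8

    def test_canonicalize_is_idempotent(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            canon = canonicalize(random_affine_params(rng))
            again = canonicalize(canon)
            assert np.abs(canon.as_array() - again.as_array()).max() < 1e-9


class TestFitProposed:
    def test_identity_data_recovers_neutral_parameters(self, identity_dataset):
        params = fit_proposed(identity_dataset)
        assert np.abs(params.as_array() - AffineParams().as_array()).max() < 1e-9

    def test_recovers_known_distortion(self, grid, example_distortion):
        data = make_simulation_pattern(grid, example_distortion)
        fitted = fit_proposed(data)
        truth = canonicalize(example_distortion.affine_params())
        assert np.abs(fitted.as_array() - truth.as_array()).max() < 1e-4
        resid = np.abs(apply_proposed(fitted, data.raw) - data.targets).max()
        assert resid < 1e-6

    def test_returns_nine_free_parameters(self, identity_dataset):
        params = fit_proposed(identity_dataset)
        assert params.n_free == 9 == len(params.as_array())

    def test_missing_semi_axis_points_rejected(self, grid):
        labels = ["Q1" if l == "+x" else l for l in grid.labels]
        data = GazeDataset(targets=grid.points.copy(), raw=grid.points.copy(), labels=labels)
        with pytest.raises(CalibrationError):
            fit_proposed(data)

    def test_wrong_point_count_rejected(self, grid):
        data = GazeDataset(
            targets=grid.points[:12].copy(), raw=grid.points[:12].copy(),
            labels=list(grid.labels[:12]),
        )
        with pytest.raises(CalibrationError):
            fit_proposed(data)

    def test_round_trip_exactness_over_seeded_draws(self, grid):
        """Noiseless forward-generated data is corrected to ~zero error."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            params = canonicalize(random_affine_params(rng))
            data = forward_dataset(grid, params)
            fitted = fit_proposed(data)
            assert np.abs(apply_proposed(fitted, data.raw) - data.targets).max() < 1e-6
            assert np.abs(fitted.as_array() - params.as_array()).max() < 1e-4


class TestQuadrantBaseline:
    def test_identity_data_gives_neutral_parameters(self, identity_dataset):
        params = fit_quadrant(identity_dataset)
        assert params.n_free == 28
        for q in params.quadrants:
            assert np.abs(q.as_array() - QuadrantTransform().as_array()).max() < 1e-9
        corrected = apply_quadrant(params, identity_dataset.raw)
        assert np.abs(corrected - identity_dataset.targets).max() < 1e-9

    def test_pure_anisotropic_scaling_fits_exactly(self, grid):
        from eogcal import DistortionSpec

        spec = DistortionSpec(pattern="a", scales=(0.8, 1.3, 1.1, 0.9))
        data = make_simulation_pattern(grid, spec)
        for fit, apply in ((fit_quadrant, apply_quadrant), (fit_proposed, apply_proposed)):
            resid = np.abs(apply(fit(data), data.raw) - data.targets).max()
            assert resid < 1e-6

    def test_large_rotation_degrades_quadrant_method(self, grid):
        """45 deg rotation disrupts raw-sign polarity, so the quadrant
        method's error strictly exceeds the proposed method's."""
        from eogcal import DistortionSpec, pixel_distance_error

        spec = DistortionSpec(
            pattern="d", scales=(0.8, 1.3, 1.1, 0.9), rotation=np.radians(45.0),
            shear=(0.15, -0.10), translation=(40.0, -25.0),
        )
        data = make_simulation_pattern(grid, spec)
        err_q = pixel_distance_error(apply_quadrant(fit_quadrant(data), data.raw), grid)
        err_p = pixel_distance_error(apply_proposed(fit_proposed(data), data.raw), grid)
        # the quadrant split leaves real pixel error; the proposed fit none
        assert err_q.mean.max() > 1.0
        assert err_p.mean.max() < 1e-6

    def test_axis_point_ties_go_to_positive_quadrant(self):
        assert quadrant_index(np.array([[5.0, 0.0]]))[0] == 0  # +x axis -> QI
        assert quadrant_index(np.array([[0.0, -5.0]]))[0] == 3  # -y axis -> QIV
        assert quadrant_index(np.array([[0.0, 0.0]]))[0] == 0

    def test_apply_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(41)
        quads = []
        for _ in range(4):
            quads.append(
                QuadrantTransform(
                    tx=rng.uniform(-50, 50), ty=rng.uniform(-50, 50),
                    m1=rng.uniform(-0.3, 0.3), m2=rng.uniform(-0.3, 0.3),
                    theta=rng.uniform(-1, 1), sx=rng.uniform(0.5, 2), sy=rng.uniform(0.5, 2),
                )
            )
        params = QuadrantParams(quadrants=tuple(quads))
        pts = rng.uniform(-300, 300, (200, 2))
        out = apply_quadrant(params, pts)
        for p, o in zip(pts, out):
            q = quads[int(quadrant_index(p[None])[0])]
            m = elementary_product(q.tx, q.ty, q.m1, q.m2, q.theta, q.sx, q.sy)
            expected = (m @ np.array([p[0], p[1], 1.0]))[:2]
            assert np.abs(o - expected).max() < 1e-9

    def test_empty_quadrant_rejected(self, grid):
        raw = np.abs(grid.points)  # everything pushed into quadrant I
        data = GazeDataset(targets=grid.points.copy(), raw=raw, labels=list(grid.labels))
        with pytest.raises(CalibrationError):
            fit_quadrant(data)


class TestParameterCounts:
    @pytest.mark.parametrize(
        "method,arrangement,expected",
        [
            ("proposed", "cross", 9),
            ("proposed", "plus", 8),
            ("conventional", "cross", 28),
            ("conventional", "plus", 28),
        ],
    )
    def test_counts(self, method, arrangement, expected):
        assert count_parameters(method, arrangement) == expected

    def test_unknown_enum_rejected(self):
        with pytest.raises(ValueError):
            count_parameters("bogus", "cross")
        with pytest.raises(ValueError):
            count_parameters("proposed", "diagonal")
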