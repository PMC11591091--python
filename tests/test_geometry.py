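"""Perspective geometry: camera position, table intersections, areas."""

import math

import numpy as np
import pytest

from diabkit.geometry import (
    EmptyMaskError,
    ParallelRayError,
    PhoneSpec,
    ShotGeometry,
    SingularGeometryError,
    base_intersection,
    camera_position,
    distance_from_image,
    image_point,
    max_valid_k,
    projected_area,
    shooting_distance,
    solve_shot,
)

SPEC = PhoneSpec(p=0.15, beta=math.pi / 6)


def line_table_oracle(A, D):
    """Independent parametric line-plane intersection: solve A + t(D - A)
    hitting y = 0 via a 1x1 linear solve."""
    t = np.linalg.solve(np.array([[D[1] - A[1]]]), np.array([-A[1]]))[0]
    return A[0] + t * (D[0] - A[0])


class TestCameraPosition:
    @pytest.mark.parametrize(
        "alpha, expected",
        [
            (math.pi / 2, (0.0, 0.15)),
            (math.pi / 3, (0.075, 0.15 * math.sqrt(3) / 2)),
            (1e-9, (0.15, 0.0)),
        ],
    )
    def test_values(self, alpha, expected):
        A = camera_position(SPEC, alpha)
        assert A == pytest.approx(expected, abs=1e-8)


class TestBaseIntersection:
    def test_exact_value(self):
        # sin(pi/3 + pi/6) = 1 so l_OB = p sin(beta) = 0.075
        assert base_intersection(SPEC, math.pi / 3) == pytest.approx(0.075)

    def test_beta_to_zero_limit(self):
        spec = PhoneSpec(p=0.15, beta=1e-9)
        assert base_intersection(spec, math.pi / 3) == pytest.approx(0.0, abs=1e-8)

    def test_vertical_phone_identity(self):
        # alpha = pi/2: l_OB = p sin(beta)/cos(beta) = p tan(beta)
        got = base_intersection(SPEC, math.pi / 2)
        assert got == pytest.approx(0.15 * math.tan(math.pi / 6))

    def test_singular_geometry(self):
        spec = PhoneSpec(p=0.15, beta=math.pi / 2 - 1e-12)
        with pytest.raises(SingularGeometryError):
            base_intersection(spec, math.pi / 2 + 1e-12)


class TestImagePoint:
    def test_k_zero_maps_to_origin(self):
        shot = ShotGeometry(alpha=math.pi / 3, a=0.0, b=100.0)
        assert image_point(SPEC, shot) == pytest.approx((0.0, 0.0))

    def test_printed_expression_value(self):
        shot = ShotGeometry(alpha=math.pi / 3, a=50.0, b=100.0)
        m = 2 * 0.15 * 0.5 * math.sin(math.pi / 3) * math.cos(math.pi / 6)
        D = image_point(SPEC, shot)
        assert D[0] == pytest.approx(m * math.cos(math.pi / 3))
        assert D[1] == pytest.approx(m * math.sin(math.pi / 3))

    def test_vertical_phone_on_y_axis(self):
        shot = ShotGeometry(alpha=math.pi / 2, a=30.0, b=100.0)
        D = image_point(SPEC, shot)
        assert D[0] == pytest.approx(0.0, abs=1e-12)
        assert shot.degenerate


class TestShootingDistance:
    def test_45_degree_line(self):
        assert shooting_distance((0.0, 2.0), (1.0, 1.0)) == pytest.approx(2.0)

    def test_vertical_ray_hits_origin(self):
        assert shooting_distance((0.0, 0.15), (0.0, 0.05)) == pytest.approx(0.0)

    def test_parallel_ray_error(self):
        with pytest.raises(ParallelRayError):
            shooting_distance((0.0, 1.0), (1.0, 1.0))

    def test_random_points_match_parametric_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            A = (rng.uniform(-1, 1), rng.uniform(0.1, 2))
            D = (rng.uniform(-1, 1), rng.uniform(-2, 2))
            if abs(D[1] - A[1]) < 1e-3:
                continue
            got = shooting_distance(A, D)
            assert got == pytest.approx(line_table_oracle(A, D), rel=1e-9)


class TestDistanceFromImage:
    def test_k_zero_equals_base_intersection(self):
        for alpha in (0.6, 0.9, 1.2):
            assert distance_from_image(SPEC, alpha, 0.0) == pytest.approx(
                base_intersection(SPEC, alpha)
            )

    def test_monotone_in_k(self):
        for alpha in (0.6, 0.9, 1.2):
            kmax = max_valid_k(SPEC, alpha)
            ks = np.linspace(0.0, 0.95 * kmax, 40)
            vals = [distance_from_image(SPEC, alpha, k) for k in ks]
            assert np.all(np.diff(vals) > 0)

    def test_scale_equivariance(self):
        big = PhoneSpec(p=3 * SPEC.p, beta=SPEC.beta)
        for alpha, k in [(0.7, 0.1), (1.0, 0.3), (1.2, 0.5)]:
            assert distance_from_image(big, alpha, k) == pytest.approx(
                3 * distance_from_image(SPEC, alpha, k)
            )
            assert base_intersection(big, alpha) == pytest.approx(
                3 * base_intersection(alpha=alpha, spec=SPEC)
            )

    def test_ray_above_horizon_rejected(self):
        with pytest.raises(ParallelRayError):
            distance_from_image(SPEC, 1.2, 0.99)

    def test_literal_mode_disagrees_with_default(self):
        # the printed formula is dimensionally inconsistent; the audit mode
        # must reproduce it, not fix it silently
        d_default = distance_from_image(SPEC, math.pi / 3, 0.3)
        d_literal = distance_from_image(SPEC, math.pi / 3, 0.3, mode="literal")
        assert not math.isclose(d_default, d_literal, rel_tol=1e-3)


class TestProjectedArea:
    def test_full_mask(self):
        S, a, b = projected_area(np.ones((10, 10)), 0.001)
        assert S == pytest.approx(1e-4)
        assert b == 10

    def test_centroid_position(self):
        mask = np.zeros((100, 20))
        mask[49:51, 8:12] = 1  # 2-px-tall centred blob
        _, a, b = projected_area(mask, 0.01)
        assert b == 100
        assert a == pytest.approx(50.0, abs=0.5)

    def test_random_blob_matches_brute_force(self):
        rng = np.random.default_rng(8)
        mask = (rng.random((64, 48)) > 0.7).astype(np.uint8)
        S, _, _ = projected_area(mask, 0.002)
        brute = sum(
            1 for i in range(64) for j in range(48) if mask[i, j]
        ) * 0.002**2
        assert S == pytest.approx(brute)

    def test_empty_mask_error(self):
        with pytest.raises(EmptyMaskError):
            projected_area(np.zeros((5, 5)), 0.001)


class TestValidation:
    def test_phone_spec_invariants(self):
        with pytest.raises(ValueError):
            PhoneSpec(p=-0.1, beta=0.3)
        with pytest.raises(ValueError):
            PhoneSpec(p=0.15, beta=2.0)

    def test_shot_geometry_invariants(self):
        with pytest.raises(ValueError):
            ShotGeometry(alpha=0.5, a=10.0, b=5.0)

    def test_solve_shot_flags_vertical(self):
        sol = solve_shot(SPEC, ShotGeometry(alpha=math.pi / 2, a=10.0, b=100.0))
        assert sol.degenerate
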