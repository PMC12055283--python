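import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from leafsettle.geometry import (
    InvalidOutlineError,
    NormalizationConfig,
    Outline,
    convex_hull_area,
    normalize_area,
    overlap_areas,
    polygon_area,
    polygon_centroid,
    reflect_outline,
    resample_outline,
)

from conftest import random_blob


class TestArea:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)

    def test_regular_256gon_closed_form(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        gon = Outline(np.column_stack([np.cos(th), np.sin(th)]))
        expected = 256 / 2 * np.sin(2 * np.pi / 256)
        assert polygon_area(gon) == pytest.approx(expected, rel=1e-12)

    def test_clockwise_input_repaired(self):
        cw = Outline([(0, 0), (0, 1), (1, 1), (1, 0)])  # clockwise
        assert polygon_area(cw) == pytest.approx(1.0)
        # canonical orientation is CCW after repair
        v = cw.vertices
        signed = 0.5 * np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        assert signed > 0

    def test_too_few_vertices_rejected(self):
        with pytest.raises(InvalidOutlineError):
            Outline([(0, 0), (1, 0)])

    def test_self_intersecting_rejected_unless_repaired(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(InvalidOutlineError):
            Outline(bowtie)
        fixed = Outline(bowtie, repair=True)
        assert fixed.to_shapely().is_valid

    def test_monte_carlo_oracle(self):
        """Point-in-polygon sampling agrees with the shoelace area within 1%."""
        rng = np.random.default_rng(42)
        for seed in range(20):
            blob = random_blob(seed, n=128)
            v = blob.vertices
            lo, hi = v.min(axis=0), v.max(axis=0)
            box_area = np.prod(hi - lo)
            pts = rng.uniform(lo, hi, size=(100_000, 2))
            inside = shapely.contains_xy(blob.to_shapely(), pts[:, 0], pts[:, 1])
            mc_area = box_area * inside.mean()
            assert mc_area == pytest.approx(polygon_area(blob), rel=0.01)


class TestCentroid:
    def test_unit_square(self, unit_square):
        assert polygon_centroid(unit_square) == pytest.approx((0.5, 0.5))

    def test_translation_equivariance(self, unit_square):
        moved = unit_square.with_vertices(unit_square.vertices + (10, 10))
        assert polygon_centroid(moved) == pytest.approx((10.5, 10.5))

    def test_composite_L_shape(self):
        # unit square at origin plus unit square at (1, 0): centroid (1.0, 0.5)
        L = Outline([(0, 0), (2, 0), (2, 1), (0, 1)])
        assert polygon_centroid(L) == pytest.approx((1.0, 0.5))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 100),
    dx=st.floats(-50, 50),
    dy=st.floats(-50, 50),
    angle=st.floats(0, 2 * np.pi),
    scale=st.floats(0.1, 10),
)
def test_similarity_transform_properties(seed, dx, dy, angle, scale):
    """Area is translation/rotation invariant and scales quadratically."""
    blob = random_blob(seed, n=64)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    moved = blob.with_vertices(scale * blob.vertices @ rot.T + (dx, dy))
    assert polygon_area(moved) == pytest.approx(scale**2 * polygon_area(blob), rel=1e-9)


class TestResample:
    def test_circle_count_and_area(self, disc_256):
        out = resample_outline(disc_256, 512)
        assert out.n_vertices == 512
        assert polygon_area(out) == pytest.approx(polygon_area(disc_256), rel=1e-3)

    def test_square_uniform_partition(self, unit_square):
        out = resample_outline(unit_square, 400)
        assert out.n_vertices == 400
        # 100 vertices per side +- 1
        for side in range(4):
            if side == 0:
                on_side = np.sum(np.isclose(out.vertices[:, 1], 0))
            elif side == 1:
                on_side = np.sum(np.isclose(out.vertices[:, 0], 1))
            elif side == 2:
                on_side = np.sum(np.isclose(out.vertices[:, 1], 1))
            else:
                on_side = np.sum(np.isclose(out.vertices[:, 0], 0))
            assert abs(on_side - 100) <= 2  # corners are shared between sides

    def test_idempotent_on_uniform_spacing(self, disc_256):
        once = resample_outline(disc_256, 256)
        twice = resample_outline(once, 256)
        assert np.allclose(once.vertices, twice.vertices, atol=1e-6)

    def test_too_coarse_rejected(self, unit_square):
        with pytest.raises(ValueError):
            resample_outline(unit_square, 8)


class TestNormalizeArea:
    def test_square_to_100(self, unit_square):
        out = normalize_area(unit_square, NormalizationConfig(100.0))
        assert polygon_area(out) == pytest.approx(100.0, rel=1e-9)
        side = out.vertices[:, 0].max() - out.vertices[:, 0].min()
        assert side == pytest.approx(10.0)

    def test_identity_when_at_target(self, unit_square):
        out = normalize_area(unit_square, NormalizationConfig(1.0))
        assert np.allclose(out.vertices, unit_square.vertices, atol=1e-9)

    def test_circle_radius_closed_form(self, disc_256):
        out = normalize_area(disc_256, NormalizationConfig(100.0))
        radii = np.linalg.norm(out.vertices - polygon_centroid(out), axis=1)
        # polygon of 256 vertices at radius R has area (n/2) R^2 sin(2pi/n)
        expected_r = np.sqrt(100.0 / (128 * np.sin(2 * np.pi / 256)))
        assert radii == pytest.approx(expected_r, rel=1e-9)
        assert expected_r == pytest.approx(np.sqrt(100 / np.pi), rel=1e-4)

    def test_projection_property(self):
        blob = random_blob(3)
        once = normalize_area(blob)
        twice = normalize_area(once)
        assert np.allclose(once.vertices, twice.vertices, atol=1e-9)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            NormalizationConfig(-5.0)


class TestReflect:
    def test_square_vertical_axis_fixed_point_set(self, unit_square):
        out = reflect_outline(unit_square, np.pi / 2)
        orig = {tuple(np.round(v, 9)) for v in unit_square.vertices}
        refl = {tuple(np.round(v, 9)) for v in out.vertices}
        assert orig == refl

    @pytest.mark.parametrize("angle", [0.0, 0.3, np.pi / 2, 2.0])
    def test_involution(self, scalene_triangle, angle):
        twice = reflect_outline(reflect_outline(scalene_triangle, angle), angle)
        # vertex order may be rotated/reversed by orientation repair; compare as polygons
        inter, union = overlap_areas(twice, scalene_triangle)
        assert inter == pytest.approx(union, rel=1e-9)

    def test_triangle_mirror_coordinates(self, scalene_triangle):
        out = reflect_outline(scalene_triangle, np.pi / 2)
        assert polygon_area(out) == pytest.approx(polygon_area(scalene_triangle))
        cx = polygon_centroid(scalene_triangle)[0]
        mirrored_x = 2 * cx - scalene_triangle.vertices[:, 0]
        assert set(np.round(mirrored_x, 9)) == set(np.round(out.vertices[:, 0], 9))


class TestOverlap:
    def test_identical(self, unit_square):
        assert overlap_areas(unit_square, unit_square) == pytest.approx((1.0, 1.0))

    def test_disjoint(self, unit_square):
        far = unit_square.with_vertices(unit_square.vertices + (5, 0))
        assert overlap_areas(unit_square, far) == pytest.approx((0.0, 2.0))

    def test_half_offset(self, unit_square):
        shifted = unit_square.with_vertices(unit_square.vertices + (0.5, 0))
        assert overlap_areas(unit_square, shifted) == pytest.approx((0.5, 1.5))

    def test_symmetric_in_arguments(self, unit_square, scalene_triangle):
        assert overlap_areas(unit_square, scalene_triangle) == pytest.approx(
            overlap_areas(scalene_triangle, unit_square)
        )


class TestConvexHull:
    def test_convex_shape_is_own_hull(self, unit_square):
        assert convex_hull_area(unit_square) == pytest.approx(1.0)

    def test_plus_sign(self, plus_sign):
        assert polygon_area(plus_sign) == pytest.approx(5.0)
        assert convex_hull_area(plus_sign) == pytest.approx(7.0)

    def test_circle(self, disc_256):
        assert convex_hull_area(disc_256) == pytest.approx(
            polygon_area(disc_256), rel=1e-6
        )
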