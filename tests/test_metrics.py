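import numpy as np
import pytest

from leafsettle.geometry import Outline, normalize_area, resample_outline
from leafsettle.metrics import (
    LOBEDNESS_METRICS,
    SYMMETRY_METRICS,
    lobedness_number,
    morphometrics,
    reflection_iou,
    symmetry_number,
)
from leafsettle.mutation import MutationSpec, digital_mutate
from leafsettle.shapegen import ParametricLeafConfig, ideal_forms, parametric_leaf

from conftest import random_blob


def brute_force_symmetry(outline: Outline, n_angles: int = 3600) -> float:
    """Dense scan over axis angles: the independent oracle for S."""
    angles = np.linspace(0, np.pi, n_angles, endpoint=False)
    return max(reflection_iou(outline, a) for a in angles)


class TestSymmetry:
    def test_regular_hexagon_is_symmetric(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        hexagon = resample_outline(
            Outline(np.column_stack([np.cos(th), np.sin(th)])), 512
        )
        S, _ = symmetry_number(hexagon)
        assert S == pytest.approx(1.0, abs=5e-3)

    def test_scalene_triangle_matches_dense_scan(self, scalene_triangle):
        tri = resample_outline(scalene_triangle, 512)
        S, _ = symmetry_number(tri)
        assert S == pytest.approx(brute_force_symmetry(tri), abs=1e-3)

    def test_optimized_search_matches_oracle_on_random_shapes(self):
        """Coarse-grid + refinement equals a dense 3600-angle scan (<1e-3)."""
        for seed in range(8):  # the full 50-shape sweep runs in the acceptance suite
            blob = resample_outline(random_blob(seed), 512)
            S, _ = symmetry_number(blob)
            assert S == pytest.approx(brute_force_symmetry(blob), abs=1e-3)

    def test_best_axis_angle_attains_reported_iou(self, scalene_triangle):
        tri = resample_outline(scalene_triangle, 512)
        S, angle = symmetry_number(tri)
        assert reflection_iou(tri, angle) == pytest.approx(S, abs=1e-9)

    def test_isosceles_axis_found(self):
        iso = resample_outline(Outline([(-1, 0), (1, 0), (0, 3)]), 512)
        S, angle = symmetry_number(iso)
        assert S == pytest.approx(1.0, abs=5e-3)
        assert angle == pytest.approx(np.pi / 2, abs=0.01)


class TestLobedness:
    def test_convex_shapes_are_unlobed(self, unit_square, disc_256):
        assert lobedness_number(unit_square) == 0.0
        assert lobedness_number(disc_256) == pytest.approx(0.0, abs=1e-9)

    def test_plus_sign_closed_form(self, plus_sign):
        assert lobedness_number(plus_sign) == pytest.approx(2 / 7, rel=1e-9)

    def test_monotone_in_lobe_depth(self):
        depths = [0.0, 0.1, 0.2, 0.3, 0.4]
        Ls = [
            lobedness_number(parametric_leaf(ParametricLeafConfig(lobe_count=5, lobe_depth=d)))
            for d in depths
        ]
        assert all(b >= a for a, b in zip(Ls, Ls[1:]))
        assert Ls[-1] > Ls[0]


class TestMorphometrics:
    def test_disc_control(self):
        disc = ideal_forms()[0]
        m = morphometrics(disc)
        assert m.S == pytest.approx(1.0, abs=5e-3)
        assert m.L == pytest.approx(0.0, abs=1e-6)
        assert m.area == pytest.approx(100.0, rel=1e-9)

    def test_similarity_invariance(self):
        blob = random_blob(11)
        m0 = morphometrics(blob)
        c, s = np.cos(np.deg2rad(37)), np.sin(np.deg2rad(37))
        rot = np.array([[c, -s], [s, c]])
        moved = blob.with_vertices(3.0 * blob.vertices @ rot.T + (40, -7))
        m1 = morphometrics(moved)
        assert m1.S == pytest.approx(m0.S, abs=1e-3)
        assert m1.L == pytest.approx(m0.L, abs=1e-3)

    def test_mutation_breaks_symmetry(self):
        """A sinusoid on one boundary segment strictly decreases S."""
        disc = normalize_area(resample_outline(ideal_forms()[0], 512))
        S0, _ = symmetry_number(disc)
        res = digital_mutate(
            disc, MutationSpec(amplitude=0.5, segments=((0.1, 0.35),))
        )
        S1, _ = symmetry_number(res.mutated)
        assert S1 < S0

    def test_metric_layer_is_pluggable(self):
        """Alternative S/L definitions drop in without any API change."""
        SYMMETRY_METRICS["always_half"] = lambda outline, coarse, refine: (0.5, 0.0)
        LOBEDNESS_METRICS["radial_cv"] = lambda outline: float(
            np.std(np.linalg.norm(outline.vertices - outline.centroid, axis=1))
            / np.mean(np.linalg.norm(outline.vertices - outline.centroid, axis=1))
        )
        try:
            m = morphometrics(
                ideal_forms()[1],
                symmetry_metric="always_half",
                lobedness_metric="radial_cv",
            )
            assert m.S == 0.5
            assert m.L >= 0
        finally:
            SYMMETRY_METRICS.pop("always_half")
            LOBEDNESS_METRICS.pop("radial_cv")
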