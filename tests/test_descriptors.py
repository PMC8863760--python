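"""Geometry of single elements and the six physical descriptors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from numstim import (
    Arena,
    Element,
    ShapeKind,
    StimulusArray,
    convex_hull_area,
    density,
    describe,
    describe_elements,
    inter_distance,
    shape_area,
    shape_perimeter,
    total_area,
    total_perimeter,
)
from numstim.descriptors import element_boundary_points
from numstim.errors import InvalidParameterError, UndefinedDescriptorError

SQRT3 = math.sqrt(3.0)


@pytest.mark.parametrize(
    "shape,R,area,perimeter",
    [
        ("circle", 1.0, math.pi, 2 * math.pi),
        ("square", 2.0, 4.0, 8.0),
        ("diamond", 3.0, 9.0, 12.0),
        ("triangle", 2.0, SQRT3, 6.0),
        ("triangle", 3.0, SQRT3 / 4 * 9, 9.0),
    ],
)
def test_shape_area_and_perimeter(shape, R, area, perimeter):
    assert shape_area(shape, R) == pytest.approx(area, rel=1e-12)
    assert shape_perimeter(shape, R) == pytest.approx(perimeter, rel=1e-12)


@pytest.mark.parametrize("R", [0.0, -1.0])
def test_nonpositive_size_rejected(R):
    with pytest.raises(InvalidParameterError):
        shape_area("circle", R)
    with pytest.raises(InvalidParameterError):
        shape_perimeter("square", R)


@given(
    shape=st.sampled_from(list(ShapeKind)),
    R=st.floats(0.01, 100.0),
    k=st.floats(0.01, 100.0),
)
def test_scaling_laws(shape, R, k):
    """area(kR) = k^2 area(R), perimeter(kR) = k perimeter(R)."""
    assert shape_area(shape, k * R) == pytest.approx(k * k * shape_area(shape, R), rel=1e-9)
    assert shape_perimeter(shape, k * R) == pytest.approx(
        k * shape_perimeter(shape, R), rel=1e-9
    )


class TestInterDistance:
    def test_pair_is_euclidean_distance(self):
        assert inter_distance([(0, 0), (3, 4)]) == pytest.approx(5.0)

    def test_equilateral_triangle_all_pairs_equal(self):
        h = SQRT3 / 2
        assert inter_distance([(0, 0), (1, 0), (0.5, h)]) == pytest.approx(1.0)

    def test_single_centre_is_undefined(self):
        with pytest.raises(UndefinedDescriptorError):
            inter_distance([(0, 0)])

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-10, 10, size=(7, 2))
        base = inter_distance(pts)
        shifted = pts + np.array([123.0, -45.0])
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        assert inter_distance(shifted) == pytest.approx(base, rel=1e-12)
        assert inter_distance(pts @ rot.T) == pytest.approx(base, rel=1e-12)


class TestConvexHull:
    def test_single_circle_equals_its_area(self):
        el = Element("circle", (0.0, 0.0), 10.0)
        assert convex_hull_area([el]) == pytest.approx(100 * math.pi, rel=1e-3)

    def test_two_circles_against_dense_sampling_oracle(self):
        els = [Element("circle", (0.0, 0.0), 1.0), Element("circle", (10.0, 0.0), 1.0)]
        got = convex_hull_area(els, boundary_samples=256)
        # brute-force oracle: hull of 4096 perimeter points per element
        pts = np.vstack([element_boundary_points(el, 4096) for el in els])
        oracle = ConvexHull(pts).volume
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_four_squares_hull_is_outer_square(self):
        els = [Element("square", (sx * 5.0, sy * 5.0), 2.0) for sx in (-1, 1) for sy in (-1, 1)]
        assert convex_hull_area(els) == pytest.approx(144.0, rel=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            convex_hull_area([])

    def test_shapes_extend_hull_beyond_centres(self):
        rng = np.random.default_rng(1)
        centres = rng.uniform(-30, 30, size=(6, 2))
        els = [Element("circle", tuple(c), 2.0) for c in centres]
        assert convex_hull_area(els) >= ConvexHull(centres).volume

    def test_convergence_in_boundary_samples(self):
        els = [Element("circle", (0.0, 0.0), 5.0), Element("circle", (12.0, 3.0), 2.0)]
        a256 = convex_hull_area(els, 256)
        a512 = convex_hull_area(els, 512)
        assert abs(a512 - a256) / a256 < 1e-4


class TestDensity:
    def test_direct_quotient(self):
        assert density(10, 150000.0) == pytest.approx(6.6667e-5, rel=1e-4)
        assert density(2, 1.0) == 2.0

    def test_single_element_undefined(self):
        with pytest.raises(UndefinedDescriptorError):
            density(1, 100.0)


def test_totals_are_additive():
    els = [Element("circle", (0, 0), 1.0), Element("square", (10, 0), 2.0)]
    assert total_area(els) == pytest.approx(math.pi + 4.0)
    assert total_perimeter(els) == pytest.approx(2 * math.pi + 8.0)
    with pytest.raises(InvalidParameterError):
        total_area([])


def test_twenty_equal_circles_hit_constructed_total_area():
    R = math.sqrt(600.0 / (20 * math.pi))
    els = [Element("circle", (3.0 * i, 0.0), R) for i in range(20)]
    assert total_area(els) == pytest.approx(600.0, rel=1e-12)


class TestDescribe:
    def test_single_element_omits_id_and_d(self):
        arr = StimulusArray(
            elements=[Element("circle", (0, 0), 3.0)], arena=Arena("circular", 50)
        )
        achieved = describe(arr)
        assert set(achieved) == {"CH", "TA", "TP", "Rmin", "Rmax"}
        assert achieved["CH"] == pytest.approx(9 * math.pi)

    def test_density_hull_identity_and_extrema(self):
        rng = np.random.default_rng(2)
        els = [Element("circle", tuple(c), r) for c, r in zip(
            rng.uniform(-30, 30, size=(5, 2)), rng.uniform(1, 4, size=5)
        )]
        arr = StimulusArray(elements=els, arena=Arena("circular", 60))
        a = describe(arr)
        assert a["D"] * a["CH"] == pytest.approx(5, rel=1e-9)
        assert a["Rmin"] == min(el.R for el in els)
        assert a["Rmax"] == max(el.R for el in els)
        # values agree with the individual descriptor calls
        assert a["TA"] == total_area(els)
        assert a["ID"] == inter_distance([el.centre for el in els])
        assert set(a) == {"ID", "CH", "D", "TA", "TP", "Rmin", "Rmax"}
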