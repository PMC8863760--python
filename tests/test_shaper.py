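"""Element shaping: radius policies, magnitude fitting, hull refinement."""

import math

import numpy as np
import pytest

from numstim import (
    Arena,
    ConstraintSet,
    Element,
    RadiusPolicy,
    convex_hull_area,
    derive_congruency_target,
    describe_elements,
    draw_radii,
    fit_magnitude,
    generate,
    inter_distance,
    refine_to_hull,
    shape_elements,
)
from numstim.errors import (
    InvalidParameterError,
    OverlapError,
    PinsExceedTargetError,
)
from numstim.sampler import sample_points


class TestDrawRadii:
    def test_equal_mode_all_identical(self):
        r = draw_radii(RadiusPolicy(mode="equal", mean=3.5), 20)
        assert np.all(r == 3.5)

    def test_degenerate_gaussian_collapses_to_mean(self):
        r = draw_radii(RadiusPolicy(mode="gaussian", mean=5.0, sigma=0.0), 4)
        assert np.all(r == 5.0)

    def test_pins_are_exact_extremes(self):
        rng = np.random.default_rng(0)
        p = RadiusPolicy(mode="gaussian", mean=5.0, sigma=1.5, fixed_min=2.0, fixed_max=8.0)
        r = draw_radii(p, 5, rng)
        assert r.min() == 2.0
        assert r.max() == 8.0
        assert np.all((r >= 2.0) & (r <= 8.0))

    def test_free_mode_within_range(self):
        rng = np.random.default_rng(1)
        r = draw_radii(RadiusPolicy(mode="free"), 50, rng, free_range=(1.0, 5.0))
        assert np.all((r >= 1.0) & (r <= 5.0))

    def test_deterministic_under_rng_seed(self):
        p = RadiusPolicy(mode="gaussian", mean=4.0, sigma=1.0)
        a = draw_radii(p, 10, np.random.default_rng(7))
        b = draw_radii(p, 10, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestFitMagnitude:
    def test_equal_circles_closed_form_area(self):
        radii = np.full(40, 1.0)
        out = fit_magnitude(radii, "circle", {"TA": 600.0}, RadiusPolicy(mode="equal"))
        assert np.allclose(out, math.sqrt(600.0 / (40 * math.pi)))
        assert np.sum(math.pi * out**2) == pytest.approx(600.0, rel=1e-12)
        out2 = fit_magnitude(radii, "circle", {"TA": 1200.0}, RadiusPolicy(mode="equal"))
        assert np.sum(math.pi * out2**2) == pytest.approx(1200.0, rel=1e-12)

    def test_perimeter_scales_linearly(self):
        radii = np.array([1.0, 2.0, 3.0])
        out = fit_magnitude(radii, "square", {"TP": 48.0}, RadiusPolicy(mode="free"))
        # TP = 4 * sum(R); current 24 -> scale 2, ratios preserved
        assert np.allclose(out, [2.0, 4.0, 6.0])

    def test_pins_alone_exceeding_target_fails(self):
        p = RadiusPolicy(mode="gaussian", mean=5.0, sigma=1.0, fixed_min=2.0, fixed_max=8.0)
        radii = np.array([2.0, 5.0, 8.0])
        # pinned discs already cover pi(4+64) = 68pi > 100
        with pytest.raises(PinsExceedTargetError):
            fit_magnitude(radii, "circle", {"TA": 100.0}, p)

    def test_pinned_radii_survive_fit_exactly(self):
        p = RadiusPolicy(mode="gaussian", mean=3.0, sigma=0.5, fixed_min=2.0, fixed_max=4.0)
        radii = np.array([2.0, 3.0, 3.2, 4.0])
        out = fit_magnitude(radii, "circle", {"TA": 120.0}, p)
        assert out.min() == 2.0
        assert out.max() == 4.0
        assert np.sum(math.pi * out**2) == pytest.approx(120.0, rel=1e-12)


def _ring_elements(n, ring_radius, R):
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return [
        Element("circle", (ring_radius * math.cos(a), ring_radius * math.sin(a)), R)
        for a in ang
    ]


class TestRefineToHull:
    def test_converges_from_above_and_is_monotone(self):
        els = _ring_elements(8, 50.0, 3.0)
        start = convex_hull_area(els)
        target = start / 1.02  # shaped hull 2% above target
        refined, iters = refine_to_hull(els, target, accepted_error=0.01)
        final = convex_hull_area(refined)
        assert iters > 0
        assert final <= start
        assert abs(final - target) / target * 100 <= 0.01

    def test_tight_tolerance_reachable(self):
        els = _ring_elements(10, 60.0, 2.0)
        target = convex_hull_area(els) / 1.05
        refined, _ = refine_to_hull(els, target, accepted_error=0.0001)
        final = convex_hull_area(refined)
        assert abs(final - target) / target * 100 <= 0.0001

    def test_already_within_tolerance_is_identity(self):
        els = _ring_elements(6, 40.0, 2.0)
        target = convex_hull_area(els)
        refined, iters = refine_to_hull(els, target, accepted_error=0.01)
        assert iters == 0
        assert [e.centre for e in refined] == [e.centre for e in els]

    def test_refinement_is_homothetic(self):
        """All pairwise centre distances shrink by one common factor."""
        els = _ring_elements(7, 55.0, 2.5)
        target = convex_hull_area(els) / 1.03
        refined, _ = refine_to_hull(els, target, accepted_error=0.001)
        d0 = inter_distance([e.centre for e in els])
        d1 = inter_distance([e.centre for e in refined])
        from scipy.spatial.distance import pdist

        r0 = pdist([e.centre for e in els])
        r1 = pdist([e.centre for e in refined])
        assert np.allclose(r1 / r0, d1 / d0, rtol=1e-9)

    def test_overlap_before_convergence(self):
        # two touching discs: the hull cannot shrink to the target without fusing
        els = [Element("circle", (-15.0, 0.0), 10.0), Element("circle", (15.0, 0.0), 10.0)]
        at_tangency = math.pi * 100 + 2 * 10.0 * 20.0  # hull area when just touching
        with pytest.raises(OverlapError):
            refine_to_hull(els, at_tangency * 0.8, accepted_error=0.01)


class TestShapeElements:
    def test_hull_and_area_jointly_controlled(self):
        cs = ConstraintSet(
            n=10,
            arena=Arena("circular", 350.0),
            spatial_target={"CH": 150000.0},
            magnitude_target={"TA": 20000.0},
            radius_policy=RadiusPolicy(mode="equal"),
            accepted_error=0.0001,
            generations=1,
            seed=4,
        )
        res = generate(cs)
        (arr,) = res.arrays
        audit = describe_elements(arr.elements)
        assert abs(audit["CH"] - 150000.0) / 150000.0 * 100 <= 0.0001
        assert abs(audit["TA"] - 20000.0) / 20000.0 * 100 <= 0.0001
        assert res.sampled == len(res.arrays) + res.discarded

    def test_single_element_array(self):
        cs = ConstraintSet(
            n=1,
            arena=Arena("circular", 50.0),
            magnitude_target={"TA": 600.0},
            radius_policy=RadiusPolicy(mode="equal"),
            generations=1,
            seed=0,
        )
        (arr,) = generate(cs).arrays
        assert arr.elements[0].R == pytest.approx(math.sqrt(600.0 / math.pi), rel=1e-12)
        assert arr.achieved["CH"] == pytest.approx(600.0, rel=1e-12)
        assert "ID" not in arr.achieved and "D" not in arr.achieved

    def test_interdistance_only_target_with_free_radii(self):
        cs = ConstraintSet(
            n=6,
            arena=Arena("circular", 100.0),
            spatial_target={"ID": 70.0},
            radius_policy=RadiusPolicy(mode="free"),
            free_radius_range=(1.0, 3.0),
            accepted_error=0.01,
            generations=3,
            seed=6,
        )
        for arr in generate(cs).arrays:
            audit = describe_elements(arr.elements)
            assert abs(audit["ID"] - 70.0) / 70.0 * 100 <= 0.01
            assert "CH" in audit  # reported even though untargeted

    def test_radius_pins_exact_in_final_arrays(self):
        cs = ConstraintSet(
            n=6,
            arena=Arena("circular", 120.0),
            spatial_target={"ID": 80.0},
            magnitude_target={"TA": 300.0},
            radius_policy=RadiusPolicy(
                mode="gaussian", mean=3.0, sigma=0.6, fixed_min=2.0, fixed_max=5.0
            ),
            accepted_error=0.01,
            generations=5,
            seed=8,
        )
        for arr in generate(cs).arrays:
            assert arr.achieved["Rmin"] == pytest.approx(2.0, rel=1e-12)
            assert arr.achieved["Rmax"] == pytest.approx(5.0, rel=1e-12)

    def test_shaping_a_sampled_configuration_directly(self):
        cs = ConstraintSet(
            n=5, arena=Arena("circular", 100.0), magnitude_target={"TP": 100.0},
            radius_policy=RadiusPolicy(mode="equal"), generations=1, seed=12,
        )
        (cfg,) = sample_points(cs)
        res = shape_elements(cfg, cs)
        assert not res.discarded
        assert res.array.achieved["TP"] == pytest.approx(100.0, rel=1e-9)


@pytest.mark.parametrize(
    "mode,expected",
    [("balanced", 600.0), ("congruent", 1200.0), ("incongruent", 300.0)],
)
def test_congruency_targets(mode, expected):
    assert derive_congruency_target(600.0, 20, 40, mode) == expected


def test_congruency_unknown_mode():
    with pytest.raises(InvalidParameterError):
        derive_congruency_target(600.0, 20, 40, "sideways")
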