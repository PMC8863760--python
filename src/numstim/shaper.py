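"""Second passage: turn accepted centre configurations into shaped elements.

Radii are drawn according to the radius policy (equal, uniform-free, or
truncated Gaussian with optional exact min/max pins), rescaled so the total
area or total perimeter hits the magnitude target (TA scales with the square
of a common scale factor, TP linearly — which is exactly why the two can
never be fixed together), and the elements are then placed on the sampled
centres.  Because shapes extend outward from their centres, the shaped
convex hull exceeds the centre-point hull that the sampler calibrated; when
a CH target is set, the centres are therefore moved by small homothetic
steps towards their centre of mass until the hull of the elements'
perimeters matches the target within the accepted error.

Element overlap is forbidden by default: visibly fused elements would change
the perceived numerosity, so a configuration whose shaping or refinement
forces an intersection is discarded (and counted), never silently kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .constraints import ConstraintSet, RadiusPolicy, normalize, validate
from .descriptors import (
    Element,
    ShapeKind,
    StimulusArray,
    convex_hull_area,
    describe_elements,
    unit_area,
    unit_perimeter,
)
from .errors import (
    BudgetExhaustedError,
    InfeasibleGeometryError,
    InvalidParameterError,
    MaxIterationError,
    NumstimError,
    OverlapError,
    PinsExceedTargetError,
)
from .sampler import DEFAULT_ATTEMPT_CAP, PointConfiguration, _sample_one

__all__ = [
    "ShapingResult",
    "GenerationResult",
    "draw_radii",
    "fit_magnitude",
    "refine_to_hull",
    "shape_elements",
    "generate",
    "derive_congruency_target",
]

REFINE_STEP = 0.005  # fractional move towards the centre of mass per iteration
REFINE_MAX_ITER = 10_000


@dataclass
class ShapingResult:
    """Outcome of shaping one point configuration."""

    array: StimulusArray | None
    refinement_iterations: int = 0
    discarded: bool = False
    reason: str | None = None


@dataclass
class GenerationResult:
    """A full generation run: kept arrays plus honest discard accounting."""

    arrays: list[StimulusArray]
    discarded: int
    sampled: int

    @property
    def discard_rate(self) -> float:
        return self.discarded / self.sampled if self.sampled else 0.0


# ---------------------------------------------------------------------------
# radii


def draw_radii(
    policy: RadiusPolicy,
    n: int,
    rng: np.random.Generator | None = None,
    free_range: tuple[float, float] = (1.0, 5.0),
) -> np.ndarray:
    """Draw ``n`` element radii according to the policy.

    With ``fixed_min``/``fixed_max`` pins set, the smallest and largest
    drawn radii are replaced by the pin values exactly, so the element size
    range is identical across arrays.
    """
    if n < 1:
        raise InvalidParameterError("need n >= 1 radii")
    if rng is None:
        rng = np.random.default_rng()
    p = policy
    n_pins = sum(x is not None for x in (p.fixed_min, p.fixed_max))
    if p.fixed_min is not None and p.fixed_max is not None and n < 2 and p.fixed_min != p.fixed_max:
        raise InvalidParameterError("cannot pin distinct min and max radii with n = 1")

    if p.mode == "equal":
        val = p.mean if p.mean is not None else (p.fixed_min if p.fixed_min is not None else 1.0)
        return np.full(n, float(val))

    lo = p.fixed_min if p.fixed_min is not None else None
    hi = p.fixed_max if p.fixed_max is not None else None
    if p.mode == "gaussian":
        if p.sigma == 0:
            radii = np.full(n, float(p.mean))
        else:
            a = -np.inf if lo is None else (lo - p.mean) / p.sigma
            b = np.inf if hi is None else (hi - p.mean) / p.sigma
            # acceptance region effectively empty (pins many sigmas away)
            if b <= a or a > 8.0 or b < -8.0:
                raise BudgetExhaustedError("empty truncation region for Gaussian radii")
            radii = truncnorm.rvs(a, b, loc=p.mean, scale=p.sigma, size=n, random_state=rng)
        if np.any(radii <= 0):
            raise InvalidParameterError(
                "Gaussian radius draw produced non-positive sizes; set fixed_min > 0"
            )
    else:  # free
        flo, fhi = free_range
        if lo is not None:
            flo = max(flo, lo)
        if hi is not None:
            fhi = min(fhi, hi)
        if flo > fhi:
            raise InvalidParameterError("free radius range collapsed by the pins")
        radii = rng.uniform(flo, fhi, size=n)

    if lo is not None:
        radii[int(np.argmin(radii))] = lo
    if hi is not None:
        radii[int(np.argmax(radii))] = hi
    if lo is not None and n >= 2 and not np.any(radii == lo):
        radii[int(np.argmin(radii))] = lo  # max-pin displaced the previous min
    return radii


def _pinned_mask(radii: np.ndarray, policy: RadiusPolicy) -> np.ndarray:
    mask = np.zeros(len(radii), dtype=bool)
    if policy.mode == "equal":
        return mask  # one common scale; pins (if any) coincide with it
    if policy.fixed_min is not None:
        mask |= radii == policy.fixed_min
    if policy.fixed_max is not None:
        mask |= radii == policy.fixed_max
    return mask


def fit_magnitude(
    radii,
    shape: ShapeKind | str,
    target: dict[str, float] | tuple[str, float],
    policy: RadiusPolicy,
) -> np.ndarray:
    """Rescale radii so the summed area or perimeter hits the target exactly.

    TP is linear in a common scale factor, TA quadratic, so the free radii
    are multiplied by ``t/cur`` resp. ``sqrt(t/cur)``.  Radii pinned to
    ``fixed_min``/``fixed_max`` are never rescaled; the residual target is
    solved over the free ones, and a rescaled free radius that would cross a
    pin is clipped onto it and re-solved, keeping the pins the true extremes.
    """
    radii = np.asarray(radii, dtype=float).copy()
    shape = ShapeKind(shape)
    if isinstance(target, dict):
        (kind, value), = target.items()
    else:
        kind, value = target
    if kind not in ("TA", "TP"):
        raise InvalidParameterError(f"magnitude target must be TA or TP, got {kind!r}")
    if not value > 0:
        raise InvalidParameterError("magnitude target must be positive")
    power = 2 if kind == "TA" else 1
    unit = unit_area(shape) if kind == "TA" else unit_perimeter(shape)

    pinned = _pinned_mask(radii, policy)
    for _ in range(len(radii) + 1):
        contrib = unit * radii**power
        residual = value - contrib[pinned].sum()
        free = ~pinned
        if not np.any(free) or residual <= 0:
            raise PinsExceedTargetError(
                f"pinned radii alone contribute {contrib[pinned].sum():.6g} "
                f">= target {kind}={value:.6g}"
            )
        s = (residual / contrib[free].sum()) ** (1.0 / power)
        new = radii.copy()
        new[free] *= s
        crossed = np.zeros_like(pinned)
        if policy.fixed_min is not None:
            crossed |= free & (new < policy.fixed_min)
            new[free & (new < policy.fixed_min)] = policy.fixed_min
        if policy.fixed_max is not None:
            crossed |= free & (new > policy.fixed_max)
            new[free & (new > policy.fixed_max)] = policy.fixed_max
        radii = new
        if not crossed.any():
            return radii
        pinned |= crossed
    raise PinsExceedTargetError("could not satisfy the magnitude target within the pins")


# ---------------------------------------------------------------------------
# overlap


def _any_overlap(elements: list[Element]) -> bool:
    """Pairwise boundary-disjointness test (exact for circles)."""
    n = len(elements)
    if n < 2:
        return False
    if all(el.shape == ShapeKind.CIRCLE for el in elements):
        c = np.array([el.centre for el in elements])
        r = np.array([el.R for el in elements])
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        lim = (r[:, None] + r[None, :]) * (1 - 1e-12)
        np.fill_diagonal(d2, np.inf)
        return bool(np.any(d2 < lim * lim))
    from shapely.geometry import Point, Polygon

    from .descriptors import element_vertices

    geoms = []
    for el in elements:
        if el.shape == ShapeKind.CIRCLE:
            geoms.append(Point(el.centre).buffer(el.R, quad_segs=32))
        else:
            geoms.append(Polygon(element_vertices(el)))
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].intersects(geoms[j]) and geoms[i].intersection(geoms[j]).area > 1e-12:
                return True
    return False


# ---------------------------------------------------------------------------
# hull refinement


def refine_to_hull(
    elements: list[Element],
    CH_target: float,
    accepted_error: float,
    step: float = REFINE_STEP,
    max_iter: int = REFINE_MAX_ITER,
    boundary_samples: int = 256,
    allow_overlap: bool = False,
) -> tuple[list[Element], int]:
    """Shrink a configuration homothetically until its shaped hull matches.

    Each iteration moves every centre towards the unweighted centre of mass
    by the fraction ``step`` of its current distance, which preserves the
    configuration's shape (and hence inter-distance ratios).  The hull area
    is recomputed on perimeter points after every move and never increases;
    a step that would land below the tolerance band is halved and retried so
    the procedure terminates inside the band even for very tight tolerances.
    """
    if not CH_target > 0:
        raise InvalidParameterError("CH target must be positive")
    tol = accepted_error / 100.0
    elements = [Element(el.shape, tuple(el.centre), el.R) for el in elements]
    centres = np.array([el.centre for el in elements], dtype=float)
    radii = [el.R for el in elements]
    shapes = [el.shape for el in elements]

    def rebuild(c):
        return [Element(s, (x, y), r) for s, (x, y), r in zip(shapes, c, radii)]

    cur = convex_hull_area(elements, boundary_samples)
    if abs(cur - CH_target) / CH_target <= tol:
        return elements, 0
    if cur < CH_target:
        raise InfeasibleGeometryError(
            f"shaped hull {cur:.6g} is below the CH target {CH_target:.6g}; "
            "shrinking towards the centre of mass cannot reach it"
        )
    com = centres.mean(axis=0)
    step_eff = step
    iters = 0
    while iters < max_iter:
        iters += 1
        cand = com + (1.0 - step_eff) * (centres - com)
        cand_elements = rebuild(cand)
        cand_ch = convex_hull_area(cand_elements, boundary_samples)
        if cand_ch < CH_target * (1.0 - tol):
            step_eff /= 2.0  # overshoot: take a finer step
            continue
        centres, cur, elements = cand, cand_ch, cand_elements
        if not allow_overlap and _any_overlap(elements):
            raise OverlapError(
                "hull refinement forced two elements to intersect before convergence"
            )
        if abs(cur - CH_target) / CH_target <= tol:
            return elements, iters
    raise MaxIterationError(f"hull refinement did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# full shaping


def _relative_errors(achieved: dict[str, float], cs: ConstraintSet) -> dict[str, float]:
    errs = {}
    for targets in (cs.spatial_target, cs.magnitude_target):
        for key, val in (targets or {}).items():
            if key in achieved:
                errs[key] = abs(achieved[key] - val) / val * 100.0
    return errs


def shape_elements(
    points: PointConfiguration,
    cs: ConstraintSet,
    rng: np.random.Generator | None = None,
) -> ShapingResult:
    """Shape one sampled configuration into a full stimulus array.

    Returns a discarded result (with the reason) instead of raising when a
    constraint cannot be met for this particular configuration, so callers
    can keep honest discard counts while continuing the run.
    """
    cs = normalize(cs)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(cs.seed), 1]))
    try:
        radii = draw_radii(cs.radius_policy, cs.n, rng, cs.free_radius_range)
        if cs.magnitude_target:
            radii = fit_magnitude(radii, cs.shape, cs.magnitude_target, cs.radius_policy)
        elements = [
            Element(cs.shape, (float(x), float(y)), float(r))
            for (x, y), r in zip(points.centres, radii)
        ]
        if not all(el.inside(cs.arena) for el in elements):
            return ShapingResult(None, discarded=True, reason="element outside arena")
        if not cs.allow_overlap and _any_overlap(elements):
            return ShapingResult(None, discarded=True, reason="element overlap")
        iters = 0
        spatial = cs.spatial_target or {}
        if "CH" in spatial:
            elements, iters = refine_to_hull(
                elements,
                spatial["CH"],
                cs.accepted_error,
                boundary_samples=cs.boundary_samples,
                allow_overlap=cs.allow_overlap,
            )
    except (OverlapError, MaxIterationError, PinsExceedTargetError, BudgetExhaustedError) as e:
        return ShapingResult(None, discarded=True, reason=str(e))

    achieved = describe_elements(elements, cs.boundary_samples)
    errors = _relative_errors(achieved, cs)
    array = StimulusArray(
        elements=elements,
        arena=cs.arena,
        achieved=achieved,
        errors=errors,
        seed=cs.seed,
        constraint_ref=cs.ref,
    )
    if any(err > cs.accepted_error + 1e-12 for err in errors.values()):
        return ShapingResult(array, iters, discarded=True, reason="outside accepted error")
    return ShapingResult(array, iters, discarded=False)


def generate(
    cs: ConstraintSet,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
    max_sampled: int | None = None,
) -> GenerationResult:
    """Run the full two-passage pipeline until ``cs.generations`` arrays pass.

    Point configurations are sampled and shaped one at a time; discarded
    shapings are replaced by fresh samples (and counted) so the returned
    pool always has the requested size.  Fully deterministic under
    ``cs.seed``.
    """
    validate(cs).raise_if_invalid()
    cs = normalize(cs)
    rng_points = np.random.default_rng(np.random.SeedSequence([int(cs.seed), 0]))
    rng_shapes = np.random.default_rng(np.random.SeedSequence([int(cs.seed), 1]))
    if max_sampled is None:
        max_sampled = max(200 * cs.generations, 1000)
    arrays: list[StimulusArray] = []
    discarded = 0
    sampled = 0
    while len(arrays) < cs.generations:
        if sampled >= max_sampled:
            raise BudgetExhaustedError(
                f"only {len(arrays)}/{cs.generations} arrays passed after "
                f"{sampled} sampled configurations ({discarded} discarded)",
                best=arrays,
            )
        cfg = _sample_one(cs, rng_points, attempt_cap)
        sampled += 1
        res = shape_elements(cfg, cs, rng_shapes)
        if res.discarded:
            discarded += 1
        else:
            arrays.append(res.array)
    return GenerationResult(arrays=arrays, discarded=discarded, sampled=sampled)


def derive_congruency_target(
    base_value: float, base_n: int, new_n: int, mode: str
) -> float:
    """Magnitude target for a congruency manipulation.

    ``balanced`` keeps the continuous variable constant across numerosities;
    ``congruent`` scales it with numerosity (doubles when n doubles);
    ``incongruent`` scales it against numerosity (halves when n doubles).
    """
    if base_n < 1 or new_n < 1:
        raise InvalidParameterError("numerosities must be >= 1")
    if not base_value > 0:
        raise InvalidParameterError("base value must be positive")
    if mode == "balanced":
        return float(base_value)
    if mode == "congruent":
        return base_value * new_n / base_n
    if mode == "incongruent":
        return base_value * base_n / new_n
    raise InvalidParameterError(f"unknown congruency mode {mode!r}")
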