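"""Seeded generation of centre configurations satisfying the spatial target.

First passage of the two-passage pipeline: only bare centre points exist
here.  Candidate configurations are drawn uniformly inside the arena (minus
an edge margin reserved for the later shaping, so elements never cross the
boundary).  When a spatial target (ID or CH; D has already been rewritten as
CH by :func:`numstim.constraints.normalize`) is set, each uniform draw is
homothetically rescaled about its centroid so the descriptor matches the
target exactly — inter-distance scales linearly with the configuration
scale, the centre hull quadratically — and the candidate is then *rejected*
if the calibrated configuration no longer fits inside the margin-reduced
arena or violates the optional neighbour-gap limits.  The loop stops after
collecting the requested number of generations, or fails loudly with the
best candidate found once the raw-attempt cap is hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .constraints import ConstraintSet, normalize, validate
from .descriptors import inter_distance, radial_extent, unit_area, unit_perimeter
from .errors import (
    BudgetExhaustedError,
    InfeasibleGeometryError,
    InvalidParameterError,
)

__all__ = [
    "PointConfiguration",
    "sample_points",
    "max_spatial_target",
    "expected_max_radius",
    "edge_margin",
    "DEFAULT_ATTEMPT_CAP",
]

DEFAULT_ATTEMPT_CAP = 1_000_000


@dataclass
class PointConfiguration:
    """An accepted centre configuration, pre-shaping."""

    centres: np.ndarray
    spatial_achieved: dict[str, float] = field(default_factory=dict)
    attempts: int = 0


def expected_max_radius(cs: ConstraintSet) -> float:
    """Upper estimate of the largest element radius the shaper will assign.

    Used to reserve an edge margin so that shaping sampled centres cannot
    push an element across the arena boundary.
    """
    p = cs.radius_policy
    if p.fixed_max is not None:
        return p.fixed_max
    if p.mode == "gaussian":
        return p.mean + 3.0 * (p.sigma or 0.0)
    if p.mode == "equal":
        mag = cs.magnitude_target or {}
        if "TA" in mag:
            return math.sqrt(mag["TA"] / (cs.n * unit_area(cs.shape)))
        if "TP" in mag:
            return mag["TP"] / (cs.n * unit_perimeter(cs.shape))
        return p.mean if p.mean is not None else 1.0
    return cs.free_radius_range[1]


def edge_margin(cs: ConstraintSet) -> float:
    """Arena-edge margin in stimulus units (explicit, or auto from radii)."""
    if cs.edge_margin is not None:
        return cs.edge_margin
    return expected_max_radius(cs) * radial_extent(cs.shape)


def max_spatial_target(cs: ConstraintSet, kind: str) -> float:
    """Geometric upper bound of a spatial descriptor inside the arena.

    CH is bounded by the arena area; ID by the largest point-to-point
    distance (the diameter of a circular arena, the diagonal of a square).
    """
    arena = cs.arena
    if kind == "CH":
        return arena.area
    if kind == "ID":
        return arena.max_point_distance
    if kind == "D":
        return math.inf  # density shrinks with CH; no upper geometric bound
    raise InvalidParameterError(f"unknown spatial descriptor {kind!r}")


def _spatial_value(kind: str, pts: np.ndarray) -> float | None:
    """Descriptor of bare centre points; None when degenerate."""
    if kind == "ID":
        return float(np.mean(pdist(pts)))
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return None


def _gaps_ok(pts: np.ndarray, min_gap: float | None, max_gap: float | None) -> bool:
    if min_gap is None and max_gap is None:
        return True
    if len(pts) < 2:
        return True
    d = pdist(pts)
    if min_gap is not None and d.min() < min_gap:
        return False
    if max_gap is not None:
        # every element must have a neighbour within max_gap
        from scipy.spatial.distance import squareform

        m = squareform(d)
        np.fill_diagonal(m, np.inf)
        if m.min(axis=1).max() > max_gap:
            return False
    return True


def _uniform_in_arena(rng: np.random.Generator, n: int, cs: ConstraintSet, r: float) -> np.ndarray:
    if cs.arena.kind == "square":
        return rng.uniform(-r, r, size=(n, 2))
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform(-r, r, size=(2 * (n - got) + 4, 2))
        ok = cand[np.einsum("ij,ij->i", cand, cand) <= r * r]
        take = min(len(ok), n - got)
        pts[got : got + take] = ok[:take]
        got += take
    return pts


def _sample_one(
    cs: ConstraintSet,
    rng: np.random.Generator,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
) -> PointConfiguration:
    """Draw configurations until one satisfies the spatial constraints."""
    margin = edge_margin(cs)
    r_eff = cs.arena.radius - margin
    if r_eff <= 0:
        raise InfeasibleGeometryError(
            f"edge margin {margin:.3g} leaves no room inside arena radius {cs.arena.radius:.3g}"
        )
    spatial = cs.spatial_target or {}
    kind = next(iter(spatial), None)
    target = spatial.get(kind) if kind else None
    if kind is not None:
        if kind == "CH" and cs.n < 3:
            raise InfeasibleGeometryError(
                "a CH target needs n >= 3: the hull of fewer centre points has zero area"
            )
        bound = max_spatial_target(cs, kind)
        if target > bound:
            raise InfeasibleGeometryError(
                f"{kind} target {target:.6g} exceeds the arena bound {bound:.6g}"
            )

    best: np.ndarray | None = None
    best_err = math.inf
    for attempt in range(1, attempt_cap + 1):
        pts = _uniform_in_arena(rng, cs.n, cs, r_eff)
        if kind is not None:
            cur = _spatial_value(kind, pts)
            if cur is None or cur <= 0:
                continue
            factor = target / cur if kind == "ID" else math.sqrt(target / cur)
            com = pts.mean(axis=0)
            pts = com + factor * (pts - com)
            if not np.all(cs.arena.contains_points(pts, margin)):
                err = abs(cur - target) / target * 100.0
                if err < best_err:
                    best_err, best = err, pts
                continue
        if not _gaps_ok(pts, cs.min_gap, cs.max_gap):
            continue
        achieved = {}
        if kind is not None:
            achieved[kind] = _spatial_value(kind, pts)
        return PointConfiguration(centres=pts, spatial_achieved=achieved, attempts=attempt)
    raise BudgetExhaustedError(
        f"no configuration satisfying the spatial constraints in {attempt_cap} attempts",
        best=best,
        best_error=best_err if best is not None else None,
    )


def sample_points(
    cs: ConstraintSet,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
    rng: np.random.Generator | None = None,
) -> list[PointConfiguration]:
    """Generate ``cs.generations`` accepted centre configurations.

    Deterministic given ``cs`` (the RNG stream is derived from ``cs.seed``
    unless an explicit generator is passed).
    """
    validate(cs).raise_if_invalid()
    cs = normalize(cs)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(cs.seed), 0]))
    return [_sample_one(cs, rng, attempt_cap) for _ in range(cs.generations)]
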