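"""User constraint specifications and geometric feasibility checks.

A :class:`ConstraintSet` states what the generator must produce: the
numerosity, the arena, at most one *spatial* target (ID, CH or D — how the
elements are spread), at most one *magnitude* target (TA or TP — how much
stuff is on screen), a radius policy, and the percent tolerance within which
a variable counts as satisfied.

Not every pairing is geometrically possible.  Total area grows with the
square of the radii while total perimeter grows linearly, so the two can
never be fixed jointly (except at a single degenerate radius), and density
is n/CH by definition, so CH and D are the same degree of freedom.
:func:`validate` encodes those rules; :func:`normalize` canonicalises a
valid set (D rewritten as CH, a zero-variance Gaussian treated as equal
radii) so downstream samplers only ever see ID or CH targets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .descriptors import Arena, ShapeKind
from .errors import (
    InfeasibleCombinationError,
    InvalidParameterError,
    MissingParameterError,
)

__all__ = [
    "RadiusPolicy",
    "ConstraintSet",
    "ValidationReport",
    "validate",
    "normalize",
    "load_constraints",
    "save_constraints",
]

SPATIAL_KEYS = ("ID", "CH", "D")
MAGNITUDE_KEYS = ("TA", "TP")


@dataclass(frozen=True)
class RadiusPolicy:
    """How element sizes are drawn.

    mode
        ``free`` — uniform in the constraint set's free range;
        ``equal`` — all elements share one radius (``mean`` when given,
        otherwise solved from the magnitude target);
        ``gaussian`` — Normal(mean, sigma) truncated to the pins.
    fixed_min / fixed_max
        Optional pins: the smallest / largest radius in every array is set
        to exactly this value, so element size range is matched across
        arrays and numerosities.
    """

    mode: str = "free"
    mean: float | None = None
    sigma: float | None = None
    fixed_min: float | None = None
    fixed_max: float | None = None

    def __post_init__(self):
        if self.mode not in ("free", "equal", "gaussian"):
            raise InvalidParameterError(f"unknown radius mode {self.mode!r}")


@dataclass(frozen=True)
class ConstraintSet:
    """Everything the generator needs to produce one pool of stimuli."""

    n: int
    arena: Arena = field(default_factory=Arena)
    shape: ShapeKind = ShapeKind.CIRCLE
    spatial_target: dict[str, float] | None = None
    magnitude_target: dict[str, float] | None = None
    radius_policy: RadiusPolicy = field(default_factory=RadiusPolicy)
    accepted_error: float = 0.01  # percent
    generations: int = 1
    seed: int = 0
    free_radius_range: tuple[float, float] = (1.0, 5.0)
    edge_margin: float | None = None  # None: auto from expected max radius
    min_gap: float | None = None  # min over pairwise centre distances
    max_gap: float | None = None  # max over nearest-neighbour distances
    allow_overlap: bool = False
    boundary_samples: int = 256
    ref: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "shape", ShapeKind(self.shape))
        if self.spatial_target is not None:
            object.__setattr__(self, "spatial_target", dict(self.spatial_target))
        if self.magnitude_target is not None:
            object.__setattr__(self, "magnitude_target", dict(self.magnitude_target))


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self):
        if not self.ok:
            raise InfeasibleCombinationError(
                "; ".join(self.violations), offending=tuple(self.violations)
            )


def validate(cs: ConstraintSet) -> ValidationReport:
    """Check a constraint set against the geometric feasibility rules.

    Total: every structurally complete set yields either an ok report or a
    non-empty violation list; feasible-but-unusual values never raise.
    """
    v: list[str] = []
    if cs.n < 1:
        v.append("numerosity n must be >= 1")
    if cs.accepted_error < 0:
        v.append("accepted_error must be >= 0 percent")
    if cs.generations < 1:
        v.append("generations must be >= 1")

    spatial = cs.spatial_target or {}
    magnitude = cs.magnitude_target or {}
    bad_spatial = set(spatial) - set(SPATIAL_KEYS)
    bad_mag = set(magnitude) - set(MAGNITUDE_KEYS)
    if bad_spatial:
        v.append(f"unknown spatial target(s) {sorted(bad_spatial)}")
    if bad_mag:
        v.append(f"unknown magnitude target(s) {sorted(bad_mag)}")

    if len(spatial) > 1:
        # CH and D are redundant (D = n/CH) and any other pair over-constrains
        v.append(f"at most one spatial target allowed, got {sorted(spatial)}")
    if len(magnitude) > 1:
        v.append(
            "total area and total perimeter cannot be fixed jointly: "
            "TA scales with R^2 while TP scales with R"
        )
    for key, val in {**spatial, **magnitude}.items():
        if not (isinstance(val, (int, float)) and val > 0):
            v.append(f"target {key} must be a positive number")

    if "ID" in spatial and cs.n < 2:
        v.append("an ID target needs n >= 2")
    if ("CH" in spatial or "D" in spatial) and cs.n < 3:
        v.append("a CH or D target needs n >= 3 (the centre hull of fewer points is degenerate)")

    p = cs.radius_policy
    if p.fixed_min is not None and p.fixed_max is not None and p.fixed_min > p.fixed_max:
        v.append("fixed_min must be <= fixed_max")
    if p.mode == "equal" and (
        (p.fixed_min is not None and p.fixed_max is not None and p.fixed_min != p.fixed_max)
    ):
        v.append("equal-radius policy cannot carry distinct fixed_min/fixed_max pins")
    if p.mode == "gaussian":
        if p.mean is None:
            v.append("gaussian radius policy requires a mean")
        if p.sigma is None:
            v.append("gaussian radius policy requires a sigma")
        elif p.sigma < 0:
            v.append("sigma must be >= 0")
    if cs.free_radius_range[0] <= 0 or cs.free_radius_range[0] > cs.free_radius_range[1]:
        v.append("free_radius_range must be 0 < lo <= hi")
    if cs.min_gap is not None and cs.min_gap < 0:
        v.append("min_gap must be >= 0")
    if cs.min_gap is not None and cs.max_gap is not None and cs.min_gap > cs.max_gap:
        v.append("min_gap must be <= max_gap")
    return ValidationReport(v)


def normalize(cs: ConstraintSet) -> ConstraintSet:
    """Canonicalise a valid constraint set (idempotent).

    * a density target becomes the equivalent convex-hull target CH = n/D;
    * a Gaussian policy with sigma = 0 becomes an equal-radius policy;
    * an equal policy with coincident pins gets its mean filled from them.
    """
    validate(cs).raise_if_invalid()
    out = cs
    spatial = dict(out.spatial_target or {})
    if "D" in spatial:
        spatial = {"CH": out.n / spatial["D"]}
        out = replace(out, spatial_target=spatial)
    p = out.radius_policy
    if p.mode == "gaussian" and p.sigma == 0:
        out = replace(
            out,
            radius_policy=RadiusPolicy(
                mode="equal", mean=p.mean, fixed_min=p.fixed_min, fixed_max=p.fixed_max
            ),
        )
        p = out.radius_policy
    if p.mode == "equal" and p.mean is None and p.fixed_min is not None:
        out = replace(out, radius_policy=replace(p, mean=p.fixed_min))
    return out


# ---------------------------------------------------------------------------
# serialization — field names match the type definitions verbatim


def _policy_to_dict(p: RadiusPolicy) -> dict:
    d = {"mode": p.mode}
    for k in ("mean", "sigma", "fixed_min", "fixed_max"):
        val = getattr(p, k)
        if val is not None:
            d[k] = val
    return d


def constraint_to_dict(cs: ConstraintSet) -> dict:
    d: dict = {
        "n": cs.n,
        "arena": {
            "kind": cs.arena.kind,
            "radius": cs.arena.radius,
            "colour": list(cs.arena.colour),
        },
        "shape": cs.shape.value,
        "radius_policy": _policy_to_dict(cs.radius_policy),
        "accepted_error": cs.accepted_error,
        "generations": cs.generations,
        "seed": cs.seed,
        "free_radius_range": list(cs.free_radius_range),
        "allow_overlap": cs.allow_overlap,
        "boundary_samples": cs.boundary_samples,
    }
    if cs.spatial_target:
        d["spatial_target"] = dict(cs.spatial_target)
    if cs.magnitude_target:
        d["magnitude_target"] = dict(cs.magnitude_target)
    for k in ("edge_margin", "min_gap", "max_gap", "ref"):
        val = getattr(cs, k)
        if val is not None:
            d[k] = val
    return d


def constraint_from_dict(d: dict) -> ConstraintSet:
    d = dict(d)
    if "n" not in d:
        raise MissingParameterError("constraint set requires a numerosity 'n'")
    arena_d = d.pop("arena", {})
    arena = Arena(
        kind=arena_d.get("kind", "circular"),
        radius=arena_d.get("radius", 100.0),
        colour=tuple(arena_d.get("colour", (0, 0, 0))),
    )
    policy_d = d.pop("radius_policy", {})
    policy = RadiusPolicy(**policy_d)
    known = {f.name for f in dataclasses.fields(ConstraintSet)}
    unknown = set(d) - known
    if unknown:
        raise InvalidParameterError(f"unknown constraint fields {sorted(unknown)}")
    if "free_radius_range" in d:
        d["free_radius_range"] = tuple(d["free_radius_range"])
    return ConstraintSet(arena=arena, radius_policy=policy, **d)


def save_constraints(cs: ConstraintSet, path: str | Path):
    """Write a constraint set to YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    d = constraint_to_dict(cs)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_constraints(path: str | Path) -> ConstraintSet:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return constraint_from_dict(d)
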