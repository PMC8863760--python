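"""Element geometry and the six controlled physical descriptors.

A numerosity stimulus is a set of shaped elements (circles, squares,
diamonds, equilateral triangles) inside a circular or square arena.  The
continuous variables an experimenter controls or audits are:

* numerosity ``n`` — the element count;
* inter-distance ``ID`` — mean Euclidean distance between element centres
  over all unordered pairs (undefined for n = 1);
* convex hull ``CH`` — area of the smallest convex polygon containing the
  elements' *perimeters* (for n = 1 it equals the single element's area);
* density ``D = n / CH`` (undefined for n = 1);
* total area ``TA`` and total perimeter ``TP`` — sums of the per-element
  surface areas / contour lengths;
* radius ``R`` — circle radius, or side length for the polygonal shapes.

Coordinates are continuous Cartesian stimulus units with the origin at the
arena centre and the y axis pointing up; rasterisation to a pixel grid is
the renderer's job, so none of the math here is quantised.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import InvalidParameterError, UndefinedDescriptorError

__all__ = [
    "ShapeKind",
    "Arena",
    "Element",
    "StimulusArray",
    "shape_area",
    "shape_perimeter",
    "inter_distance",
    "convex_hull_area",
    "density",
    "total_area",
    "total_perimeter",
    "describe",
    "describe_elements",
    "element_vertices",
    "element_boundary_points",
    "radial_extent",
    "DEFAULT_BOUNDARY_SAMPLES",
]

#: default number of perimeter points fed to the hull per element; keeps the
#: polygonal approximation error of a circle's area below ~1e-4 relative.
DEFAULT_BOUNDARY_SAMPLES = 256


class ShapeKind(str, enum.Enum):
    """Supported element shapes.

    ``diamond`` is a square rotated by 45 degrees; ``triangle`` is
    equilateral.  For circles ``R`` is the radius, for the polygonal shapes
    it is the side length.
    """

    CIRCLE = "circle"
    SQUARE = "square"
    DIAMOND = "diamond"
    TRIANGLE = "triangle"


_SQRT3 = math.sqrt(3.0)

# per-shape area/perimeter of the unit-R element
_UNIT_AREA = {
    ShapeKind.CIRCLE: math.pi,
    ShapeKind.SQUARE: 1.0,
    ShapeKind.DIAMOND: 1.0,
    ShapeKind.TRIANGLE: _SQRT3 / 4.0,
}
_UNIT_PERIMETER = {
    ShapeKind.CIRCLE: 2.0 * math.pi,
    ShapeKind.SQUARE: 4.0,
    ShapeKind.DIAMOND: 4.0,
    ShapeKind.TRIANGLE: 3.0,
}
# farthest boundary point from the centre, per unit R
_RADIAL_EXTENT = {
    ShapeKind.CIRCLE: 1.0,
    ShapeKind.SQUARE: math.sqrt(0.5),
    ShapeKind.DIAMOND: math.sqrt(0.5),
    ShapeKind.TRIANGLE: 1.0 / _SQRT3,
}


def _as_shape(shape: ShapeKind | str) -> ShapeKind:
    return ShapeKind(shape)


@dataclass(frozen=True)
class Arena:
    """The bounded field elements live in.

    ``radius`` is the circle radius, or half the side for a square arena.
    """

    kind: str = "circular"
    radius: float = 100.0
    colour: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if self.kind not in ("circular", "square"):
            raise InvalidParameterError(f"unknown arena kind {self.kind!r}")
        if not self.radius > 0:
            raise InvalidParameterError("arena radius must be > 0")

    @property
    def area(self) -> float:
        if self.kind == "circular":
            return math.pi * self.radius**2
        return (2.0 * self.radius) ** 2

    @property
    def max_point_distance(self) -> float:
        """Largest possible distance between two points of the arena."""
        if self.kind == "circular":
            return 2.0 * self.radius
        return 2.0 * self.radius * math.sqrt(2.0)

    def contains_points(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points lying inside the arena shrunk by ``margin``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = self.radius - margin
        if self.kind == "circular":
            return np.einsum("ij,ij->i", pts, pts) <= r * r * (1 + 1e-12)
        return np.all(np.abs(pts) <= r * (1 + 1e-12), axis=1)


@dataclass
class Element:
    """One shaped item: shape kind, centre coordinates, size parameter R."""

    shape: ShapeKind
    centre: tuple[float, float]
    R: float

    def __post_init__(self):
        self.shape = _as_shape(self.shape)
        if not self.R > 0:
            raise InvalidParameterError("element size R must be > 0")

    @property
    def area(self) -> float:
        return shape_area(self.shape, self.R)

    @property
    def perimeter(self) -> float:
        return shape_perimeter(self.shape, self.R)

    @property
    def extent(self) -> float:
        """Distance from centre to the farthest boundary point."""
        return radial_extent(self.shape) * self.R

    def inside(self, arena: Arena, tol: float = 1e-9) -> bool:
        """True when the whole element lies inside the arena."""
        cx, cy = self.centre
        if arena.kind == "square":
            # bounding half-width of the shape along each axis
            if self.shape == ShapeKind.CIRCLE:
                hw = hh = self.R
            else:
                verts = element_vertices(self)
                hw = float(np.max(np.abs(verts[:, 0] - cx)))
                hh = float(np.max(np.abs(verts[:, 1] - cy)))
            return (
                abs(cx) + hw <= arena.radius + tol
                and abs(cy) + hh <= arena.radius + tol
            )
        if self.shape == ShapeKind.CIRCLE:
            return math.hypot(cx, cy) + self.R <= arena.radius + tol
        verts = element_vertices(self)
        return bool(np.all(np.hypot(verts[:, 0], verts[:, 1]) <= arena.radius + tol))


def radial_extent(shape: ShapeKind | str) -> float:
    """Centre-to-farthest-boundary distance of the unit-R shape."""
    return _RADIAL_EXTENT[_as_shape(shape)]


def shape_area(shape: ShapeKind | str, R: float) -> float:
    """Surface area of a single element of size ``R``.

    Circle: pi R^2; square and diamond: R^2; equilateral triangle:
    (sqrt(3)/4) R^2.
    """
    if not R > 0:
        raise InvalidParameterError("R must be > 0")
    return _UNIT_AREA[_as_shape(shape)] * R * R


def shape_perimeter(shape: ShapeKind | str, R: float) -> float:
    """Contour length of a single element of size ``R``."""
    if not R > 0:
        raise InvalidParameterError("R must be > 0")
    return _UNIT_PERIMETER[_as_shape(shape)] * R


def element_vertices(el: Element) -> np.ndarray:
    """Exact polygon vertices of a polygonal element (error for circles)."""
    cx, cy = el.centre
    R = el.R
    if el.shape == ShapeKind.SQUARE:
        h = R / 2.0
        local = np.array([(-h, -h), (h, -h), (h, h), (-h, h)])
    elif el.shape == ShapeKind.DIAMOND:
        d = R * math.sqrt(0.5)
        local = np.array([(d, 0.0), (0.0, d), (-d, 0.0), (0.0, -d)])
    elif el.shape == ShapeKind.TRIANGLE:
        # centroid at the centre, apex up; circumradius R/sqrt(3)
        rc = R / _SQRT3
        ang = np.array([math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3])
        local = rc * np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        raise InvalidParameterError("circles have no vertices")
    return local + np.array([cx, cy])


def element_boundary_points(el: Element, samples: int = DEFAULT_BOUNDARY_SAMPLES) -> np.ndarray:
    """Points on the element's perimeter, used for shape-aware hulls.

    Polygonal shapes always include their true vertices on top of the evenly
    spaced edge samples, so their hull is exact regardless of ``samples``.
    """
    if samples < 16:
        raise InvalidParameterError("need at least 16 boundary samples per element")
    cx, cy = el.centre
    if el.shape == ShapeKind.CIRCLE:
        theta = np.linspace(0.0, 2.0 * math.pi, samples, endpoint=False)
        return np.column_stack([cx + el.R * np.cos(theta), cy + el.R * np.sin(theta)])
    verts = element_vertices(el)
    k = len(verts)
    per_edge = max(samples // k, 1)
    pts = [verts]
    t = np.arange(1, per_edge)[:, None] / per_edge
    for i in range(k):
        a, b = verts[i], verts[(i + 1) % k]
        if len(t):
            pts.append(a + t * (b - a))
    return np.vstack(pts)


def inter_distance(centres) -> float:
    """Mean Euclidean distance between all unordered pairs of centres."""
    pts = np.asarray(centres, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise UndefinedDescriptorError("ID is not defined for one element")
    return float(np.mean(pdist(pts)))


def convex_hull_area(elements, boundary_samples: int = DEFAULT_BOUNDARY_SAMPLES) -> float:
    """Area of the convex hull of the elements' sampled perimeters.

    For a single element the hull degenerates to the element itself, so its
    area is returned exactly.
    """
    elements = list(elements)
    if not elements:
        raise InvalidParameterError("convex hull of an empty element list")
    if len(elements) == 1:
        return elements[0].area
    pts = np.vstack([element_boundary_points(el, boundary_samples) for el in elements])
    return float(ConvexHull(pts).volume)  # .volume is the area in 2-D


def density(n: int, CH: float) -> float:
    """Element density D = n / CH."""
    if n < 2:
        raise UndefinedDescriptorError("D is not defined for one element")
    if not CH > 0:
        raise InvalidParameterError("CH must be > 0")
    return n / CH


def total_area(elements) -> float:
    elements = list(elements)
    if not elements:
        raise InvalidParameterError("total area of an empty element list")
    return float(sum(el.area for el in elements))


def total_perimeter(elements) -> float:
    elements = list(elements)
    if not elements:
        raise InvalidParameterError("total perimeter of an empty element list")
    return float(sum(el.perimeter for el in elements))


def describe_elements(elements, boundary_samples: int = DEFAULT_BOUNDARY_SAMPLES) -> dict[str, float]:
    """All achieved descriptor values for a list of elements.

    Returns keys ``CH, TA, TP, Rmin, Rmax`` always, plus ``ID`` and ``D``
    when two or more elements are present.
    """
    elements = list(elements)
    if not elements:
        raise InvalidParameterError("cannot describe an empty element list")
    out: dict[str, float] = {}
    ch = convex_hull_area(elements, boundary_samples)
    out["CH"] = ch
    out["TA"] = total_area(elements)
    out["TP"] = total_perimeter(elements)
    radii = [el.R for el in elements]
    out["Rmin"] = float(min(radii))
    out["Rmax"] = float(max(radii))
    if len(elements) >= 2:
        out["ID"] = inter_distance([el.centre for el in elements])
        out["D"] = density(len(elements), ch)
    return out


@dataclass
class StimulusArray:
    """A generated stimulus: elements + arena + achieved descriptor audit."""

    elements: list[Element]
    arena: Arena
    achieved: dict[str, float] = field(default_factory=dict)
    errors: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    constraint_ref: str | None = None

    def __post_init__(self):
        if not self.elements:
            raise InvalidParameterError("a stimulus array needs at least one element")

    @property
    def n(self) -> int:
        return len(self.elements)

    @property
    def centres(self) -> np.ndarray:
        return np.array([el.centre for el in self.elements], dtype=float)


def describe(array: StimulusArray, boundary_samples: int = DEFAULT_BOUNDARY_SAMPLES) -> dict[str, float]:
    """Compute and store the achieved descriptor map of an array."""
    array.achieved = describe_elements(array.elements, boundary_samples)
    return array.achieved


def unit_area(shape: ShapeKind | str) -> float:
    """Area of the shape at R = 1."""
    return _UNIT_AREA[_as_shape(shape)]


def unit_perimeter(shape: ShapeKind | str) -> float:
    """Perimeter of the shape at R = 1."""
    return _UNIT_PERIMETER[_as_shape(shape)]
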