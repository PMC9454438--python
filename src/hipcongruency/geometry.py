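"""Planar polygon primitives: areas, intersections, and shape constructors.

All coordinates are continuous pixel coordinates in the image convention:
origin at the top-left, x increasing rightward (columns), y increasing
downward (rows). Areas are in square pixels.

Polygon clipping is delegated to shapely's robust GEOS backend, which
handles degenerate contact and sliver configurations exactly; no coordinate
snapping is applied, so areas and overlap ratios are invariant under
uniform rescaling of the coordinates to within float tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

from hipcongruency.errors import InvalidPolygonError, ParameterError

@dataclass(frozen=True)
class Point2D:
    """A point in continuous pixel coordinates (y grows downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidPolygonError(f"non-finite coordinate: ({self.x}, {self.y})")


@dataclass(frozen=True)
class CircleSpec:
    """A circle given by center and strictly positive radius (pixels)."""

    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ParameterError(f"radius must be a positive finite number, got {self.radius}")


class Polygon2D:
    """A simple polygon given by an ordered vertex ring.

    The ring is implicitly closed (the last vertex connects back to the
    first). Validation rejects rings with fewer than three vertices,
    non-finite coordinates, consecutive duplicate vertices and
    self-intersections; a repeated closing vertex (last == first) is
    dropped silently since many annotation tools emit closed rings.
    """

    __slots__ = ("_coords", "_shapely")

    def __init__(self, vertices: Sequence[Point2D | tuple[float, float]]):
        pts = [(float(p.x), float(p.y)) if isinstance(p, Point2D) else (float(p[0]), float(p[1])) for p in vertices]
        if len(pts) >= 2 and pts[0] == pts[-1]:
            pts = pts[:-1]
        if len(pts) < 3:
            raise InvalidPolygonError(f"polygon needs at least 3 vertices, got {len(pts)}")
        arr = np.asarray(pts, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidPolygonError("polygon has non-finite coordinates")
        nxt = np.roll(arr, -1, axis=0)
        if np.any(np.all(arr == nxt, axis=1)):
            raise InvalidPolygonError("polygon has consecutive duplicate vertices")
        self._coords = arr
        self._shapely: _ShPolygon | None = None
        if not self._as_shapely().is_valid:
            raise InvalidPolygonError("polygon is self-intersecting or otherwise invalid")

    @property
    def vertices(self) -> tuple[Point2D, ...]:
        return tuple(Point2D(x, y) for x, y in self._coords)

    @property
    def coords(self) -> np.ndarray:
        """Vertex coordinates as an (n, 2) float array (read-only view)."""
        v = self._coords.view()
        v.flags.writeable = False
        return v

    def __len__(self) -> int:
        return len(self._coords)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Polygon2D) and np.array_equal(self._coords, other._coords)

    def __repr__(self) -> str:
        return f"Polygon2D({len(self._coords)} vertices)"

    def _as_shapely(self) -> _ShPolygon:
        if self._shapely is None:
            self._shapely = _ShPolygon(self._coords)
        return self._shapely

    def translated(self, dx: float, dy: float) -> "Polygon2D":
        return Polygon2D(self._coords + np.array([dx, dy]))

    def scaled(self, s: float, about: Point2D | None = None) -> "Polygon2D":
        origin = np.zeros(2) if about is None else np.array([about.x, about.y])
        return Polygon2D(origin + (self._coords - origin) * s)


def polygon_area(p: Polygon2D) -> float:
    """Absolute polygon area by the shoelace formula (square pixels).

    Independent of vertex orientation and of which vertex starts the ring.
    """
    xy = p.coords
    x, y = xy[:, 0], xy[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))) / 2.0


def polygon_intersection(a: Polygon2D, b: Polygon2D) -> list[Polygon2D]:
    """Intersection of two simple polygons as a list of disjoint simple pieces.

    Non-convex inputs are supported. Boundary-only contact (zero-width
    overlap) yields an empty list. Output order is deterministic: pieces
    sorted by (min x, min y) of their bounding box.
    """
    inter = a._as_shapely().intersection(b._as_shapely())
    pieces: list[Polygon2D] = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.geom_type == "Polygon" and g.area > 0.0:
            pieces.append(Polygon2D(list(g.exterior.coords)))
    pieces.sort(key=lambda p: (p.coords[:, 0].min(), p.coords[:, 1].min()))
    return pieces


def intersection_area(a: Polygon2D, b: Polygon2D) -> float:
    """Overlap area of two simple polygons (square pixels).

    Symmetric in its arguments; never exceeds either input area beyond
    floating-point tolerance.
    """
    return float(a._as_shapely().intersection(b._as_shapely()).area)


def circle_polygon(c: CircleSpec, n_vertices: int, *, min_vertices: int = 8) -> Polygon2D:
    """Regular n-gon inscribed in a circle.

    The first vertex lies at angle 0 from the +x axis; vertices proceed
    counterclockwise in the y-down frame. ``min_vertices`` exists so tests
    may relax the n >= 8 precondition deliberately.
    """
    if n_vertices < min_vertices:
        raise ParameterError(f"n_vertices must be >= {min_vertices}, got {n_vertices}")
    t = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    xy = np.column_stack(
        (c.center.x + c.radius * np.cos(t), c.center.y - c.radius * np.sin(t))
    )
    return Polygon2D(xy)


def circle_circle_overlap_area(c1: CircleSpec, c2: CircleSpec) -> float:
    """Exact lens area of two overlapping circles (closed form)."""
    r1, r2 = c1.radius, c2.radius
    d = math.hypot(c2.center.x - c1.center.x, c2.center.y - c1.center.y)
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    k = (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    return a1 + a2 - 0.5 * math.sqrt(max(k, 0.0))


@dataclass(frozen=True)
class GridArea:
    """Result of a midpoint-rasterization area estimate."""

    area: float
    error_bound: float

    def __float__(self) -> float:
        return self.area


RegionPredicate = Callable[[np.ndarray, np.ndarray], np.ndarray]


def grid_overlap_oracle(
    region_a: RegionPredicate,
    region_b: RegionPredicate,
    bbox: tuple[float, float, float, float],
    resolution: int,
) -> GridArea:
    """Brute-force overlap area of two implicit regions by midpoint rasterization.

    ``region_a`` and ``region_b`` are vectorized predicates taking x and y
    coordinate arrays and returning boolean membership arrays. ``bbox`` is
    (xmin, ymin, xmax, ymax) and must contain both regions; ``resolution``
    is the cell count per axis (>= 100). The reported error bound is the
    cell area times the number of cells on the overlap boundary.
    """
    if resolution < 100:
        raise ParameterError(f"resolution must be >= 100, got {resolution}")
    xmin, ymin, xmax, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ParameterError(f"degenerate bbox: {bbox}")
    dx = (xmax - xmin) / resolution
    dy = (ymax - ymin) / resolution
    xs = xmin + (np.arange(resolution) + 0.5) * dx
    ys = ymin + (np.arange(resolution) + 0.5) * dy
    X = xs[None, :]
    Y = ys[:, None]
    inside = region_a(X, Y) & region_b(X, Y)
    inside = np.broadcast_to(inside, (resolution, resolution))
    cell = dx * dy
    boundary = (
        (inside[:, 1:] != inside[:, :-1]).sum()
        + (inside[1:, :] != inside[:-1, :]).sum()
    )
    return GridArea(area=float(inside.sum() * cell), error_bound=float(boundary * cell))


def polygon_predicate(p: Polygon2D) -> RegionPredicate:
    """Vectorized point-in-polygon predicate via matplotlib-free ray casting."""
    xy = p.coords

    def predicate(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        X, Y = np.broadcast_arrays(X, Y)
        inside = np.zeros(X.shape, dtype=bool)
        n = len(xy)
        for i in range(n):
            x1, y1 = xy[i]
            x2, y2 = xy[(i + 1) % n]
            cond = (y1 > Y) != (y2 > Y)
            with np.errstate(divide="ignore", invalid="ignore"):
                xcross = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (X < xcross)
        return inside

    return predicate
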