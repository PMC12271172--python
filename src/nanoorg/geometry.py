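"""2D alpha-shape areas and polygon helpers.

The alpha shape at radius ``alpha`` is the union of Delaunay triangles whose
circumradius is at most ``alpha``: a scale-aware generalization of the convex
hull used throughout the pipeline to measure cluster areas (synapses use
``alpha = 150`` nm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .exceptions import ParameterError

DEFAULT_ALPHA_NM = 150.0


def triangle_circumradius(pts: np.ndarray) -> np.ndarray:
    """Circumradius of each triangle in an (m, 3, 2) vertex array.

    R = abc / (4K) with side lengths a, b, c and triangle area K; degenerate
    (zero-area) triangles get R = inf.
    """
    a = np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1)
    b = np.linalg.norm(pts[:, 2] - pts[:, 1], axis=1)
    c = np.linalg.norm(pts[:, 0] - pts[:, 2], axis=1)
    cross = ((pts[:, 1, 0] - pts[:, 0, 0]) * (pts[:, 2, 1] - pts[:, 0, 1])
             - (pts[:, 1, 1] - pts[:, 0, 1]) * (pts[:, 2, 0] - pts[:, 0, 0]))
    area2 = np.abs(cross)  # 2K
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


@dataclass
class AlphaShapeRegion:
    """Alpha shape of a 2D point set: retained triangles and their total area."""

    points: np.ndarray            # (n, 2) input points, nm
    triangles: np.ndarray         # (m, 3) vertex indices of retained triangles
    area: float                   # nm^2
    alpha_radius: float           # nm
    _polygon: Polygon | None = field(default=None, repr=False, compare=False)

    @property
    def polygon(self):
        """Shapely (multi)polygon union of the retained triangles."""
        if self._polygon is None:
            if len(self.triangles) == 0:
                self._polygon = Polygon()
            else:
                tris = [Polygon(self.points[t]) for t in self.triangles]
                self._polygon = unary_union(tris)
        return self._polygon

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test for an (n, 2) array."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        if self.polygon.is_empty:
            return np.zeros(len(xy), dtype=bool)
        return shapely.intersects_xy(self.polygon, xy[:, 0], xy[:, 1])

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly inside the shape by rejection sampling."""
        if self.area <= 0 or n == 0:
            return np.empty((0, 2))
        minx, miny, maxx, maxy = self.polygon.bounds
        out = np.empty((n, 2))
        got = 0
        # acceptance rate = area / bbox area; cap iterations defensively
        for _ in range(10_000):
            need = n - got
            batch = max(int(need * (maxx - minx) * (maxy - miny) / self.area * 1.2),
                        need, 16)
            cand = np.column_stack([rng.uniform(minx, maxx, batch),
                                    rng.uniform(miny, maxy, batch)])
            keep = cand[self.contains(cand)]
            take = min(len(keep), need)
            out[got:got + take] = keep[:take]
            got += take
            if got == n:
                return out
        raise RuntimeError("rejection sampling failed to converge")


def alpha_shape(points, alpha_radius: float = DEFAULT_ALPHA_NM) -> AlphaShapeRegion:
    """Alpha shape of a point set.

    Triangulates the points (Delaunay) and keeps triangles with circumradius
    <= ``alpha_radius``; the region's area is the summed area of the retained
    triangles.  Degenerate inputs (< 3 points, or all collinear) yield an
    empty region with area 0.
    """
    if alpha_radius <= 0:
        raise ParameterError("alpha_radius must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    empty = AlphaShapeRegion(pts, np.empty((0, 3), dtype=int), 0.0, alpha_radius)
    if len(pts) < 3:
        return empty
    try:
        tri = Delaunay(pts)
    except QhullError:
        return empty  # collinear or otherwise degenerate
    simplices = tri.simplices
    verts = pts[simplices]
    radii = triangle_circumradius(verts)
    keep = radii <= alpha_radius
    kept = simplices[keep]
    cross = ((verts[keep, 1, 0] - verts[keep, 0, 0]) * (verts[keep, 2, 1] - verts[keep, 0, 1])
             - (verts[keep, 1, 1] - verts[keep, 0, 1]) * (verts[keep, 2, 0] - verts[keep, 0, 0]))
    area = float(np.abs(cross).sum() / 2.0)
    return AlphaShapeRegion(pts, kept, area, alpha_radius)


def circle_equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area: d = 2 sqrt(A / pi)."""
    if area < 0:
        raise ParameterError("area must be >= 0")
    return 2.0 * np.sqrt(area / np.pi)


def points_in_polygon(polygon: Polygon, xy) -> np.ndarray:
    """Boundary-inclusive point-in-polygon test (points on edges count)."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if polygon.is_empty:
        return np.zeros(len(xy), dtype=bool)
    return shapely.intersects_xy(polygon, xy[:, 0], xy[:, 1])
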