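"""Per-vine geometric parameters: heights and alpha-shape area/volume.

Five parameters are computed from the trellis-filtered canopy points of
one vine:

* ``h_max`` — the highest normalized point of the canopy;
* ``h90``, ``h95`` — 90th/95th-percentile heights (linear-interpolation
  percentile with index ``(n - 1) * p / 100`` on the sorted heights);
* ``area_m2`` — area of the 2D alpha shape of the XY coordinates;
* ``volume_m3`` — volume of the 3D alpha shape.

Alpha semantics: a simplex of the Delaunay triangulation is retained
when its circumradius (circumsphere radius in 3D) is at most ``alpha``
metres; smaller alpha gives a tighter shape. ``alpha = inf`` retains
every simplex, which equals the convex hull. Dense terrestrial-laser
clouds use alpha 0.05 m; sparser UAV clouds use 0.5 m. No hole-filling
or regularization is applied to the filtered complex: the 2D area is
the summed area of retained triangles, which honors holes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from vinemetrics.vine_segmentation import VineCloud

logger = logging.getLogger(__name__)

#: default alpha (m) per sensor class
ALPHA_TLS = 0.05
ALPHA_UAV = 0.5


class MetricUndefined(ValueError):
    """Raised when a metric is requested on an empty canopy."""


@dataclass(frozen=True)
class AlphaParams:
    alpha: float = ALPHA_UAV  # circumradius criterion, metres; inf = convex hull

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0 (use inf for convex hull)")


@dataclass
class GeometryMetrics:
    vine_id: str
    sensor_name: str
    h_max: float  # NaN when undefined
    h90: float
    h95: float
    area_m2: float
    volume_m3: float
    n_points: int
    n_canopy_points: int
    alpha_used: float

    def as_dict(self) -> dict:
        return {
            "vine_id": self.vine_id, "sensor": self.sensor_name,
            "h_max": self.h_max, "h90": self.h90, "h95": self.h95,
            "area_m2": self.area_m2, "volume_m3": self.volume_m3,
            "n_points": self.n_points, "n_canopy_points": self.n_canopy_points,
            "alpha_used": self.alpha_used,
        }


# ---------------------------------------------------------------------------
# heights
# ---------------------------------------------------------------------------


def height_max(heights: np.ndarray) -> float:
    heights = np.asarray(heights, float)
    if heights.size == 0:
        raise MetricUndefined("height_max: empty canopy")
    return float(heights.max())


def height_percentile(heights: np.ndarray, p: float) -> float:
    """Linear-interpolation percentile, index ``(n - 1) * p / 100``."""
    heights = np.asarray(heights, float)
    if heights.size == 0:
        raise MetricUndefined("height_percentile: empty canopy")
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    return float(np.percentile(heights, p, method="linear"))


# ---------------------------------------------------------------------------
# alpha shapes
# ---------------------------------------------------------------------------


def _circumradius_2d(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (
        b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (4.0 * area)
    r[~np.isfinite(r)] = np.inf
    return r, area


def _circumradius_3d(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra, via the linear system
    |p_i - c|^2 = R^2 reduced against vertex 0."""
    p0 = pts[simplices[:, 0]]
    rows = [pts[simplices[:, k]] - p0 for k in (1, 2, 3)]
    A = np.stack(rows, axis=1)  # (m, 3, 3)
    rhs = 0.5 * np.stack([np.einsum("ij,ij->i", r, r) for r in rows], axis=1)
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-14
    centers = np.full((len(simplices), 3), np.nan)
    if ok.any():
        centers[ok] = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
    radii = np.full(len(simplices), np.inf)
    radii[ok] = np.linalg.norm(centers[ok], axis=1)
    volume = np.abs(det) / 6.0
    return radii, volume


def alpha_shape_2d(
    xy: np.ndarray, alpha: float
) -> tuple[np.ndarray, list[np.ndarray], float]:
    """2D alpha shape: retained triangles, boundary rings, and area.

    Returns ``(triangles, boundary_rings, area)``; degenerate inputs
    (fewer than three non-collinear points) give area 0 with a logged
    reason. ``alpha = inf`` retains the whole Delaunay triangulation,
    whose summed area equals the convex hull area.
    """
    xy = np.asarray(xy, float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    if len(xy) < 3:
        logger.info("alpha_shape_2d: fewer than 3 points, area 0")
        return np.empty((0, 3), int), [], 0.0
    try:
        tri = Delaunay(xy)
    except QhullError:
        logger.info("alpha_shape_2d: degenerate (collinear?) input, area 0")
        return np.empty((0, 3), int), [], 0.0
    radii, areas = _circumradius_2d(xy, tri.simplices)
    keep = radii <= alpha if math.isfinite(alpha) else np.ones(len(radii), bool)
    kept = tri.simplices[keep]
    area = float(areas[keep].sum())
    return kept, _boundary_rings(xy, kept), area


def _boundary_rings(xy: np.ndarray, triangles: np.ndarray) -> list[np.ndarray]:
    """Rings of edges that belong to exactly one retained triangle."""
    if len(triangles) == 0:
        return []
    edges = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                       triangles[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = edges[idx[counts == 1]]
    # chain edges into rings
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    rings = []
    visited: set[tuple[int, int]] = set()
    for a, b in boundary:
        e = (int(a), int(b))
        if e in visited or (e[1], e[0]) in visited:
            continue
        ring = [int(a), int(b)]
        visited.add(e)
        while True:
            cur, prev = ring[-1], ring[-2]
            cand = [v for v in nxt.get(cur, []) if v != prev
                    and (cur, v) not in visited and (v, cur) not in visited]
            if not cand:
                break
            ring.append(cand[0])
            visited.add((cur, cand[0]))
            if cand[0] == ring[0]:
                break
        rings.append(xy[np.array(ring)])
    return rings


def alpha_shape_3d(xyz: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """3D alpha shape: retained tetrahedra and their summed volume.

    Degenerate inputs (fewer than four non-coplanar points) give
    volume 0; ``alpha = inf`` equals the convex hull volume.
    """
    xyz = np.asarray(xyz, float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("xyz must be (n, 3)")
    if len(xyz) < 4:
        logger.info("alpha_shape_3d: fewer than 4 points, volume 0")
        return np.empty((0, 4), int), 0.0
    try:
        tri = Delaunay(xyz)
    except QhullError:
        logger.info("alpha_shape_3d: degenerate (coplanar?) input, volume 0")
        return np.empty((0, 4), int), 0.0
    radii, volumes = _circumradius_3d(xyz, tri.simplices)
    keep = radii <= alpha if math.isfinite(alpha) else np.ones(len(radii), bool)
    kept = tri.simplices[keep]
    return kept, float(volumes[keep].sum())


def convex_hull_measures(points: np.ndarray) -> float:
    """Convex hull area (2D input) or volume (3D input), for cross-checks."""
    try:
        return float(ConvexHull(np.asarray(points, float)).volume)
    except QhullError:
        return 0.0


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def compute_vine_metrics(
    vine_cloud: VineCloud, alpha_params: AlphaParams
) -> GeometryMetrics:
    """All five parameters for one vine; missing metrics propagate as NaN."""
    canopy = vine_cloud.canopy_points
    nan = float("nan")
    if canopy is None or len(canopy) == 0:
        return GeometryMetrics(
            vine_id=vine_cloud.vine_id,
            sensor_name="" if canopy is None else canopy.sensor_name,
            h_max=nan, h90=nan, h95=nan, area_m2=nan, volume_m3=nan,
            n_points=vine_cloud.n_points, n_canopy_points=0,
            alpha_used=alpha_params.alpha,
        )
    h = canopy.z
    _, _, area = alpha_shape_2d(np.column_stack([canopy.x, canopy.y]),
                                alpha_params.alpha)
    _, volume = alpha_shape_3d(canopy.xyz, alpha_params.alpha)
    return GeometryMetrics(
        vine_id=vine_cloud.vine_id,
        sensor_name=canopy.sensor_name,
        h_max=height_max(h),
        h90=height_percentile(h, 90),
        h95=height_percentile(h, 95),
        area_m2=area,
        volume_m3=volume,
        n_points=vine_cloud.n_points,
        n_canopy_points=len(canopy),
        alpha_used=alpha_params.alpha,
    )
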