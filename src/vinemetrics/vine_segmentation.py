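"""Per-vine footprints, clipping, and the trellis-wire height filter.

Each monitored vine gets a rectangular footprint centered on its surveyed
trunk coordinate: 1.0 m along the row axis by 2 x 0.8 m across it
(flat caps, so adjacent footprints at 1.2 m spacing do not overlap).
Points inside the footprint are clipped out of the normalized cloud;
points at or below the lower trellis wire (0.30 m) are then excluded as
undergrowth noise before any metric is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from shapely.prepared import prep

from vinemetrics.cloud_io import NormalizedPointCloud, VinePolygon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClipSpec:
    segment_length: float = 1.0  # m along the row axis
    half_width: float = 0.8  # m either side of the row axis
    row_azimuth: float = 0.0  # degrees from north
    trellis_height: float = 0.30  # m
    cap_style: str = "flat"  # {"flat", "round"}

    def __post_init__(self) -> None:
        if self.segment_length <= 0 or self.half_width <= 0:
            raise ValueError("segment_length and half_width must be > 0")
        if self.trellis_height < 0:
            raise ValueError("trellis_height must be >= 0")
        if not math.isfinite(self.row_azimuth):
            raise ValueError("row_azimuth must be finite")


@dataclass
class VineCloud:
    """One vine's clipped points plus the trellis-filtered canopy subset."""

    vine_id: str
    polygon: VinePolygon
    all_points: NormalizedPointCloud | None
    canopy_points: NormalizedPointCloud | None

    @property
    def n_points(self) -> int:
        return 0 if self.all_points is None else len(self.all_points)

    @property
    def n_canopy_points(self) -> int:
        return 0 if self.canopy_points is None else len(self.canopy_points)


def build_vine_polygons(
    vine_xy: list[tuple[str, float, float]] | dict[str, tuple[float, float]],
    spec: ClipSpec = ClipSpec(),
) -> list[VinePolygon]:
    """Rectangles centered on each vine point, oriented along the row.

    The rectangle extends ``segment_length`` along the row azimuth and
    ``2 * half_width`` across it, vertices counterclockwise. With the
    ``round`` cap style the footprint is instead the buffered 1 m
    segment (round caps), which can overlap neighbors.
    """
    if isinstance(vine_xy, dict):
        items = list(vine_xy.items())
        labeled = [(vid, xy[0], xy[1]) for vid, xy in items]
    else:
        labeled = list(vine_xy)
    ids = [v[0] for v in labeled]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate vine_ids: {dupes}")

    a = math.radians(spec.row_azimuth)
    along = np.array([math.sin(a), math.cos(a)])
    across = np.array([math.cos(a), -math.sin(a)])
    half_l = spec.segment_length / 2
    polys = []
    for vid, x, y in labeled:
        c = np.array([x, y])
        if spec.cap_style == "round":
            from shapely.geometry import LineString

            seg = LineString([c - half_l * along, c + half_l * along])
            ring = np.asarray(
                seg.buffer(spec.half_width, cap_style="round").exterior.coords
            )
        else:
            corners = [
                c - half_l * along - spec.half_width * across,
                c + half_l * along - spec.half_width * across,
                c + half_l * along + spec.half_width * across,
                c - half_l * along + spec.half_width * across,
            ]
            ring = np.array(corners)
            # enforce counterclockwise orientation
            area2 = 0.0
            for i in range(4):
                x0, y0 = ring[i]
                x1, y1 = ring[(i + 1) % 4]
                area2 += x0 * y1 - x1 * y0
            if area2 < 0:
                ring = ring[::-1]
        polys.append(VinePolygon(vine_id=str(vid), ring=ring, provenance="built"))
    return polys


def clip_by_polygon(
    cloud: NormalizedPointCloud, polygon: VinePolygon
) -> NormalizedPointCloud | None:
    """Points whose XY falls inside or on the polygon boundary, order kept."""
    poly = polygon.shapely
    # boundary-inclusive: interior test plus a tolerant boundary check
    inside = contains_xy(poly, cloud.x, cloud.y)
    if not inside.all():
        boundary = prep(poly.boundary.buffer(1e-9))
        from shapely import points as shapely_points

        cand = ~inside
        on_edge = np.zeros(len(cloud), dtype=bool)
        # only test points near the boundary to stay O(n)
        minx, miny, maxx, maxy = poly.bounds
        near = cand & (cloud.x >= minx - 1e-9) & (cloud.x <= maxx + 1e-9) \
            & (cloud.y >= miny - 1e-9) & (cloud.y <= maxy + 1e-9)
        if near.any():
            pts = shapely_points(np.column_stack([cloud.x[near], cloud.y[near]]))
            on_edge[np.flatnonzero(near)] = [boundary.intersects(p) for p in pts]
        inside = inside | on_edge
    if not inside.any():
        logger.info("polygon %s: empty clip", polygon.vine_id)
        return None
    return cloud.subset(inside)


def filter_trellis(
    points: NormalizedPointCloud | None, trellis_height: float = 0.30
) -> NormalizedPointCloud | None:
    """Retain points strictly above the trellis wire height.

    Equality is excluded: a point exactly at the wire is treated as
    undergrowth (the exclusion is documented, not implied by the wire
    height itself). Idempotent.
    """
    if points is None:
        return None
    keep = points.z > trellis_height
    if not keep.any():
        return None
    return points.subset(keep)


def segment_vines(
    cloud: NormalizedPointCloud,
    polygons: list[VinePolygon],
    trellis_height: float = 0.30,
) -> list[VineCloud]:
    """Clip the cloud per vine and apply the trellis filter."""
    out = []
    for poly in polygons:
        clipped = clip_by_polygon(cloud, poly)
        canopy = filter_trellis(clipped, trellis_height)
        out.append(VineCloud(poly.vine_id, poly, clipped, canopy))
    return out
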