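"""Ground classification and height normalization.

A progressive morphological filter in the SMRF family drives the
workflow: (1) grid the cloud into a minimum-elevation surface,
(2) open that surface with windows of increasing radius and flag cells
that rise faster than a slope-scaled tolerance (non-ground), (3)
interpolate a DTM from the surviving ground cells and classify the
original points against it, then subtract the interpolated ground
elevation from every point.

Defaults (0.25 m cells, 2.0 m maximum window, slope 0.15, 0.05 m
elevation threshold, scaler 1.25) follow the published recommendations
for the algorithm family, with the maximum window sized above a vine
canopy footprint so whole canopies cannot be absorbed into the terrain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from vinemetrics.cloud_io import LAS_GROUND, NormalizedPointCloud, PointCloud

logger = logging.getLogger(__name__)


class DegenerateTerrainError(RuntimeError):
    """All cells were flagged non-ground; try a larger max_window_radius."""


class OutOfExtentError(ValueError):
    """A point lies more than one cell outside the ground model's grid."""


@dataclass(frozen=True)
class SmrfParams:
    cell_size: float = 0.25  # m, minimum-surface grid
    max_window_radius: float = 2.0  # m
    slope_threshold: float = 0.15  # rise/run
    elevation_threshold: float = 0.05  # m
    elevation_scaler: float = 1.25  # unitless

    def __post_init__(self) -> None:
        for name in ("cell_size", "max_window_radius", "slope_threshold",
                     "elevation_threshold", "elevation_scaler"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0")
        if self.max_window_radius <= self.cell_size:
            raise ValueError("max_window_radius must exceed cell_size")


@dataclass
class GroundModel:
    """Gridded ground elevation (cell centers) plus the ground-cell mask."""

    origin: tuple[float, float]  # world XY of the grid corner (min x, min y)
    cell_size: float
    elevation: np.ndarray  # (nx, ny), finite after inpainting
    ground_mask: np.ndarray  # (nx, ny) bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.elevation.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def interpolate(self, x: np.ndarray, y: np.ndarray,
                    margin_cells: float = 1.0) -> np.ndarray:
        """Bilinear ground elevation at XY, nearest-cell at the margins."""
        xs, ys = self.cell_centers()
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        tol = margin_cells * self.cell_size
        if (
            (x < xs[0] - 0.5 * self.cell_size - tol).any()
            or (x > xs[-1] + 0.5 * self.cell_size + tol).any()
            or (y < ys[0] - 0.5 * self.cell_size - tol).any()
            or (y > ys[-1] + 0.5 * self.cell_size + tol).any()
        ):
            raise OutOfExtentError(
                "points lie more than one cell outside the ground model"
            )
        if xs.size < 2 or ys.size < 2:
            # degenerate 1-cell axis: nearest-cell lookup
            ix = np.clip(((x - self.origin[0]) / self.cell_size).astype(int), 0, xs.size - 1)
            iy = np.clip(((y - self.origin[1]) / self.cell_size).astype(int), 0, ys.size - 1)
            return self.elevation[ix, iy]
        interp = RegularGridInterpolator(
            (xs, ys), self.elevation, method="linear",
            bounds_error=False, fill_value=None,  # linear extrapolation at margin
        )
        return interp(np.column_stack([np.clip(x, xs[0], xs[-1]),
                                       np.clip(y, ys[0], ys[-1])]))

    def slope(self) -> np.ndarray:
        """Per-cell slope magnitude (rise/run) of the elevation grid."""
        if min(self.elevation.shape) < 2:
            return np.zeros_like(self.elevation)
        gx, gy = np.gradient(self.elevation, self.cell_size)
        return np.hypot(gx, gy)

    def to_ascii_grid(self, path) -> None:
        """Export as an ESRI ASCII raster (rows from north to south)."""
        nx, ny = self.elevation.shape
        lines = [
            f"ncols {nx}", f"nrows {ny}",
            f"xllcorner {self.origin[0]:.3f}", f"yllcorner {self.origin[1]:.3f}",
            f"cellsize {self.cell_size}", "NODATA_value -9999",
        ]
        grid = self.elevation.T[::-1]  # (ny, nx), top row = max y
        for row in grid:
            lines.append(" ".join(f"{v:.3f}" for v in row))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# minimum surface
# ---------------------------------------------------------------------------


def _grid_index(cloud: PointCloud, origin, cell_size, shape):
    ix = np.floor((cloud.x - origin[0]) / cell_size).astype(int)
    iy = np.floor((cloud.y - origin[1]) / cell_size).astype(int)
    return np.clip(ix, 0, shape[0] - 1), np.clip(iy, 0, shape[1] - 1)


def build_min_surface(cloud: PointCloud, cell_size: float = 0.25) -> GroundModel:
    """Minimum z per cell; empty cells inpainted from their nearest finite
    neighbor followed by one Laplacian smoothing pass over inpainted cells."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    origin = (float(cloud.x.min()), float(cloud.y.min()))
    nx = max(1, int(np.ceil((cloud.x.max() - origin[0]) / cell_size)))
    ny = max(1, int(np.ceil((cloud.y.max() - origin[1]) / cell_size)))
    ix, iy = _grid_index(cloud, origin, cell_size, (nx, ny))
    grid = np.full((nx, ny), np.inf)
    np.minimum.at(grid, (ix, iy), cloud.z)
    empty = ~np.isfinite(grid)
    if empty.any():
        grid = _inpaint(grid, empty)
    return GroundModel(origin=origin, cell_size=cell_size,
                       elevation=grid, ground_mask=np.ones((nx, ny), bool))


def _inpaint(grid: np.ndarray, holes: np.ndarray) -> np.ndarray:
    """Nearest-finite-neighbor fill, then one Laplacian pass on the holes."""
    out = grid.copy()
    if holes.all():
        raise ValueError("cannot inpaint a fully empty grid")
    _, (ii, jj) = ndimage.distance_transform_edt(holes, return_indices=True)
    out[holes] = out[ii[holes], jj[holes]]
    if min(out.shape) >= 2:
        smoothed = ndimage.uniform_filter(out, size=3, mode="nearest")
        out[holes] = smoothed[holes]
    return out


# ---------------------------------------------------------------------------
# SMRF classification
# ---------------------------------------------------------------------------


def _disk(radius_cells: int) -> np.ndarray:
    r = radius_cells
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx**2 + yy**2) <= r**2


def smrf_classify(
    cloud: PointCloud, params: SmrfParams = SmrfParams()
) -> tuple[np.ndarray, GroundModel]:
    """Progressive morphological ground filtering.

    Returns per-point ground flags and the final (inpainted) DTM. A point
    is ground when its elevation sits within
    ``elevation_threshold + elevation_scaler * local_DTM_slope``
    of the bilinearly interpolated DTM at its XY.
    """
    provisional = build_min_surface(cloud, params.cell_size)
    surface = provisional.elevation.copy()
    nongrd = np.zeros(surface.shape, dtype=bool)
    max_r = int(np.ceil(params.max_window_radius / params.cell_size))
    opened = surface.copy()
    for r in range(1, max_r + 1):
        footprint = _disk(r)
        opened = ndimage.grey_dilation(
            ndimage.grey_erosion(opened, footprint=footprint),
            footprint=footprint,
        )
        tolerance = params.slope_threshold * (r * params.cell_size)
        nongrd |= (surface - opened) > tolerance
    if nongrd.all():
        raise DegenerateTerrainError(
            "no ground cells survived the morphological opening; "
            "consider a larger max_window_radius"
        )
    ground_cells = ~nongrd

    dtm_grid = provisional.elevation.copy()
    dtm_grid[nongrd] = np.inf
    dtm_grid = _inpaint(dtm_grid, ~np.isfinite(dtm_grid))
    dtm = GroundModel(origin=provisional.origin, cell_size=params.cell_size,
                      elevation=dtm_grid, ground_mask=ground_cells)

    ground_z = dtm.interpolate(cloud.x, cloud.y)
    slope = dtm.slope()
    ix, iy = _grid_index(cloud, dtm.origin, params.cell_size, dtm.shape)
    tol = params.elevation_threshold + params.elevation_scaler * slope[ix, iy]
    flags = np.abs(cloud.z - ground_z) <= tol
    logger.info(
        "SMRF: %d / %d points classified ground (%.1f%% ground cells)",
        int(flags.sum()), len(cloud), 100 * ground_cells.mean(),
    )
    return flags, dtm


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_heights(
    cloud: PointCloud,
    ground_model: GroundModel,
    ground_flags: np.ndarray | None = None,
) -> NormalizedPointCloud:
    """Replace elevation with height above the interpolated ground.

    Slightly negative heights (sensor noise below the DTM) are kept;
    the downstream trellis filter removes them anyway.
    """
    if not np.isfinite(ground_model.elevation).all():
        raise ValueError("ground model must be fully inpainted")
    heights = cloud.z - ground_model.interpolate(cloud.x, cloud.y)
    classification = cloud.classification
    if ground_flags is not None:
        classification = np.where(ground_flags, LAS_GROUND, 0).astype(np.uint8)
    return NormalizedPointCloud(
        x=cloud.x.copy(), y=cloud.y.copy(), z=heights,
        classification=classification,
        return_number=cloud.return_number,
        number_of_returns=cloud.number_of_returns,
        rgb=cloud.rgb, truth=cloud.truth,
        crs_tag=cloud.crs_tag, sensor_name=cloud.sensor_name,
        ground_flag=ground_flags,
    )


def normalize_cloud(
    cloud: PointCloud, params: SmrfParams = SmrfParams()
) -> tuple[NormalizedPointCloud, GroundModel]:
    """Convenience: SMRF-classify, build the DTM, and normalize in one call."""
    flags, dtm = smrf_classify(cloud, params)
    return normalize_heights(cloud, dtm, ground_flags=flags), dtm
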