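"""Canopy structure metrics from normalized-height plot point clouds.

Seven features per plot: 75th and 90th height percentiles, quadratic mean
height, column (2.5D) voxel volume at 8 cm resolution, and canopy cover at
the 20th/50th/75th percentile heights.

Conventions, fixed here because they matter for comparability:

* percentiles use linear interpolation between order statistics and are
  computed over non-ground returns;
* canopy cover thresholds come from the non-ground height distribution, but
  the cover fraction counts strictly-above points over *all* returns (ground
  included), so the metric responds to canopy closure instead of reducing to
  1 - p/100;
* volume sums, over occupied 8 cm x 8 cm grid cells, cell area times the
  maximum non-ground height in the cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "PlotPointCloud",
    "LidarFeatureVector",
    "LIDAR_FEATURE_NAMES",
    "height_percentile",
    "quadratic_mean_height",
    "voxel_volume",
    "canopy_cover_at_percentile",
    "extract_lidar_features",
]

LIDAR_FEATURE_NAMES = (
    "height_p75",
    "height_p90",
    "height_qmean",
    "voxel_volume",
    "cover_p20",
    "cover_p50",
    "cover_p75",
)

#: fallback height (m) separating ground from canopy when no flags exist
GROUND_HEIGHT_THRESHOLD = 0.1


@dataclass
class PlotPointCloud:
    """Normalized-height returns of one plot on one date.

    x, y        : (n,) plot-local coordinates in m
    height      : (n,) height above ground in m (>= 0)
    plot_polygon: shapely Polygon of the (already row-trimmed) plot
    ground_flag : (n,) booleans; points within 0.1 m of the ground are
                  flagged when no classification is supplied
    """

    x: np.ndarray
    y: np.ndarray
    height: np.ndarray
    plot_polygon: Polygon
    ground_flag: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if np.any(self.height < 0):
            raise DomainError("normalized heights must be >= 0")
        if self.ground_flag is None:
            self.ground_flag = self.height <= GROUND_HEIGHT_THRESHOLD
        else:
            self.ground_flag = np.asarray(self.ground_flag, dtype=bool)

    @property
    def n_points(self) -> int:
        return self.height.size

    def canopy_heights(self) -> np.ndarray:
        return self.height[~self.ground_flag]


@dataclass
class LidarFeatureVector:
    values: np.ndarray
    names: tuple = field(default=LIDAR_FEATURE_NAMES)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise DomainError("LiDAR feature vector must have 7 entries")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def height_percentile(cloud: PlotPointCloud, p: float) -> float:
    """p-th percentile of non-ground heights (linear interpolation).

    An empty canopy yields 0.0 with a warning rather than an error, so bare
    plots flow through feature extraction.
    """
    if not 0 < p < 100:
        raise DomainError("percentile must lie in (0, 100)")
    h = cloud.canopy_heights()
    if h.size == 0:
        logger.warning("empty canopy: height percentile set to 0")
        return 0.0
    return float(np.percentile(h, p))


def quadratic_mean_height(cloud: PlotPointCloud) -> float:
    """Q = sqrt(mean(h_i^2)) over non-ground returns."""
    h = cloud.canopy_heights()
    if h.size == 0:
        logger.warning("empty canopy: quadratic mean height set to 0")
        return 0.0
    return float(np.sqrt(np.mean(h**2)))


def voxel_volume(cloud: PlotPointCloud, cell_size: float = 0.08) -> float:
    """Column volume: sum over occupied cells of cell area x max canopy height."""
    if cell_size <= 0:
        raise DomainError("cell_size must be positive")
    keep = ~cloud.ground_flag
    if not keep.any():
        return 0.0
    xs, ys, hs = cloud.x[keep], cloud.y[keep], cloud.height[keep]
    x0, y0 = xs.min(), ys.min()
    ix = np.floor((xs - x0) / cell_size).astype(np.int64)
    iy = np.floor((ys - y0) / cell_size).astype(np.int64)
    cell = ix * (iy.max() + 1) + iy
    order = np.argsort(cell, kind="stable")
    cell_sorted, h_sorted = cell[order], hs[order]
    boundaries = np.flatnonzero(np.diff(cell_sorted)) + 1
    cell_max = np.maximum.reduceat(h_sorted, np.concatenate(([0], boundaries)))
    return float(cell_size * cell_size * cell_max.sum())


def canopy_cover_at_percentile(cloud: PlotPointCloud, p: float) -> float:
    """Fraction of all returns strictly above the p-th canopy-height percentile."""
    if cloud.n_points == 0:
        raise DomainError("point cloud is empty")
    h = cloud.canopy_heights()
    if h.size == 0:
        return 0.0
    threshold = np.percentile(h, p)
    return float(np.mean(cloud.height > threshold))


def extract_lidar_features(cloud: PlotPointCloud) -> LidarFeatureVector:
    """All seven canopy structure features of one plot, in fixed order."""
    values = np.array(
        [
            height_percentile(cloud, 75),
            height_percentile(cloud, 90),
            quadratic_mean_height(cloud),
            voxel_volume(cloud),
            canopy_cover_at_percentile(cloud, 20),
            canopy_cover_at_percentile(cloud, 50),
            canopy_cover_at_percentile(cloud, 75),
        ]
    )
    return LidarFeatureVector(values)


# ---------------------------------------------------------------------------
# I/O helpers

def read_cloud_csv(path, plot_polygon: Polygon) -> PlotPointCloud:
    """Read an XYZ(+ground flag) CSV with columns x, y, height[, ground]."""
    import pandas as pd

    frame = pd.read_csv(path)
    ground = frame["ground"].to_numpy(bool) if "ground" in frame else None
    return PlotPointCloud(
        frame["x"].to_numpy(),
        frame["y"].to_numpy(),
        frame["height"].to_numpy(),
        plot_polygon,
        ground,
    )
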