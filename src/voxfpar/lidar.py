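"""Point-cloud processing: ground classification, height normalization,
canopy height models and watershed tree segmentation.

Conventions
-----------
* Cell binning is half-open and lower-edge inclusive; the grid origin is the
  minimum coordinate floored to the cell grid, which prevents double counting
  at cell edges.
* Ties (equal maxima in a cell, plateau maxima in segmentation) are broken by
  the lowest point index / lexicographically smallest cell, so every result
  is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .cloud import GROUND_CLASS, UNCLASSIFIED, PointCloud
from .errors import InsufficientDataError
from .las_io import read_las, write_las  # noqa: F401  (module surface)

NODATA = np.nan


@dataclass
class HeightRaster:
    """Single-band height grid; ``values[j, i]`` covers the half-open cell
    [x0 + i*cell, x0 + (i+1)*cell) x [y0 + j*cell, y0 + (j+1)*cell).
    Empty cells hold NaN."""

    origin_x: float
    origin_y: float
    cell: float
    values: np.ndarray

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    def cell_center(self, row, col):
        return (self.origin_x + (np.asarray(col) + 0.5) * self.cell,
                self.origin_y + (np.asarray(row) + 0.5) * self.cell)

    def cell_index(self, x, y):
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell).astype(int)
        return row, col


def _grid_indices(x, y, cell):
    x0 = np.floor(x.min() / cell) * cell
    y0 = np.floor(y.min() / cell) * cell
    col = np.floor((x - x0) / cell).astype(int)
    row = np.floor((y - y0) / cell).astype(int)
    return x0, y0, row, col


def classify_ground(pc: PointCloud, cell: float = 2.0,
                    tolerance: float = 0.3) -> PointCloud:
    """Flag per-cell lowest points (within ``tolerance``) as ground.

    A simple minimum-surface classifier: within every ``cell`` x ``cell``
    tile the lowest return defines the local ground level and every point
    within ``tolerance`` of it is classified as ground. Adequate for the
    near-planar terrain this package targets.
    """
    if cell <= 0:
        raise ValueError("cell must be positive")
    if len(pc) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(pc)}")
    x0, y0, row, col = _grid_indices(pc.x, pc.y, cell)
    nrow, ncol = row.max() + 1, col.max() + 1
    zmin = np.full((nrow, ncol), np.inf)
    np.minimum.at(zmin, (row, col), pc.z)
    is_ground = pc.z <= zmin[row, col] + tolerance
    classification = np.where(is_ground, GROUND_CLASS, UNCLASSIFIED).astype(np.uint8)
    return PointCloud(pc.x.copy(), pc.y.copy(), pc.z.copy(), classification,
                      None if pc.return_number is None else pc.return_number.copy())


def ground_surface(pc: PointCloud, cell: float = 2.0) -> HeightRaster:
    """Per-cell mean elevation of ground-classified points, holes filled by
    nearest neighbour."""
    ground = pc.subset(pc.is_ground)
    if len(ground) == 0:
        raise InsufficientDataError("no ground-classified points")
    x0, y0, row, col = _grid_indices(pc.x, pc.y, cell)
    grow = np.floor((ground.y - y0) / cell).astype(int)
    gcol = np.floor((ground.x - x0) / cell).astype(int)
    nrow, ncol = row.max() + 1, col.max() + 1
    total = np.zeros((nrow, ncol))
    count = np.zeros((nrow, ncol))
    np.add.at(total, (grow, gcol), ground.z)
    np.add.at(count, (grow, gcol), 1.0)
    with np.errstate(invalid="ignore"):
        mean = total / count
    if (count == 0).any():
        # nearest-neighbour hole fill
        idx = ndimage.distance_transform_edt(count == 0, return_distances=False,
                                             return_indices=True)
        mean = mean[tuple(idx)]
    return HeightRaster(x0, y0, cell, mean)


def _bilinear(surface: HeightRaster, x, y):
    """Bilinear interpolation at cell centers, clamped at the grid edge."""
    g = surface.cell
    fx = (np.asarray(x) - surface.origin_x) / g - 0.5
    fy = (np.asarray(y) - surface.origin_y) / g - 0.5
    nrow, ncol = surface.shape
    i0 = np.clip(np.floor(fx).astype(int), 0, max(ncol - 2, 0))
    j0 = np.clip(np.floor(fy).astype(int), 0, max(nrow - 2, 0))
    tx = np.clip(fx - i0, 0.0, 1.0)
    ty = np.clip(fy - j0, 0.0, 1.0)
    i1 = np.minimum(i0 + 1, ncol - 1)
    j1 = np.minimum(j0 + 1, nrow - 1)
    v = surface.values
    return ((1 - tx) * (1 - ty) * v[j0, i0] + tx * (1 - ty) * v[j0, i1]
            + (1 - tx) * ty * v[j1, i0] + tx * ty * v[j1, i1])


def normalize_heights(pc: PointCloud, cell: float = 2.0,
                      drop_below: float = -0.1) -> PointCloud:
    """Convert elevations to height above the interpolated ground surface.

    Points more than 0.1 m below the ground surface are dropped; small
    negative heights are clamped to zero. Requires ground classification.
    """
    if pc.classification is None or not pc.is_ground.any():
        raise InsufficientDataError("cloud has no ground-classified points")
    surface = ground_surface(pc, cell=cell)
    z = pc.z - _bilinear(surface, pc.x, pc.y)
    keep = z >= drop_below
    out = pc.subset(keep)
    out.z = np.maximum(z[keep], 0.0)
    return out


def rasterize_chm(pc: PointCloud, gsd: float) -> HeightRaster:
    """Canopy height model: per-cell maximum of normalized heights."""
    if gsd <= 0:
        raise ValueError("gsd must be positive")
    if len(pc) == 0:
        return HeightRaster(0.0, 0.0, gsd, np.full((1, 1), NODATA))
    x0, y0, row, col = _grid_indices(pc.x, pc.y, gsd)
    nrow, ncol = row.max() + 1, col.max() + 1
    values = np.full((nrow, ncol), -np.inf)
    np.maximum.at(values, (row, col), pc.z)
    values[np.isinf(values)] = NODATA
    return HeightRaster(x0, y0, gsd, values)


@dataclass
class TreeSegmentation:
    """Label raster (0 = background) plus a per-tree apex table."""

    labels: np.ndarray
    raster: HeightRaster  # geometry reference (the CHM that was segmented)
    trees: pd.DataFrame   # tree_id, apex_x, apex_y, apex_height

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def label_at(self, x, y) -> np.ndarray:
        """Segment label for world coordinates (0 outside every segment)."""
        row, col = self.raster.cell_index(x, y)
        nrow, ncol = self.labels.shape
        inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        out = np.zeros(np.shape(row), dtype=int)
        out[inside] = self.labels[row[inside], col[inside]]
        return out


def segment_trees(chm: HeightRaster, smooth_sigma: float = 1.0,
                  min_height: float = 2.0,
                  min_distance: int = 3) -> TreeSegmentation:
    """Marker-controlled watershed segmentation of a CHM.

    The CHM (NaN treated as zero) is Gaussian-smoothed, local maxima above
    ``min_height`` and at least ``min_distance`` cells apart become markers,
    and a watershed on the inverted smoothed surface grows one segment per
    marker within the above-threshold mask. Returns zero trees when nothing
    exceeds ``min_height``.
    """
    filled = np.where(np.isnan(chm.values), 0.0, chm.values)
    smoothed = ndimage.gaussian_filter(filled, smooth_sigma) if smooth_sigma > 0 \
        else filled
    mask = smoothed >= min_height
    if not mask.any():
        return TreeSegmentation(np.zeros(chm.shape, dtype=int), chm,
                                pd.DataFrame(columns=["tree_id", "apex_x",
                                                      "apex_y", "apex_height"]))
    peaks = peak_local_max(smoothed, min_distance=min_distance,
                           threshold_abs=min_height, exclude_border=False)
    if len(peaks) == 0:
        return TreeSegmentation(np.zeros(chm.shape, dtype=int), chm,
                                pd.DataFrame(columns=["tree_id", "apex_x",
                                                      "apex_y", "apex_height"]))
    # deterministic marker ids: sort peaks lexicographically by (row, col)
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    markers = np.zeros(chm.shape, dtype=int)
    markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers, mask=mask)

    rows = []
    chm_vals = np.where(np.isnan(chm.values), -np.inf, chm.values)
    for tree_id in range(1, len(peaks) + 1):
        seg = labels == tree_id
        if not seg.any():
            continue
        masked = np.where(seg, chm_vals, -np.inf)
        flat = int(np.argmax(masked))  # first occurrence = row-major smallest
        r, c = np.unravel_index(flat, masked.shape)
        ax, ay = chm.cell_center(r, c)
        rows.append((tree_id, float(ax), float(ay), float(chm_vals[r, c])))
    trees = pd.DataFrame(rows, columns=["tree_id", "apex_x", "apex_y",
                                        "apex_height"])
    return TreeSegmentation(labels, chm, trees)
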