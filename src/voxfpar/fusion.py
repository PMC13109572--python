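"""Co-registration, voxelization, and column-wise reflectance propagation.

Nadir imagery only sees the uppermost illuminated canopy surface, so the
five-band reflectance for a vertical column is taken from the orthomosaic
pixel under the column's highest LiDAR point and duplicated to every
occupied voxel of that column ("highest point within column" propagation).
Reflectance is therefore constant along the vertical dimension within each
column and varies only horizontally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .errors import DegenerateDataError, FormatError
from .raster import MultiBandRaster

REFLECTANCE_COLUMNS = ["R450", "R560", "R650", "R730", "R840"]


@dataclass
class AffineTransform2D:
    """2D affine map from the point-cloud frame to the raster frame."""

    matrix: np.ndarray  # shape (2, 3): [[a, b, c], [d, e, f]]
    rmse: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise DegenerateDataError("affine transform is not invertible")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        m = self.matrix
        return (m[0, 0] * x + m[0, 1] * y + m[0, 2],
                m[1, 0] * x + m[1, 1] * y + m[1, 2])


def fit_coregistration(cloud_xy, raster_xy) -> AffineTransform2D:
    """Least-squares affine fit from control-point pairs.

    ``cloud_xy`` and ``raster_xy`` are (n, 2) arrays of matched coordinates;
    at least three non-collinear pairs are required.
    """
    src = np.asarray(cloud_xy, dtype=float).reshape(-1, 2)
    dst = np.asarray(raster_xy, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise DegenerateDataError("control point lists differ in length")
    if len(src) < 3:
        raise DegenerateDataError(f"need >= 3 control pairs, got {len(src)}")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateDataError("control points are collinear")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef.T  # (2, 3)
    fitted = design @ coef
    rmse = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    return AffineTransform2D(matrix, rmse=rmse)


@dataclass
class VoxelGrid:
    """Occupied voxels of a normalized cloud plus per-column top points.

    ``voxels`` columns: i, j, k, n_points. ``columns`` columns: i, j, top_z,
    top_x, top_y — the LiDAR point with the highest normalized height in the
    column (ties broken by smallest point index).
    """

    origin_x: float
    origin_y: float
    dx: float
    dy: float
    dz: float
    voxels: pd.DataFrame
    columns: pd.DataFrame

    @property
    def n_points(self) -> int:
        return int(self.voxels["n_points"].sum()) if len(self.voxels) else 0

    def centroids(self) -> pd.DataFrame:
        v = self.voxels
        return pd.DataFrame({
            "x": self.origin_x + (v["i"] + 0.5) * self.dx,
            "y": self.origin_y + (v["j"] + 0.5) * self.dy,
            "z": (v["k"] + 0.5) * self.dz,
        })


def voxelize(pc: PointCloud, dx: float = 0.25, dy: float = 0.25,
             dz: float = 2.0) -> VoxelGrid:
    """Bin a normalized cloud into (dx, dy, dz) voxels by half-open flooring.

    i = floor((x - x0)/dx), j = floor((y - y0)/dy), k = floor(z/dz) with the
    horizontal origin floored to the cell grid and the vertical origin at
    ground level (z = 0).
    """
    if min(dx, dy, dz) <= 0:
        raise ValueError("voxel resolutions must be positive")
    if len(pc) == 0:
        empty_v = pd.DataFrame(columns=["i", "j", "k", "n_points"]).astype(int)
        empty_c = pd.DataFrame(columns=["i", "j", "top_z", "top_x", "top_y"])
        return VoxelGrid(0.0, 0.0, dx, dy, dz, empty_v, empty_c)
    x0 = np.floor(pc.x.min() / dx) * dx
    y0 = np.floor(pc.y.min() / dy) * dy
    i = np.floor((pc.x - x0) / dx).astype(int)
    j = np.floor((pc.y - y0) / dy).astype(int)
    k = np.floor(pc.z / dz).astype(int)

    ijk = np.column_stack([i, j, k])
    uniq, counts = np.unique(ijk, axis=0, return_counts=True)
    voxels = pd.DataFrame({"i": uniq[:, 0], "j": uniq[:, 1], "k": uniq[:, 2],
                           "n_points": counts})

    # per-column top point: sort by (column, -z, index) and take the first
    # row of each column so equal heights resolve to the smallest index
    idx = np.arange(len(pc))
    order = np.lexsort((idx, -pc.z, j, i))
    si, sj = i[order], j[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = (si[1:] != si[:-1]) | (sj[1:] != sj[:-1])
    top = order[first]
    columns = pd.DataFrame({
        "i": i[top], "j": j[top],
        "top_z": pc.z[top], "top_x": pc.x[top], "top_y": pc.y[top],
    }).sort_values(["i", "j"], ignore_index=True)
    return VoxelGrid(float(x0), float(y0), dx, dy, dz, voxels, columns)


def propagate_reflectance(grid: VoxelGrid, raster: MultiBandRaster,
                          transform: AffineTransform2D | None = None,
                          ) -> pd.DataFrame:
    """Assign each column's top-point reflectance to all its occupied voxels.

    The column's top point is mapped into the raster frame (identity if no
    transform is given) and the five-band value of the pixel containing it
    (nearest-neighbour sampling) is written to every voxel of the column.
    Columns falling outside the raster get missing reflectance and
    ``in_raster = False``.

    Returns the fused voxel table: i, j, k, x, y, z, n_points, R450..R840,
    in_raster.
    """
    if raster.n_bands != 5:
        raise FormatError(f"expected a 5-band raster, got {raster.n_bands} bands")
    if transform is None:
        transform = AffineTransform2D.identity()
    cols = grid.columns
    rx, ry = transform.apply(cols["top_x"].to_numpy(), cols["top_y"].to_numpy())
    values, inside = raster.sample_nearest(rx, ry)
    col_refl = cols[["i", "j"]].copy()
    for b, name in enumerate(REFLECTANCE_COLUMNS):
        col_refl[name] = values[:, b]
    col_refl["in_raster"] = inside

    table = pd.concat([grid.voxels.reset_index(drop=True),
                       grid.centroids().reset_index(drop=True)], axis=1)
    table = table.merge(col_refl, on=["i", "j"], how="left", validate="m:1")
    table = table[["i", "j", "k", "x", "y", "z", "n_points",
                   *REFLECTANCE_COLUMNS, "in_raster"]]
    return table.sort_values(["i", "j", "k"], ignore_index=True)
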