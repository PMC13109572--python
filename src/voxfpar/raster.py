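"""Simple in-memory multi-band raster with TIFF serialization.

The raster lives in a local metric frame: pixel (row j, col i) covers the
half-open square [x0 + i*gsd, x0 + (i+1)*gsd) x [y0 + j*gsd, y0 + (j+1)*gsd),
i.e. row index increases with y (origin at the lower-left corner).
Georeferencing (origin, gsd, band centers) travels in the TIFF description
tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError

BAND_CENTERS_NM = (450, 560, 650, 730, 840)


@dataclass
class MultiBandRaster:
    origin_x: float
    origin_y: float
    gsd: float
    data: np.ndarray  # (n_bands, n_rows, n_cols)
    band_centers: tuple = BAND_CENTERS_NM

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("raster data must be (bands, rows, cols)")
        if self.gsd <= 0:
            raise FormatError("gsd must be positive")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    def pixel_index(self, x, y):
        """Map world coordinates to (row, col); may fall outside the grid."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.gsd).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.gsd).astype(int)
        return row, col

    def sample_nearest(self, x, y):
        """Sample the pixel containing each (x, y).

        Returns (values, inside) where values is (n, n_bands) with NaN rows
        for points outside the raster extent.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.pixel_index(x, y)
        ny, nx = self.shape
        inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        out = np.full((x.size, self.n_bands), np.nan)
        if inside.any():
            out[inside] = self.data[:, row[inside], col[inside]].T
        return out, inside

    def to_tiff(self, path) -> None:
        meta = {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "gsd": self.gsd,
            "band_centers": list(self.band_centers),
        }
        tifffile.imwrite(path, self.data.astype(np.float32),
                         description=json.dumps(meta))

    @classmethod
    def from_tiff(cls, path) -> "MultiBandRaster":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: missing raster metadata in TIFF description") from exc
        if data.ndim == 2:
            data = data[None, :, :]
        return cls(origin_x=float(meta["origin_x"]), origin_y=float(meta["origin_y"]),
                   gsd=float(meta["gsd"]), data=np.asarray(data, dtype=float),
                   band_centers=tuple(meta.get("band_centers", BAND_CENTERS_NM)))


def write_single_band(path, values: np.ndarray, origin_x: float, origin_y: float,
                      gsd: float) -> None:
    """Write one 2D grid (e.g. a CHM or a label raster) as a TIFF."""
    meta = {"origin_x": origin_x, "origin_y": origin_y, "gsd": gsd,
            "band_centers": []}
    tifffile.imwrite(path, np.asarray(values), description=json.dumps(meta))


def read_single_band(path):
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    return data, float(meta["origin_x"]), float(meta["origin_y"]), float(meta["gsd"])
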