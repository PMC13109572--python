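"""The point-cloud container shared by LiDAR I/O, normalization and fusion."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FormatError

#: ASPRS classification codes used throughout the package.
GROUND_CLASS = 2
VEGETATION_CLASS = 5
UNCLASSIFIED = 1


@dataclass
class PointCloud:
    """x/y/z returns in a local metric frame.

    ``classification`` follows ASPRS codes (2 = ground); ``return_number`` is
    optional and unused downstream but preserved through LAS round trips.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: Optional[np.ndarray] = None
    return_number: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise FormatError("x, y, z must have equal length")
        for arr in (self.x, self.y, self.z):
            if arr.size and not np.isfinite(arr).all():
                raise FormatError("point coordinates must be finite")
        if self.classification is not None:
            self.classification = np.asarray(self.classification, dtype=np.uint8)
            if self.classification.size != n:
                raise FormatError("classification length mismatch")
        if self.return_number is not None:
            self.return_number = np.asarray(self.return_number, dtype=np.uint8)
            if self.return_number.size != n:
                raise FormatError("return_number length mismatch")

    def __len__(self) -> int:
        return self.x.size

    @property
    def is_ground(self) -> np.ndarray:
        if self.classification is None:
            return np.zeros(len(self), dtype=bool)
        return self.classification == GROUND_CLASS

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            None if self.classification is None else self.classification[mask],
            None if self.return_number is None else self.return_number[mask],
        )
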