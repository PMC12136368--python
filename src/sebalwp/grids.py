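"""Raster grid geometry and masking conventions.

All rasters in one analysis share a single grid: same shape, cell size and
origin. Invalid pixels are encoded as NaN in float rasters; helper functions
derive boolean masks from that. Integer rasters (zones) use a nodata value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry", "valid_mask", "check_aligned"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular grid in a projected (metric) coordinate system.

    ``origin_x``/``origin_y`` locate the *outer corner* of pixel (0, 0);
    rows increase southward (y decreases), columns increase eastward.
    Geographic coordinates returned by :meth:`cell_center` refer to pixel
    centers.
    """

    rows: int
    cols: int
    cell_size: float  # m
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def cell_center(self, row, col):
        """x, y coordinates of the center of pixel (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def xy_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full per-pixel center-coordinate grids (x, y), each rows x cols."""
        rr, cc = np.mgrid[0 : self.rows, 0 : self.cols]
        return self.cell_center(rr, cc)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "cell_size": self.cell_size,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            cell_size=float(d["cell_size"]),
            origin_x=float(d.get("origin_x", 0.0)),
            origin_y=float(d.get("origin_y", 0.0)),
        )


def valid_mask(*arrays: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels finite in every input array."""
    if not arrays:
        raise ValueError("at least one array required")
    m = np.isfinite(np.asarray(arrays[0], dtype=float))
    for a in arrays[1:]:
        m &= np.isfinite(np.asarray(a, dtype=float))
    return m


def check_aligned(*arrays: np.ndarray, shape: tuple[int, int] | None = None) -> tuple[int, int]:
    """Reject shape mismatches instead of broadcasting or resampling."""
    shapes = {np.asarray(a).shape for a in arrays}
    if shape is not None:
        shapes.add(tuple(shape))
    if len(shapes) != 1:
        raise ValueError(f"rasters are not co-registered: shapes {sorted(shapes)}")
    return shapes.pop()
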