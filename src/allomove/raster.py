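"""Plain-text gridded rasters (ESRI-ASCII style) with bilinear sampling.

Used for the distance-to-shore covariate: cell values hold distance (km)
from each cell centre to the shoreline, and track locations are sampled by
bilinear interpolation between the four surrounding cell centres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["AsciiRaster"]

log = logging.getLogger(__name__)


@dataclass
class AsciiRaster:
    """A regular grid with lower-left origin, row 0 of ``data`` at the top.

    ``data`` has shape (nrows, ncols); cell (row, col) has its centre at
    ``(xll + (col + 0.5) h, yll + (nrows - row - 0.5) h)`` with cellsize
    ``h`` — the ESRI ASCII grid convention.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("raster data must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Ascending y of cell centres (i.e. bottom row first)."""
        return self.yll + (np.arange(self.nrows) + 0.5) * self.cellsize

    def interpolate(self, x, y) -> np.ndarray:
        """Bilinear interpolation between the four surrounding cell centres.

        Points outside the hull of cell centres return NaN with a warning.
        """
        interp = RegularGridInterpolator(
            (self.y_centers(), self.x_centers()),
            self.data[::-1],  # flip so row index increases with y
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )
        pts = np.column_stack([np.atleast_1d(y), np.atleast_1d(x)])
        out = interp(pts)
        n_out = int(np.sum(~np.isfinite(out)))
        if n_out:
            log.warning("%d query point(s) outside raster extent -> NaN", n_out)
        return out if np.ndim(x) else float(out[0])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            np.savetxt(fh, self.data, fmt="%.8g")

    @classmethod
    def read(cls, path) -> "AsciiRaster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("raster body does not match header dimensions")
        return cls(
            data=data,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )
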