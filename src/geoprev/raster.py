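"""Minimal single-band raster container with plain-text (ESRI ASCII grid) I/O.

Rasters are stored row-major with row 0 at the *top* (north), matching the
ASCII-grid convention.  Coordinates are planar kilometres throughout the
package; ``cellsize`` is therefore in km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band gridded surface.

    Attributes
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values, row 0 at the top (largest y).
    xll, yll : float
        Coordinates of the lower-left corner of the grid (km).
    cellsize : float
        Square cell edge length (km).
    nodata : float
        Sentinel for missing cells.
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates, each shaped (nrows, ncols)."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell whose *center* is nearest to (x, y).

        Points outside the extent snap to the nearest edge cell.  Ties on a
        cell boundary break to the lower (row, col) index so extraction is
        deterministic.
        """
        col = (x - self.xll) / self.cellsize - 0.5
        # row measured from the top
        row = (self.yll + self.nrows * self.cellsize - y) / self.cellsize - 0.5
        # round half toward the lower index
        c = int(np.ceil(col - 0.5))
        r = int(np.ceil(row - 0.5))
        return (min(max(r, 0), self.nrows - 1), min(max(c, 0), self.ncols - 1))

    def is_nodata(self, value: float) -> bool:
        return not np.isfinite(value) or value == self.nodata

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return np.isfinite(self.data) & (self.data != self.nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (plain text, portable, diff-able)."""
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xll!r}\n"
        f"yllcorner {raster.yll!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    body = np.where(np.isfinite(raster.data), raster.data, raster.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"grid body shape {data.shape} disagrees with header")
    nodata = meta.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data=data,
        xll=meta["xllcorner"],
        yll=meta["yllcorner"],
        cellsize=meta["cellsize"],
        nodata=nodata,
    )
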