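"""Regular-grid rasters with ESRI ASCII grid text I/O.

Row 0 of ``values`` is the northernmost row (the ASCII-grid convention).
Cells are attributed by their center value; queries use half-open cell
membership so every point strictly inside the extent maps to one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AsciiGrid"]


@dataclass
class AsciiGrid:
    values: np.ndarray  # (nrows, ncols); row 0 = top (north)
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded extent."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def mask_valid(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values != self.nodata)

    def finite_values(self) -> np.ndarray:
        return self.values[self.mask_valid()]

    def cell_index(self, x, y):
        """Row/col of the cell containing each point (arrays ok).

        Points on the top or right edge of the extent are clamped into the
        last cell so the closed extent is fully covered.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cellsize).astype(int)
        col = np.clip(col, 0, self.ncols - 1)
        row_from_bottom = np.clip(row_from_bottom, 0, self.nrows - 1)
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def value_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates, shapes (nrows,) y descending and (ncols,) x."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return xs, ys

    def write(self, path: str | Path) -> None:
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll!r}\n"
            f"yllcorner {self.yll!r}\n"
            f"cellsize {self.cellsize!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        out = np.where(np.isfinite(self.values), self.values, self.nodata)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "AsciiGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                line = fh.readline()
                key, _, val = line.partition(" ")
                key = key.strip().lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value"}:
                    meta[key] = float(val)
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            values = np.loadtxt(fh, ndmin=2)
        nodata = meta.get("nodata_value", -9999.0)
        values = np.where(values == nodata, np.nan, values)
        grid = cls(
            values=values,
            xll=meta["xllcorner"],
            yll=meta["yllcorner"],
            cellsize=meta["cellsize"],
            nodata=nodata,
        )
        if grid.nrows != int(meta["nrows"]) or grid.ncols != int(meta["ncols"]):
            raise ValueError("ASCII grid header does not match data shape")
        return grid
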