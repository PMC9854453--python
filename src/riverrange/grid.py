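"""Aligned single-variable raster grids on a planar projected coordinate system.

Conventions
-----------
* Values are stored row-major with row 0 at the *lower-left* origin, so
  ``values[r, c]`` has its cell centre at ``origin + ((c + 0.5) * cell,
  (r + 0.5) * cell)``.
* Point-in-cell membership uses half-open intervals ``[x0, x0 + cell)``.
* Grids are serialized as ESRI ASCII grids (plain text, widely readable);
  GeoTIFF export is available when :mod:`tifffile` is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "GridAlignmentError"]

DEFAULT_NODATA = -9999.0


class GridAlignmentError(ValueError):
    """Raised when an operation receives grids that do not share geometry."""


@dataclass
class Grid:
    """A georeferenced 2-D raster of one variable.

    Parameters
    ----------
    values
        2-D array of cell values, row 0 at the bottom (lower-left origin).
    cell_size_m
        Edge length of the square cells, in metres.
    origin_xy
        Projected coordinates (metres) of the lower-left corner of the grid.
    nodata
        Sentinel value marking cells outside the analysis region.
    """

    values: np.ndarray
    cell_size_m: float = 1000.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size_m > 0:
            raise ValueError(f"cell_size_m must be positive, got {self.cell_size_m}")
        self.origin_xy = (float(self.origin_xy[0]), float(self.origin_xy[1]))
        if np.issubdtype(self.values.dtype, np.floating):
            bad = ~np.isfinite(self.values) & ~self.nodata_mask()
            if bad.any():
                raise ValueError("grid contains non-finite values that are not nodata")

    # -- geometry -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.values.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin_xy, other.origin_xy)
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} are misaligned: {self.shape}@{self.origin_xy}/"
                f"{self.cell_size_m} vs {other.shape}@{other.origin_xy}/"
                f"{other.cell_size_m}"
            )

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of nodata cells (NaN always counts as nodata)."""
        vals = self.values
        mask = vals == self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask = mask | np.isnan(vals)
        return mask

    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask()

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the half-open cell containing the point.

        Raises :class:`ValueError` for points outside the grid extent.
        """
        x0, y0 = self.origin_xy
        col = int(np.floor((x - x0) / self.cell_size_m))
        row = int(np.floor((y - y0) / self.cell_size_m))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def cells_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`cell_of`; out-of-grid points get index -1."""
        x0, y0 = self.origin_xy
        col = np.floor((np.asarray(x, float) - x0) / self.cell_size_m).astype(int)
        row = np.floor((np.asarray(y, float) - y0) / self.cell_size_m).astype(int)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        row[bad] = -1
        col[bad] = -1
        return row, col

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        x0, y0 = self.origin_xy
        return (
            x0 + (np.asarray(col) + 0.5) * self.cell_size_m,
            y0 + (np.asarray(row) + 0.5) * self.cell_size_m,
        )

    # -- construction helpers ----------------------------------------------

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new grid sharing this grid's geometry with different values."""
        return replace(
            self,
            values=np.asarray(values),
            nodata=self.nodata if nodata is None else nodata,
        )

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    # -- I/O ----------------------------------------------------------------

    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (rows top-down, as the format requires)."""
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin_xy[0]:.6f}\n"
            f"yllcorner {self.origin_xy[1]:.6f}\n"
            f"cellsize {self.cell_size_m:.6f}\n"
            f"NODATA_value {self.nodata}\n"
        )
        vals = np.flipud(np.where(self.nodata_mask(), self.nodata, self.values))
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def from_ascii(cls, path) -> "Grid":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                line = fh.readline()
                parts = line.split()
                if len(parts) != 2 or not _is_number(parts[1]):
                    fh.seek(pos)
                    break
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            values = np.loadtxt(fh, ndmin=2)
        grid = cls(
            values=np.flipud(values),
            cell_size_m=header.get("cellsize", 1.0),
            origin_xy=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
            nodata=header.get("nodata_value", DEFAULT_NODATA),
        )
        return grid

    def to_geotiff(self, path) -> None:
        """Write a single-band GeoTIFF with geo tags (requires tifffile)."""
        import tifffile

        vals = np.flipud(np.asarray(self.values, dtype=np.float32))
        x0, y0 = self.origin_xy
        top = y0 + self.n_rows * self.cell_size_m
        tifffile.imwrite(
            path,
            vals,
            extratags=[
                # ModelPixelScaleTag, ModelTiepointTag, GDAL_NODATA
                (33550, "d", 3, (self.cell_size_m, self.cell_size_m, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, x0, top, 0.0)),
                (42113, "s", 0, str(self.nodata)),
            ],
        )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
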