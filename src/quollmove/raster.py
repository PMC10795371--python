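"""Plain-text raster grids with half-open cell lookup.

A :class:`RasterGrid` stores a row-major matrix anchored at a top-left
corner in projected planar metres.  A cell's value applies to the whole
cell; a point on a shared edge belongs to the cell to the right / below,
so lookups are deterministic at patch boundaries.

The on-disk format is a small self-describing text dialect (``QGRID``)
so that tests and pipelines never need geospatial binaries::

    QGRID 1
    name habitat
    origin_x 0.0
    origin_y 4000.0
    cell_size 10.0
    n_rows 400
    n_cols 400
    nodata -9999.0
    <n_rows whitespace-separated data rows>
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "RasterFormatError"]


class RasterFormatError(ValueError):
    """Raised when a grid file or matrix is malformed."""


@dataclass
class RasterGrid:
    """A single raster layer in projected planar metres.

    ``origin_x, origin_y`` locate the *top-left corner* of the grid; row
    indices increase southwards (decreasing y), column indices eastwards.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterFormatError("values must be a 2-D matrix")
        if self.cell_size <= 0:
            raise RasterFormatError("cell_size must be > 0")

    # -- geometry -----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_size

    def cell_of(self, x, y):
        """Row/col indices of the cells containing points ``(x, y)``.

        Half-open cells: a point on a vertical shared edge belongs to the
        cell on the right, a point on a horizontal edge to the cell below.
        Out-of-bounds points get index -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def value_at(self, x, y):
        """Cell value(s) at point(s); out-of-bounds points get ``nodata``."""
        row, col = self.cell_of(x, y)
        out = np.where(
            (row < 0) | (col < 0),
            self.nodata,
            self.values[np.clip(row, 0, self.n_rows - 1), np.clip(col, 0, self.n_cols - 1)],
        )
        return out if out.ndim else float(out)

    def in_bounds(self, x, y):
        row, col = self.cell_of(x, y)
        return (row >= 0) & (col >= 0)

    def cell_centres(self):
        """(x, y) coordinate arrays of every cell centre (2-D, row-major)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    # -- I/O ----------------------------------------------------------
    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("QGRID 1\n")
            fh.write(f"name {self.name}\n")
            fh.write(f"origin_x {self.origin_x!r}\n")
            fh.write(f"origin_y {self.origin_y!r}\n")
            fh.write(f"cell_size {self.cell_size!r}\n")
            fh.write(f"n_rows {self.n_rows}\n")
            fh.write(f"n_cols {self.n_cols}\n")
            fh.write(f"nodata {self.nodata!r}\n")
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def read(cls, path) -> "RasterGrid":
        with open(path) as fh:
            magic = fh.readline().split()
            if not magic or magic[0] != "QGRID":
                raise RasterFormatError(f"{path}: not a QGRID file")
            header: dict = {}
            for _ in range(7):
                key, _, val = fh.readline().partition(" ")
                header[key.strip()] = val.strip()
            try:
                values = np.loadtxt(fh, ndmin=2)
            except Exception as exc:  # pragma: no cover - loadtxt message varies
                raise RasterFormatError(f"{path}: bad data block: {exc}") from exc
        n_rows, n_cols = int(header["n_rows"]), int(header["n_cols"])
        if values.shape != (n_rows, n_cols):
            raise RasterFormatError(
                f"{path}: dimension mismatch, header {n_rows}x{n_cols}, "
                f"data {values.shape[0]}x{values.shape[1]}"
            )
        return cls(
            origin_x=float(header["origin_x"]),
            origin_y=float(header["origin_y"]),
            cell_size=float(header["cell_size"]),
            values=values,
            nodata=float(header["nodata"]),
            name=header.get("name", ""),
        )
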