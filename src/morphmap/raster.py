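"""Categorical raster layer: integer environmental classes on a regular grid.

Emulates an ecosystems/isobioclimate classification: each cell carries an
integer class id.  The grid lives in projected metres; ``grid[iy, ix]``
is indexed from the lower-left origin (iy increases northwards), and a cell
covers the half-open square [x0 + ix*cell, x0 + (ix+1)*cell) x
[y0 + iy*cell, y0 + (iy+1)*cell).  I/O uses the plain-text ESRI ASCII-grid
dialect (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ClassRaster", "read_ascii_grid", "block_downsample", "extract_class"]


@dataclass
class ClassRaster:
    origin_xy: tuple[float, float]  # lower-left corner, metres
    cell_m: float
    grid: np.ndarray  # (nrows, ncols) int; row 0 is the southernmost row
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not self.cell_m > 0:
            raise ValueError("cell_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin_xy
        return (x0, y0, x0 + nx * self.cell_m, y0 + ny * self.cell_m)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin_xy
        return (int(np.floor((y - y0) / self.cell_m)), int(np.floor((x - x0) / self.cell_m)))

    def cell_box(self, iy: int, ix: int) -> tuple[float, float, float, float]:
        x0, y0 = self.origin_xy
        return (
            x0 + ix * self.cell_m,
            y0 + iy * self.cell_m,
            x0 + (ix + 1) * self.cell_m,
            y0 + (iy + 1) * self.cell_m,
        )

    def classes(self) -> np.ndarray:
        """Distinct class ids present, excluding nodata."""
        vals = np.unique(self.grid)
        return vals[vals != self.nodata]

    def write_ascii(self, path: str | Path) -> None:
        ny, nx = self.grid.shape
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"ncols {nx}\n")
            fh.write(f"nrows {ny}\n")
            fh.write(f"xllcorner {self.origin_xy[0]:.6f}\n")
            fh.write(f"yllcorner {self.origin_xy[1]:.6f}\n")
            fh.write(f"cellsize {self.cell_m:.6f}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            for row in self.grid[::-1]:  # ASCII grid stores the north row first
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> ClassRaster:
    """Read an ESRI ASCII grid of integer classes."""
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {req}")
    grid = np.array(rows, dtype=int)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header")
    return ClassRaster(
        origin_xy=(header["xllcorner"], header["yllcorner"]),
        cell_m=header["cellsize"],
        grid=grid[::-1],  # store south row first
        nodata=int(header.get("nodata_value", -9999)),
    )


def block_downsample(raster: ClassRaster, block_m: float = 20_000.0) -> ClassRaster:
    """Majority-class block statistics at coarser resolution.

    Each output cell takes the most frequent class among the input cells of
    its block; ties resolve to the smallest class id.  Nodata cells are
    ignored unless the whole block is nodata.  ``block_m`` must be an
    integer multiple of the input cell size; partial edge blocks use
    whatever cells they cover.
    """
    ratio = block_m / raster.cell_m
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError("block_m must be a positive integer multiple of cell_m")
    r = int(round(ratio))
    if r == 1:
        return ClassRaster(raster.origin_xy, raster.cell_m, raster.grid.copy(), raster.nodata)
    ny, nx = raster.grid.shape
    out_ny, out_nx = -(-ny // r), -(-nx // r)
    # tally class counts per block via a flat bincount; argmax over ascending
    # class ids resolves ties to the smallest id
    ids = np.unique(raster.grid)
    ids = ids[ids != raster.nodata]
    out = np.full((out_ny, out_nx), raster.nodata, dtype=int)
    if ids.size:
        class_idx = np.searchsorted(ids, raster.grid)
        valid = raster.grid != raster.nodata
        by, bx = np.meshgrid(np.arange(ny) // r, np.arange(nx) // r, indexing="ij")
        block_idx = by * out_nx + bx
        flat = block_idx[valid] * ids.size + class_idx[valid]
        counts = np.bincount(flat, minlength=out_ny * out_nx * ids.size)
        counts = counts.reshape(out_ny * out_nx, ids.size)
        best = ids[np.argmax(counts, axis=1)]
        best[counts.sum(axis=1) == 0] = raster.nodata  # all-nodata blocks
        out = best.reshape(out_ny, out_nx)
    return ClassRaster(raster.origin_xy, block_m, out, raster.nodata)


def extract_class(raster: ClassRaster, x: float, y: float) -> int:
    """Class id of the cell containing a point (half-open cell convention).

    A point exactly on a shared cell edge belongs to the cell on the
    greater side.  Outside the raster extent returns nodata with a warning.
    """
    iy, ix = raster.cell_index(x, y)
    ny, nx = raster.grid.shape
    if not (0 <= iy < ny and 0 <= ix < nx):
        warnings.warn(f"point ({x:.0f}, {y:.0f}) outside raster extent", stacklevel=2)
        return raster.nodata
    return int(raster.grid[iy, ix])


def extract_classes(raster: ClassRaster, xy: np.ndarray) -> np.ndarray:
    """Vectorised :func:`extract_class` for an (n, 2) point array."""
    xy = np.asarray(xy, dtype=float)
    x0, y0 = raster.origin_xy
    ix = np.floor((xy[:, 0] - x0) / raster.cell_m).astype(int)
    iy = np.floor((xy[:, 1] - y0) / raster.cell_m).astype(int)
    ny, nx = raster.grid.shape
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    if not np.all(inside):
        warnings.warn(f"{int((~inside).sum())} point(s) outside raster extent", stacklevel=2)
    out = np.full(len(xy), raster.nodata, dtype=int)
    out[inside] = raster.grid[iy[inside], ix[inside]]
    return out
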