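"""Plain-text readers and writers for masks, density states and parcels.

Two dialects for the river mask: a CSV of ``row,col`` river cells and a
0/1 ASCII raster (one grid row per line, space-separated). Density states
travel as ``row,col,omega`` CSV at full precision or as a dense raster
text grid. All formats are plain text so runs are diffable and portable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GeometryError, GridSpec


def write_mask_csv(mask: np.ndarray, path: str | Path) -> None:
    cells = np.argwhere(np.asarray(mask, dtype=bool))
    pd.DataFrame(cells, columns=["row", "col"]).to_csv(path, index=False)


def read_mask_csv(path: str | Path, grid: GridSpec) -> np.ndarray:
    df = pd.read_csv(path)
    mask = np.zeros(grid.shape, dtype=bool)
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    if (rows < 0).any() or (rows >= grid.n_rows).any() or (cols < 0).any() or (
        cols >= grid.n_cols
    ).any():
        raise GeometryError(f"mask CSV {path} contains cells outside the grid")
    mask[rows, cols] = True
    return mask


def write_mask_raster(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def read_mask_raster(path: str | Path, grid: GridSpec | None = None) -> np.ndarray:
    arr = np.loadtxt(path, dtype=int)
    arr = np.atleast_2d(arr)
    if grid is not None and arr.shape != grid.shape:
        raise GeometryError(
            f"raster shape {arr.shape} does not match grid shape {grid.shape}"
        )
    return arr.astype(bool)


def write_state_csv(cells: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    """Write (row, col, omega) rows at full float precision."""
    df = pd.DataFrame(
        {"row": cells[:, 0], "col": cells[:, 1], "omega": values}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_state_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    cells = df[["row", "col"]].to_numpy(dtype=np.int64)
    return cells, df["omega"].to_numpy(dtype=float)


def write_state_raster(grid_values: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, grid_values, fmt="%.17g")


def read_state_raster(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, dtype=float))


def read_parcels_csv(path: str | Path, grid: GridSpec | None = None) -> list[tuple[int, int]]:
    """Read parcels as grid cells. Columns ``row,col``; or ``easting,northing``
    when ``grid`` carries a UTM anchor."""
    from .geometry import utm_to_grid

    df = pd.read_csv(path)
    if {"row", "col"} <= set(df.columns):
        return [(int(r), int(c)) for r, c in df[["row", "col"]].to_numpy()]
    if {"easting", "northing"} <= set(df.columns):
        if grid is None or grid.utm_anchor is None:
            raise GeometryError("parcels given in UTM but grid has no anchor")
        return [
            utm_to_grid(e, n, grid)
            for e, n in df[["easting", "northing"]].to_numpy(dtype=float)
        ]
    raise GeometryError(
        f"parcel file {path} needs columns row,col or easting,northing"
    )
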