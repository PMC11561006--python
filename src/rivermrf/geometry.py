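"""Lattice geometry: grid definition, river mask, region labeling, distances.

The study area is a rectangular grid of square cells. A river mask marks
the cells touching the river; the remaining cells decompose into
4-connected off-river regions that the conditioned Gibbs measure treats
independently. Each off-river cell also carries a taxicab-style distance
to the river, split into a horizontal and a vertical component, which
feeds the quadratic potential well.

Coordinates are 0-based ``(row, col)`` with row 0 at the north (top) edge
and col 0 at the west (left) edge.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

RIVER = 0
"""Label value reserved for river cells in :class:`GeometryLabels`."""

#: 4-connectivity structuring element (von Neumann neighborhood).
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class GeometryError(ValueError):
    """Raised for invalid geometric inputs (dimension mismatch, no river...)."""


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice of square cells, optionally anchored in UTM.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (rows run north to south, columns west to east).
    cell_size_m
        Side length of a cell in meters.
    utm_anchor
        Optional pair of diagonal corner coordinates
        ``((easting_min, northing_min), (easting_max, northing_max))`` in
        meters, enabling UTM <-> grid-index conversion.
    """

    n_rows: int
    n_cols: int
    cell_size_m: float = 5.0
    utm_anchor: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have at least one row and column")
        if self.cell_size_m <= 0:
            raise GeometryError("cell_size_m must be positive")
        if self.utm_anchor is not None:
            (e0, n0), (e1, n1) = self.utm_anchor
            if e1 <= e0 or n1 <= n0:
                raise GeometryError(
                    "utm_anchor corners must be (min, min), (max, max) diagonal"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols


def neighbors(cell: tuple[int, int], shape: tuple[int, int]) -> list[tuple[int, int]]:
    """First-order (von Neumann) neighbors of ``cell``, truncated to the grid.

    Every interior cell has 4 neighbors; edge cells 3; corner cells 2.
    """
    r, c = cell
    out = []
    for rr, cc in ((r, c - 1), (r + 1, c), (r, c + 1), (r - 1, c)):
        if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
            out.append((rr, cc))
    return out


@dataclass
class GeometryLabels:
    """Per-cell classification into the river and numbered off-river regions.

    ``labels[r, c]`` is :data:`RIVER` (0) on river cells and a region id in
    ``1..k`` elsewhere. Regions are maximal 4-connected components of
    non-river cells, numbered by descending size (ties broken by the
    smallest row-major first cell), so "region 1" is stable across runs.
    """

    labels: np.ndarray
    region_sizes: list[int] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_regions(self) -> int:
        return len(self.region_sizes)

    @property
    def river_mask(self) -> np.ndarray:
        return self.labels == RIVER

    @property
    def river_cells(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in np.argwhere(self.labels == RIVER)}

    def region_mask(self, region_id: int) -> np.ndarray:
        if not 1 <= region_id <= self.n_regions:
            raise GeometryError(f"region {region_id} does not exist (k={self.n_regions})")
        return self.labels == region_id

    def region_cells(self, region_id: int | None) -> np.ndarray:
        """Cells of one region (or of all off-river cells when ``None``),
        as an ``(m, 2)`` int array in row-major order."""
        mask = (self.labels != RIVER) if region_id is None else self.region_mask(region_id)
        return np.argwhere(mask)


def label_regions(river_mask: np.ndarray, grid: GridSpec) -> GeometryLabels:
    """Decompose the off-river cells into 4-connected regions.

    Parameters
    ----------
    river_mask
        Boolean grid, True on river cells. Must match ``grid.shape``.

    Returns
    -------
    GeometryLabels with regions numbered deterministically
    (descending size, ties by smallest row-major first cell).
    """
    river_mask = np.asarray(river_mask, dtype=bool)
    if river_mask.shape != grid.shape:
        raise GeometryError(
            f"river mask shape {river_mask.shape} != grid shape {grid.shape}"
        )
    raw, k = ndimage.label(~river_mask, structure=_STRUCTURE_4)
    if k == 0:
        return GeometryLabels(labels=np.zeros(grid.shape, dtype=np.int32))

    sizes = ndimage.sum_labels(np.ones(grid.shape), raw, index=range(1, k + 1))
    # first row-major flat index of each raw component, for deterministic ties
    flat = raw.ravel()
    first_idx = np.full(k + 1, flat.size, dtype=np.int64)
    for pos, lab in enumerate(flat):
        if lab and first_idx[lab] == flat.size:
            first_idx[lab] = pos
    order = sorted(range(1, k + 1), key=lambda lab: (-sizes[lab - 1], first_idx[lab]))
    remap = np.zeros(k + 1, dtype=np.int32)
    for new_id, old in enumerate(order, start=1):
        remap[old] = new_id
    labels = remap[raw]
    region_sizes = [int(sizes[old - 1]) for old in order]
    return GeometryLabels(labels=labels, region_sizes=region_sizes)


@dataclass
class DistanceField:
    """Distance of every cell to the river, in cell units.

    ``d = m_horiz + a_vert`` where ``m_horiz`` is the minimal absolute
    column offset to any river cell, and ``a_vert`` is the absolute row
    offset to a river cell achieving that column minimum (smallest such
    offset). The decomposition mirrors how the attraction well penalizes
    horizontal excursions from the river first. River cells have d = 0.
    """

    d: np.ndarray
    m_horiz: np.ndarray
    a_vert: np.ndarray


def distance_field(labels: GeometryLabels) -> DistanceField:
    """Compute the horizontal+vertical distance field for all cells.

    Requires at least one river cell (otherwise the potential well is
    undefined). Ties in the minimal column offset are broken by the
    smallest row offset; the result ``d`` does not depend on further
    tie-breaking because only the offsets enter it.
    """
    mask = labels.river_mask
    if not mask.any():
        raise GeometryError("distance field requires at least one river cell")
    n_rows, n_cols = mask.shape

    rows_by_col: list[list[int]] = [
        sorted(np.nonzero(mask[:, c])[0].tolist()) for c in range(n_cols)
    ]
    river_cols = [c for c in range(n_cols) if rows_by_col[c]]

    def nearest_row_offset(col: int, row: int) -> int:
        rows = rows_by_col[col]
        i = bisect_left(rows, row)
        best = n_rows
        if i < len(rows):
            best = rows[i] - row
        if i > 0:
            best = min(best, row - rows[i - 1])
        return best

    m_h = np.zeros(mask.shape, dtype=np.int64)
    a_v = np.zeros(mask.shape, dtype=np.int64)
    i_sorted = river_cols  # already ascending
    for r in range(n_rows):
        for c in range(n_cols):
            if mask[r, c]:
                continue
            j = bisect_left(i_sorted, c)
            best_m = n_cols
            cand = []
            if j < len(i_sorted):
                cand.append(i_sorted[j])
            if j > 0:
                cand.append(i_sorted[j - 1])
            best_m = min(abs(cc - c) for cc in cand)
            a = min(
                nearest_row_offset(cc, r) for cc in cand if abs(cc - c) == best_m
            )
            m_h[r, c] = best_m
            a_v[r, c] = a
    return DistanceField(d=m_h + a_v, m_horiz=m_h, a_vert=a_v)


@dataclass(frozen=True)
class ParcelSet:
    """Off-river survey parcels and their pooled field counts.

    ``total_year_count`` is the number of individuals recorded in the
    parcels over the whole year; ``n_trips`` the number of field trips,
    so the target year-average expectation is ``total / n_trips``.
    """

    parcels: tuple[tuple[int, int], ...]
    total_year_count: int = 0
    n_trips: int = 10

    def __post_init__(self) -> None:
        if len(set(self.parcels)) != len(self.parcels):
            raise GeometryError("parcel cells must be pairwise distinct")
        if self.total_year_count < 0:
            raise GeometryError("total_year_count must be nonnegative")
        if self.n_trips < 1:
            raise GeometryError("n_trips must be positive")

    @property
    def target_expectation(self) -> float:
        """Year-average number of individuals expected over the parcels."""
        return self.total_year_count / self.n_trips

    def common_region(self, labels: GeometryLabels) -> int:
        """The single region containing every parcel; error otherwise."""
        ids = {int(labels.labels[r, c]) for r, c in self.parcels}
        if len(ids) != 1 or RIVER in ids:
            raise GeometryError(
                f"parcels must lie in exactly one off-river region, got labels {ids}"
            )
        return ids.pop()


def utm_to_grid(easting: float, northing: float, grid: GridSpec) -> tuple[int, int]:
    """Convert a UTM point to the (row, col) of the containing cell.

    Rows count down from the northern edge, columns up from the western
    edge; offsets are divided by the cell size and rounded to the nearest
    integer.
    """
    if grid.utm_anchor is None:
        raise GeometryError("grid has no utm_anchor; conversion undefined")
    (e_min, n_min), (e_max, n_max) = grid.utm_anchor
    if not (e_min <= easting <= e_max and n_min <= northing <= n_max):
        raise GeometryError(
            f"point ({easting}, {northing}) outside anchored rectangle "
            f"[{e_min}, {e_max}] x [{n_min}, {n_max}]"
        )
    row = round((n_max - northing) / grid.cell_size_m)
    col = round((easting - e_min) / grid.cell_size_m)
    return int(row), int(col)


def grid_to_utm(row: int, col: int, grid: GridSpec) -> tuple[float, float]:
    """Approximate inverse of :func:`utm_to_grid` (cell-center anchored)."""
    if grid.utm_anchor is None:
        raise GeometryError("grid has no utm_anchor; conversion undefined")
    (e_min, _), (_, n_max) = grid.utm_anchor
    return (e_min + col * grid.cell_size_m, n_max - row * grid.cell_size_m)


@dataclass
class GeometryReport:
    """Result of :func:`validate_geometry`: pass/fail plus offending cells."""

    passed: bool
    issues: list[str] = field(default_factory=list)
    offending_cells: list[tuple[int, int]] = field(default_factory=list)


def validate_geometry(labels: GeometryLabels) -> GeometryReport:
    """Check the labeling invariants: complete partition, consistent sizes,
    4-connected regions, and no adjacency between distinct regions."""
    issues: list[str] = []
    offending: list[tuple[int, int]] = []
    arr = labels.labels
    k = labels.n_regions

    bad = np.argwhere((arr < 0) | (arr > k))
    if bad.size:
        issues.append(f"{len(bad)} cell(s) carry labels outside 0..{k}")
        offending.extend((int(r), int(c)) for r, c in bad)

    for i in range(1, k + 1):
        size = int((arr == i).sum())
        if size != labels.region_sizes[i - 1]:
            issues.append(
                f"region {i}: recorded size {labels.region_sizes[i - 1]} != actual {size}"
            )
        if size == 0:
            continue
        comp, n_comp = ndimage.label(arr == i, structure=_STRUCTURE_4)
        if n_comp != 1:
            issues.append(f"region {i} is not 4-connected ({n_comp} components)")
            offending.extend(
                (int(r), int(c)) for r, c in np.argwhere(comp > 1)
            )

    # cross-region adjacency
    for axis in (0, 1):
        a = arr.take(range(arr.shape[axis] - 1), axis=axis)
        b = arr.take(range(1, arr.shape[axis]), axis=axis)
        clash = (a != b) & (a != RIVER) & (b != RIVER)
        for r, c in np.argwhere(clash):
            pair = (int(r), int(c))
            nbr = (r + 1, c) if axis == 0 else (r, c + 1)
            issues.append(f"cells {pair} and {(int(nbr[0]), int(nbr[1]))} are adjacent but in different regions")
            offending.extend([pair, (int(nbr[0]), int(nbr[1]))])

    return GeometryReport(passed=not issues, issues=issues, offending_cells=offending)
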