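"""Hamiltonians of the river-conditioned Gibbs measure.

The model places a year-average density ``omega in [0, K]`` on every
off-river cell. Its energy has two parts:

* a free (spreading) term ``H0 = sum over neighbor pairs (w_t1 - w_t2)^2``,
  including pairs with fixed river boundary values, minimized by the
  constant state — it makes density diffuse;
* a potential well ``V_g = g * sum_t d_t^2 * w_t`` penalizing density far
  from the river — it pulls individuals toward the water.

The Gibbs measure is ``pi(omega) ∝ exp(-H(omega)/T)``. The partition
constant is never materialized: sampling and comparison only ever need
energy differences, which :func:`delta_energy` computes from a single
cell's local terms.

Because river cells carry fixed boundary values and cells of different
off-river regions are never neighbors, the total energy over all
off-river cells splits exactly into per-region energies — the regions are
probabilistically independent and can be simulated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RIVER, DistanceField, GeometryError, GeometryLabels


class EnergyError(ValueError):
    """Invalid energy input (domain mismatch, out-of-range value...)."""


@dataclass
class ModelParams:
    """Model parameters: density cap K, river-attraction coupling g,
    temperature T (concentration parameter of the Gibbs measure)."""

    K: float
    g: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise EnergyError("K must be positive")
        if self.g < 0:
            raise EnergyError("g must be nonnegative")
        if self.T <= 0:
            raise EnergyError("T must be positive")


@dataclass
class BoundaryCondition:
    """Fixed densities on river cells conditioning the Gibbs measure.

    ``values`` is a full-grid array whose entries are meaningful only on
    river cells. In the case study the boundary is the constant K: the
    density is assumed maximal on the river.
    """

    values: np.ndarray

    @classmethod
    def constant(cls, value: float, labels: GeometryLabels) -> "BoundaryCondition":
        return cls(values=np.full(labels.shape, float(value)))

    def validate(self, labels: GeometryLabels, K: float) -> None:
        river = labels.river_mask
        v = self.values[river]
        if (v < 0).any() or (v > K).any():
            raise EnergyError("boundary values must lie in [0, K]")


@dataclass
class DensityState:
    """Density field on the cells of one region (or all off-river cells).

    ``cells`` is an ``(m, 2)`` int array in row-major order and ``values``
    the matching densities. ``region_id`` is the region the state lives
    on, or ``None`` for the union of all off-river cells.
    """

    cells: np.ndarray
    values: np.ndarray
    region_id: int | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.cells.shape != (self.values.size, 2):
            raise EnergyError("cells and values sizes disagree")

    @classmethod
    def constant(
        cls, labels: GeometryLabels, region_id: int | None, value: float
    ) -> "DensityState":
        cells = labels.region_cells(region_id)
        return cls(cells=cells, values=np.full(len(cells), float(value)), region_id=region_id)

    @classmethod
    def zeros(cls, labels: GeometryLabels, region_id: int | None) -> "DensityState":
        return cls.constant(labels, region_id, 0.0)

    @property
    def n_cells(self) -> int:
        return self.values.size

    def index_of(self, cell: tuple[int, int]) -> int:
        if not self._index:
            self._index.update(
                {(int(r), int(c)): i for i, (r, c) in enumerate(self.cells)}
            )
        try:
            return self._index[(int(cell[0]), int(cell[1]))]
        except KeyError:
            raise EnergyError(f"cell {tuple(cell)} not in state's domain") from None

    def value_at(self, cell: tuple[int, int]) -> float:
        return float(self.values[self.index_of(cell)])

    def to_grid(self, shape: tuple[int, int], fill: float = np.nan) -> np.ndarray:
        out = np.full(shape, fill, dtype=float)
        out[self.cells[:, 0], self.cells[:, 1]] = self.values
        return out

    def copy(self) -> "DensityState":
        return DensityState(
            cells=self.cells.copy(), values=self.values.copy(), region_id=self.region_id
        )


def _check_domain(
    state: DensityState, labels: GeometryLabels, region_id: int | None
) -> None:
    expected = labels.region_cells(region_id)

    def _sorted_flat(cells: np.ndarray, n_cols: int) -> np.ndarray:
        return np.sort(cells[:, 0] * n_cols + cells[:, 1])

    if state.cells.shape != expected.shape or not np.array_equal(
        _sorted_flat(state.cells, labels.shape[1]),
        _sorted_flat(expected, labels.shape[1]),
    ):
        raise EnergyError(
            f"state domain does not match region {region_id!r} of the geometry"
        )


def free_energy(
    state: DensityState,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    region_id: int | None = None,
) -> float:
    """Spreading energy with river boundary terms.

    Each unordered pair of neighboring domain cells contributes
    ``(w1 - w2)^2`` once; each (domain cell, adjacent river cell)
    incidence contributes ``(w - boundary)^2`` — a cell flanked by the
    river on two sides contributes two boundary terms.
    """
    _check_domain(state, labels, region_id)
    shape = labels.shape
    grid = state.to_grid(shape, fill=np.nan)
    total = 0.0
    # interior pairs, counted once via right/down shifts
    for a, b in (
        (grid[:, :-1], grid[:, 1:]),
        (grid[:-1, :], grid[1:, :]),
    ):
        both = np.isfinite(a) & np.isfinite(b)
        diff = a[both] - b[both]
        total += float(np.sum(diff * diff))
    # boundary incidences: domain cell next to a river cell, all 4 directions
    river = labels.river_mask
    in_dom = np.isfinite(grid)
    bv = boundary.values
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        t_sl = (
            slice(max(0, -dr), shape[0] - max(0, dr)),
            slice(max(0, -dc), shape[1] - max(0, dc)),
        )
        s_sl = (
            slice(max(0, dr), shape[0] - max(0, -dr)),
            slice(max(0, dc), shape[1] - max(0, -dc)),
        )
        pair = in_dom[t_sl] & river[s_sl]
        diff = grid[t_sl][pair] - bv[s_sl][pair]
        total += float(np.sum(diff * diff))
    return total


def potential_energy(state: DensityState, dist: DistanceField, g: float) -> float:
    """Attraction well ``g * sum_t d_t^2 * w_t`` over the state's domain."""
    if g < 0:
        raise EnergyError("g must be nonnegative")
    d = dist.d[state.cells[:, 0], state.cells[:, 1]].astype(float)
    return float(g * np.sum(d * d * state.values))


def total_energy(
    state: DensityState,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    params: ModelParams,
) -> float:
    """Full Hamiltonian ``H = H0 + V_g``."""
    return free_energy(state, labels, boundary, state.region_id) + potential_energy(
        state, dist, params.g
    )


def delta_energy(
    state: DensityState,
    cell: tuple[int, int],
    new_value: float,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    params: ModelParams,
) -> float:
    """Energy change from setting one cell to ``new_value``.

    Only the cell's <=4 neighbor terms and its own potential term move, so
    the difference is O(1) — this is what makes single-site Metropolis
    steps cheap.
    """
    if not (0.0 <= new_value <= params.K):
        raise EnergyError(f"new_value {new_value} outside [0, {params.K}]")
    i = state.index_of(cell)
    a = float(state.values[i])
    x = float(new_value)
    r, c = int(cell[0]), int(cell[1])
    d = float(dist.d[r, c])
    dh = params.g * d * d * (x - a)
    arr = labels.labels
    for rr, cc in ((r, c - 1), (r + 1, c), (r, c + 1), (r - 1, c)):
        if not (0 <= rr < arr.shape[0] and 0 <= cc < arr.shape[1]):
            continue
        lab = arr[rr, cc]
        if lab == RIVER:
            w = float(boundary.values[rr, cc])
        else:
            if state.region_id is not None and lab != state.region_id:
                continue  # unreachable for valid geometry; defensive
            w = state.value_at((rr, cc))
        dh += (x - w) ** 2 - (a - w) ** 2
    return dh


def log_unnorm_density(
    state: DensityState,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    params: ModelParams,
) -> float:
    """Log of the unnormalized Gibbs density, ``-H/T``.

    The normalization Z cancels in every ratio the samplers use, so it is
    never computed.
    """
    return -total_energy(state, labels, boundary, dist, params) / params.T


def merge_states(states: list[DensityState]) -> DensityState:
    """Combine per-region states into one state on the union of their cells,
    in row-major order."""
    cells = np.concatenate([s.cells for s in states])
    values = np.concatenate([s.values for s in states])
    order = np.lexsort((cells[:, 1], cells[:, 0]))
    return DensityState(cells=cells[order], values=values[order], region_id=None)
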