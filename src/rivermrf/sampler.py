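"""Layered cell ordering and single-site Metropolis sampling.

Each off-river region is swept in a fixed periodic order that starts at
the cells touching the river and moves outward breadth-first: layer 0 is
every region cell adjacent to the river, layer l+1 the unvisited
neighbors of earlier layers. Sweeping river-first lets the boundary
information propagate into the region quickly, which is what makes the
energy descend fast even at low temperature with a single temperature
drop instead of a slow annealing schedule.

One *sweep* visits every cell of the region once (the region size in
single-site proposals). At each visit a replacement value is drawn
uniformly on [0, K]; it is accepted outright if it lowers the energy and
with probability ``exp(-dH/T)`` otherwise. The chain therefore never
leaves ``[0, K]^region``. Per-sweep energies are recorded and the
year-average density estimate is the running mean of the end-of-sweep
states over the last ``tail_sweeps`` sweeps.

The inner loop is JIT-compiled (numba); the RNG is numba's seeded global
stream, consumed in a fixed documented order (proposal first, acceptance
uniform only when the energy did not decrease), so runs are bit-for-bit
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .energy import BoundaryCondition, DensityState, EnergyError, ModelParams
from .geometry import RIVER, DistanceField, GeometryError, GeometryLabels


@dataclass
class CellOrdering:
    """Periodic visit order for one region's cells.

    ``sequence`` lists each region cell exactly once (one period);
    ``layer_index`` gives each cell's breadth-first distance layer from
    the river. Cells appear in non-decreasing layer order, row-major
    within a layer.
    """

    region_id: int
    sequence: np.ndarray  # (m, 2) int
    layer_index: np.ndarray  # (m,) int

    @property
    def n_cells(self) -> int:
        return len(self.sequence)


def make_ordering(labels: GeometryLabels, region_id: int) -> CellOrdering:
    """Deterministic river-outward BFS ordering of a region's cells."""
    region = labels.region_mask(region_id)
    river = labels.river_mask
    shape = labels.shape

    def river_adjacent(r: int, c: int) -> bool:
        for rr, cc in ((r, c - 1), (r + 1, c), (r, c + 1), (r - 1, c)):
            if 0 <= rr < shape[0] and 0 <= cc < shape[1] and river[rr, cc]:
                return True
        return False

    frontier = [
        (int(r), int(c)) for r, c in np.argwhere(region) if river_adjacent(r, c)
    ]
    if not frontier:
        raise GeometryError(
            f"region {region_id} has no river-adjacent cell; the boundary-"
            "conditioned model requires one"
        )
    visited = np.zeros(shape, dtype=bool)
    for r, c in frontier:
        visited[r, c] = True
    sequence: list[tuple[int, int]] = []
    layers: list[int] = []
    layer = 0
    while frontier:
        frontier.sort()  # row-major within the layer
        sequence.extend(frontier)
        layers.extend([layer] * len(frontier))
        nxt = []
        for r, c in frontier:
            for rr, cc in ((r, c - 1), (r + 1, c), (r, c + 1), (r - 1, c)):
                if (
                    0 <= rr < shape[0]
                    and 0 <= cc < shape[1]
                    and region[rr, cc]
                    and not visited[rr, cc]
                ):
                    visited[rr, cc] = True
                    nxt.append((rr, cc))
        frontier = nxt
        layer += 1
    if len(sequence) != int(region.sum()):
        raise GeometryError(
            f"region {region_id} ordering covered {len(sequence)} of "
            f"{int(region.sum())} cells; region not river-connected"
        )
    return CellOrdering(
        region_id=region_id,
        sequence=np.array(sequence, dtype=np.int64),
        layer_index=np.array(layers, dtype=np.int64),
    )


@dataclass
class ChainResult:
    """Summary of one Metropolis run on one region."""

    final_state: DensityState
    tail_average: DensityState
    energy_trace: np.ndarray
    acceptance_rate: float
    n_sweeps: int
    tail_sweeps: int
    seed: int
    tail_states: np.ndarray | None = None  # (stored_sweeps, m), ordering order


@njit(cache=True)
def _metropolis_kernel(
    omega,
    nbr_idx,
    nbr_count,
    bnd_count,
    bnd_sum,
    bnd_sumsq,
    d2,
    g,
    T,
    K,
    n_sweeps,
    tail_sweeps,
    seed,
    n_store,
):  # pragma: no cover - exercised via run_chain
    np.random.seed(seed)
    m = omega.size
    energy = np.empty(n_sweeps)
    tail_sum = np.zeros(m)
    stored = np.empty((n_store, m))
    accepted = 0
    for sweep in range(n_sweeps):
        for t in range(m):
            a = omega[t]
            x = np.random.uniform(0.0, K)
            dh = g * d2[t] * (x - a)
            for k in range(nbr_count[t]):
                w = omega[nbr_idx[t, k]]
                dh += (x - w) ** 2 - (a - w) ** 2
            if bnd_count[t] > 0:
                dh += bnd_count[t] * (x * x - a * a) - 2.0 * bnd_sum[t] * (x - a)
            if dh < 0.0:
                omega[t] = x
                accepted += 1
            else:
                y = np.random.random()
                if y <= np.exp(-dh / T):
                    omega[t] = x
                    accepted += 1
        # exact end-of-sweep energy (each unordered pair once via j > t)
        h = 0.0
        for t in range(m):
            w = omega[t]
            h += g * d2[t] * w
            h += bnd_count[t] * w * w - 2.0 * bnd_sum[t] * w + bnd_sumsq[t]
            for k in range(nbr_count[t]):
                j = nbr_idx[t, k]
                if j > t:
                    h += (w - omega[j]) ** 2
        energy[sweep] = h
        if sweep >= n_sweeps - tail_sweeps:
            for t in range(m):
                tail_sum[t] += omega[t]
        if n_store > 0 and sweep >= n_sweeps - n_store:
            idx = sweep - (n_sweeps - n_store)
            for t in range(m):
                stored[idx, t] = omega[t]
    return energy, tail_sum / tail_sweeps, accepted, stored


def _kernel_arrays(
    ordering: CellOrdering,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
):
    """Precompute per-cell neighbor indices and boundary moments in the
    ordering's visit order."""
    m = ordering.n_cells
    shape = labels.shape
    pos = {
        (int(r), int(c)): i for i, (r, c) in enumerate(ordering.sequence)
    }
    nbr_idx = np.full((m, 4), -1, dtype=np.int64)
    nbr_count = np.zeros(m, dtype=np.int64)
    bnd_count = np.zeros(m, dtype=np.float64)
    bnd_sum = np.zeros(m, dtype=np.float64)
    bnd_sumsq = np.zeros(m, dtype=np.float64)
    d2 = np.zeros(m, dtype=np.float64)
    arr = labels.labels
    for i, (r, c) in enumerate(ordering.sequence):
        r, c = int(r), int(c)
        d = float(dist.d[r, c])
        d2[i] = d * d
        for rr, cc in ((r, c - 1), (r + 1, c), (r, c + 1), (r - 1, c)):
            if not (0 <= rr < shape[0] and 0 <= cc < shape[1]):
                continue
            if arr[rr, cc] == RIVER:
                b = float(boundary.values[rr, cc])
                bnd_count[i] += 1.0
                bnd_sum[i] += b
                bnd_sumsq[i] += b * b
            elif (rr, cc) in pos:
                nbr_idx[i, nbr_count[i]] = pos[(rr, cc)]
                nbr_count[i] += 1
    return nbr_idx, nbr_count, bnd_count, bnd_sum, bnd_sumsq, d2


def run_chain(
    initial: DensityState,
    params: ModelParams,
    ordering: CellOrdering,
    n_sweeps: int,
    tail_sweeps: int,
    seed: int,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    store_tail_states: int = 0,
) -> ChainResult:
    """Run the single-site Metropolis chain on one region.

    Parameters
    ----------
    initial
        Starting state on the ordering's region; values must lie in [0, K].
    n_sweeps, tail_sweeps
        Chain length and averaging window, both in sweeps (one sweep =
        one proposal at every region cell, in the layered order).
    store_tail_states
        If > 0, additionally retain the last that many end-of-sweep
        states (columns in ordering order) — used for marginal
        diagnostics on tiny regions; the year-average estimate itself is
        a running mean and never stores the history.
    """
    if n_sweeps < tail_sweeps or tail_sweeps < 1:
        raise EnergyError("need n_sweeps >= tail_sweeps >= 1")
    vals = np.array(
        [initial.value_at((int(r), int(c))) for r, c in ordering.sequence],
        dtype=float,
    )
    if (vals < 0).any() or (vals > params.K).any():
        raise EnergyError("initial state has values outside [0, K]")
    boundary.validate(labels, params.K)
    nbr_idx, nbr_count, bnd_count, bnd_sum, bnd_sumsq, d2 = _kernel_arrays(
        ordering, labels, boundary, dist
    )
    omega = vals.copy()
    energy, tail_vals, accepted, stored = _metropolis_kernel(
        omega,
        nbr_idx,
        nbr_count,
        bnd_count,
        bnd_sum,
        bnd_sumsq,
        d2,
        float(params.g),
        float(params.T),
        float(params.K),
        int(n_sweeps),
        int(tail_sweeps),
        int(seed) & 0x7FFFFFFF,
        int(store_tail_states),
    )

    def _to_state(v: np.ndarray) -> DensityState:
        order = np.lexsort((ordering.sequence[:, 1], ordering.sequence[:, 0]))
        return DensityState(
            cells=ordering.sequence[order],
            values=v[order],
            region_id=ordering.region_id,
        )

    return ChainResult(
        final_state=_to_state(omega),
        tail_average=_to_state(tail_vals),
        energy_trace=energy,
        acceptance_rate=accepted / (n_sweeps * ordering.n_cells),
        n_sweeps=n_sweeps,
        tail_sweeps=tail_sweeps,
        seed=int(seed),
        tail_states=stored if store_tail_states > 0 else None,
    )


def tail_average(chain: ChainResult) -> DensityState:
    """The year-average density estimate: mean of the last ``tail_sweeps``
    end-of-sweep states, accumulated as a running mean during the run."""
    return chain.tail_average


def run_two_stage(
    params_hot: ModelParams,
    params_cold: ModelParams,
    ordering: CellOrdering,
    n_sweeps: int,
    tail_sweeps: int,
    seed: int,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    initial: DensityState | None = None,
) -> tuple[ChainResult, ChainResult]:
    """Two-chain annealing recipe: a chain at the warmer temperature from
    the zero state, then a second chain at the colder temperature started
    from the first chain's tail average. Stage seeds are derived from
    ``seed`` with a splitting sequence."""
    s1, s2 = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2) % (2**31)
    )
    if initial is None:
        initial = DensityState.zeros(labels, ordering.region_id)
    hot = run_chain(
        initial, params_hot, ordering, n_sweeps, tail_sweeps, s1, labels, boundary, dist
    )
    cold = run_chain(
        hot.tail_average,
        params_cold,
        ordering,
        n_sweeps,
        tail_sweeps,
        s2,
        labels,
        boundary,
        dist,
    )
    return hot, cold
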