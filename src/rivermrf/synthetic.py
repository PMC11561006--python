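"""Synthetic river geometries and planted-truth scenarios.

The field study's river raster is not published, so every end-to-end
exercise of the model runs on generated geometries: a 4-connected river
band of configurable width crossing the grid top to bottom (optionally
forking once, which carves an extra wedge region), splitting the lattice
into two or more off-river regions exactly as the real river splits the
study area. The case-study constants (density cap, grid, parcels,
calibrated temperatures and coupling) ship as a reference preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import BoundaryCondition, ModelParams
from .geometry import (
    GeometryError,
    GeometryLabels,
    GridSpec,
    ParcelSet,
    distance_field,
    label_regions,
)
from .sampler import make_ordering, run_two_stage


def vertical_river_mask(rows: int, cols: int, col: int, width: int = 1) -> np.ndarray:
    """Straight vertical river band covering columns [col, col+width)."""
    if not 0 <= col <= cols - width:
        raise GeometryError("river band does not fit in the grid")
    mask = np.zeros((rows, cols), dtype=bool)
    mask[:, col : col + width] = True
    return mask


def make_river(
    rows: int, cols: int, width: int = 1, bifurcate: bool = False, seed: int = 0
) -> np.ndarray:
    """Random 4-connected river band crossing the grid top to bottom.

    The band follows a random lattice path monotone in the row index;
    column shifts insert an elbow cell so 4-connectivity holds at any
    width. Without a fork the band splits the grid into 2 regions; with
    ``bifurcate`` the path forks once below the upper third and the two
    diverging branches enclose a wedge, giving 3 (or, with width > 1
    pinch-offs, up to 4) regions.
    """
    if width < 1:
        raise GeometryError("width must be >= 1")
    if width >= cols - 1 or cols < width + 2 or rows < 2:
        if width >= cols:
            return np.ones((rows, cols), dtype=bool)
        raise GeometryError("grid too small to host a crossing band with margins")
    rng = np.random.default_rng(seed)
    mask = np.zeros((rows, cols), dtype=bool)

    def clamp(c: int) -> int:
        return int(min(max(c, 1), cols - width - 1))

    def walk(r0: int, c0: int, drift: tuple[int, ...], stop_row: int) -> int:
        """Mark the band from row r0 down to stop_row-1; returns last col."""
        c = clamp(c0)
        for r in range(r0, stop_row):
            step = int(rng.choice(drift)) if r > r0 else 0
            c_new = clamp(c + step)
            if c_new != c:
                mask[r, min(c, c_new) : max(c, c_new) + width] = True  # elbow
            c = c_new
            mask[r, c : c + width] = True
        return c

    start = clamp(cols // 2 + int(rng.integers(-cols // 8, cols // 8 + 1)))
    if not bifurcate:
        walk(0, start, (-1, 0, 1), rows)
        return mask

    fork_row = rows // 3 + int(rng.integers(0, max(1, rows // 6)))
    c_fork = walk(0, start, (-1, 0, 1), fork_row)
    # two diverging branches; each immediately moves apart, enclosing a wedge
    left = clamp(c_fork - 1)
    right = clamp(c_fork + 1)
    mask[fork_row, min(left, c_fork) : max(right, c_fork) + width] = True
    walk(fork_row, left, (-1, -1, 0), rows)
    walk(fork_row, right, (0, 1, 1), rows)
    return mask


@dataclass
class SyntheticScenario:
    """A generated geometry plus planted ground-truth parameters."""

    grid: GridSpec
    river_mask: np.ndarray
    parcels: ParcelSet
    true_params: ModelParams
    seed: int
    labels: GeometryLabels
    reference_tail_average: DensityState | None = None


def planted_scenario(
    rows: int = 20,
    cols: int = 22,
    g_true: float = 2e-5,
    T: float = 1e-4,
    seed: int = 0,
    K: float = 0.113,
    n_parcels: int = 3,
    n_sweeps: int = 50000,
    tail_sweeps: int = 5000,
    river_width: int = 1,
    T_cold: float | None = None,
) -> SyntheticScenario:
    """Build a geometry, plant parcels in its largest region, and run the
    reference two-stage chain at the true parameters to produce a
    ground-truth year-average field for calibration-recovery experiments.

    ``T`` is the warmer stage temperature; the colder stage runs at
    ``T_cold`` (default ``T / 100``), warm-started from the first stage's
    tail average — the same annealing recipe the calibration evaluations
    use, so recovery experiments compare like with like. The defaults
    (20 x 22 grid, width-1 river, g_true = 2e-5, T = 1e-4) put the parcel
    expectation mid-range between the free-case and fully river-bound
    extremes, where the coupling is identifiable.
    """
    grid = GridSpec(n_rows=rows, n_cols=cols, cell_size_m=5.0)
    mask = make_river(rows, cols, width=river_width, bifurcate=False, seed=seed)
    labels = label_regions(mask, grid)
    if labels.n_regions < 2:
        raise GeometryError("generated river failed to split the grid")
    region_cells = labels.region_cells(1)
    rng = np.random.default_rng(seed + 1)
    # spread parcels over distinct distances from the river for an
    # informative calibration signal
    dist = distance_field(labels)
    dvals = dist.d[region_cells[:, 0], region_cells[:, 1]]
    order = np.argsort(dvals, kind="stable")
    picks = [
        region_cells[order[int(q * (len(order) - 1))]]
        for q in np.linspace(0.25, 0.85, n_parcels)
    ]
    # de-duplicate while keeping determinism
    seen: dict[tuple[int, int], None] = {}
    for p in picks:
        seen[(int(p[0]), int(p[1]))] = None
    while len(seen) < n_parcels:
        extra = region_cells[rng.integers(len(region_cells))]
        seen[(int(extra[0]), int(extra[1]))] = None
    parcels = ParcelSet(parcels=tuple(seen.keys()), total_year_count=0, n_trips=10)
    params = ModelParams(K=K, g=g_true, T=T)
    boundary = BoundaryCondition.constant(K, labels)
    ordering = make_ordering(labels, 1)
    _, cold = run_two_stage(
        params,
        ModelParams(K=K, g=g_true, T=T_cold if T_cold is not None else T / 100.0),
        ordering,
        n_sweeps,
        tail_sweeps,
        seed,
        labels,
        boundary,
        dist,
    )
    return SyntheticScenario(
        grid=grid,
        river_mask=mask,
        parcels=parcels,
        true_params=params,
        seed=int(seed),
        labels=labels,
        reference_tail_average=cold.tail_average,
    )


@dataclass(frozen=True)
class CaseStudyPreset:
    """Published constants of the Tacana-volcano field study.

    Reference values only: the river raster itself is not included, so
    these numbers parameterize the model but cannot regenerate the
    original maps. The calibrated temperatures and coupling were tuned on
    that unpublished full-scale geometry.
    """

    K: float
    trips: int
    transect_length_m: float
    transect_river_count: int
    parcel_cells: tuple[tuple[int, int], ...]
    parcel_total_count: int
    grid: GridSpec
    T1: float
    T2: float
    g_hat: float
    target_parcel_expectation: float
    note: str = "reference preset; river raster not included"


def tacana_preset() -> CaseStudyPreset:
    """The case-study constants: 17 individuals on a 75 m / 15-cell river
    transect over 10 trips (K = 0.113), 3 individuals in 5 off-river
    parcels, a 192 x 202 grid of 5 m cells anchored in UTM, and the
    calibrated temperatures and coupling."""
    grid = GridSpec(
        n_rows=192,
        n_cols=202,
        cell_size_m=5.0,
        utm_anchor=((594378.0, 1668578.0), (595383.0, 1669533.0)),
    )
    return CaseStudyPreset(
        K=0.113,
        trips=10,
        transect_length_m=75.0,
        transect_river_count=17,
        parcel_cells=((133, 126), (126, 134), (117, 138), (112, 147), (107, 157)),
        parcel_total_count=3,
        grid=grid,
        T1=4.75e-6,
        T2=2e-8,
        g_hat=3.25e-7,
        target_parcel_expectation=0.3,
    )
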