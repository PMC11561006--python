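"""Shared fixtures: small synthetic geometries built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import rivermrf as rm

K = 0.113


@pytest.fixture(scope="session")
def strip_geometry():
    """20x22 grid with a straight vertical river at column 20: region 1 is
    a 20x20 block west of the river, region 2 a 20x1 strip east of it."""
    grid = rm.GridSpec(20, 22)
    mask = rm.vertical_river_mask(20, 22, 20)
    labels = rm.label_regions(mask, grid)
    dist = rm.distance_field(labels)
    boundary = rm.BoundaryCondition.constant(K, labels)
    return grid, labels, dist, boundary


@pytest.fixture(scope="session")
def wiggly_geometry():
    """8x10 grid crossed by a random river: two irregular regions."""
    grid = rm.GridSpec(8, 10)
    mask = rm.make_river(8, 10, seed=5)
    labels = rm.label_regions(mask, grid)
    dist = rm.distance_field(labels)
    boundary = rm.BoundaryCondition.constant(K, labels)
    return grid, labels, dist, boundary


@pytest.fixture(scope="session")
def two_cell_geometry():
    """1x3 grid: river cell (0,0), region cells (0,1) and (0,2)."""
    grid = rm.GridSpec(1, 3)
    mask = np.array([[True, False, False]])
    labels = rm.label_regions(mask, grid)
    dist = rm.distance_field(labels)
    boundary = rm.BoundaryCondition.constant(K, labels)
    return grid, labels, dist, boundary


def random_state(labels, region_id, rng, cap=K):
    cells = labels.region_cells(region_id)
    return rm.DensityState(
        cells=cells, values=rng.uniform(0.0, cap, len(cells)), region_id=region_id
    )
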