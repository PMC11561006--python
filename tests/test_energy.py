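"""Hamiltonian checks: hand-summed examples, a brute-force oracle over all
cliques, the incremental-difference identity, and the region decoupling."""

from __future__ import annotations

import numpy as np
import pytest

import rivermrf as rm
from conftest import random_state

K = 0.113


# ---------------------------------------------------------------------------
# brute-force oracle: double loop over all cell pairs and river incidences
def brute_force_energy(state, labels, boundary, dist, g):
    cells = [tuple(map(int, rc)) for rc in state.cells]
    vals = {c: v for c, v in zip(cells, state.values)}
    shape = labels.shape
    total = 0.0
    for i, c1 in enumerate(cells):
        for c2 in cells[i + 1 :]:
            if abs(c1[0] - c2[0]) + abs(c1[1] - c2[1]) == 1:
                total += (vals[c1] - vals[c2]) ** 2
        for nb in rm.neighbors(c1, shape):
            if labels.labels[nb] == rm.RIVER:
                total += (vals[c1] - boundary.values[nb]) ** 2
        total += g * float(dist.d[c1]) ** 2 * vals[c1]
    return total


class TestFreeEnergy:
    def test_isolated_three_cell_chain(self):
        # 1x3 region with no river adjacency: only the two interior cliques
        labels = rm.GeometryLabels(
            labels=np.array([[1, 1, 1]], dtype=np.int32), region_sizes=[3]
        )
        state = rm.DensityState(
            cells=np.array([[0, 0], [0, 1], [0, 2]]),
            values=np.array([0.0, K, 0.0]),
            region_id=1,
        )
        boundary = rm.BoundaryCondition.constant(K, labels)
        assert rm.free_energy(state, labels, boundary, 1) == pytest.approx(
            2 * K**2, rel=1e-12
        )

    def test_single_cell_with_one_river_neighbor(self, two_cell_geometry):
        _, labels, _, boundary = two_cell_geometry
        state = rm.DensityState(
            cells=np.array([[0, 1], [0, 2]]), values=np.array([0.0, 0.0]), region_id=1
        )
        # boundary term (0-K)^2 at (0,1) plus the interior pair (0-0)^2
        assert rm.free_energy(state, labels, boundary, 1) == pytest.approx(
            K**2, rel=1e-12
        )

    def test_constant_boundary_state_has_zero_energy(self, strip_geometry):
        _, labels, _, boundary = strip_geometry
        state = rm.DensityState.constant(labels, 1, K)
        assert rm.free_energy(state, labels, boundary, 1) == 0.0

    def test_domain_mismatch_raises(self, strip_geometry):
        _, labels, _, boundary = strip_geometry
        state = rm.DensityState.constant(labels, 2, K)
        with pytest.raises(rm.EnergyError):
            rm.free_energy(state, labels, boundary, 1)


class TestPotentialEnergy:
    def test_single_cell_value(self):
        dist = rm.DistanceField(
            d=np.array([[2]]), m_horiz=np.array([[2]]), a_vert=np.array([[0]])
        )
        state = rm.DensityState(
            cells=np.array([[0, 0]]), values=np.array([0.1]), region_id=1
        )
        assert rm.potential_energy(state, dist, 0.5) == pytest.approx(0.2, rel=1e-12)

    def test_zero_coupling_and_zero_state(self, strip_geometry):
        _, labels, dist, _ = strip_geometry
        rng = np.random.default_rng(0)
        state = random_state(labels, 1, rng)
        assert rm.potential_energy(state, dist, 0.0) == 0.0
        zero = rm.DensityState.zeros(labels, 1)
        assert rm.potential_energy(zero, dist, 1.0) == 0.0

    def test_negative_coupling_rejected(self, strip_geometry):
        _, labels, dist, _ = strip_geometry
        state = rm.DensityState.zeros(labels, 1)
        with pytest.raises(rm.EnergyError):
            rm.potential_energy(state, dist, -1.0)


class TestTotalEnergy:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, wiggly_geometry, seed):
        _, labels, dist, boundary = wiggly_geometry
        rng = np.random.default_rng(seed)
        g = rng.uniform(0, 1e-3)
        params = rm.ModelParams(K=K, g=g, T=1.0)
        for region in [1, 2, None]:
            state = random_state(labels, region, rng)
            got = rm.total_energy(state, labels, boundary, dist, params)
            want = brute_force_energy(state, labels, boundary, dist, g)
            assert got == pytest.approx(want, rel=1e-12)

    def test_nonnegative_on_random_states(self, wiggly_geometry):
        _, labels, dist, boundary = wiggly_geometry
        rng = np.random.default_rng(42)
        params = rm.ModelParams(K=K, g=1e-4, T=1.0)
        for _ in range(20):
            state = random_state(labels, None, rng)
            assert rm.total_energy(state, labels, boundary, dist, params) >= 0.0

    def test_constant_boundary_state_is_global_minimum(self, strip_geometry):
        """With boundary K and g = 0 the constant-K state attains H = 0, the
        minimum of a sum of squares."""
        _, labels, dist, boundary = strip_geometry
        params = rm.ModelParams(K=K, g=0.0, T=1.0)
        const = rm.DensityState.constant(labels, 1, K)
        assert rm.total_energy(const, labels, boundary, dist, params) == 0.0
        rng = np.random.default_rng(1)
        for _ in range(10):
            other = random_state(labels, 1, rng)
            assert rm.total_energy(other, labels, boundary, dist, params) >= 0.0


class TestDeltaEnergy:
    def test_noop_is_zero(self, wiggly_geometry):
        _, labels, dist, boundary = wiggly_geometry
        rng = np.random.default_rng(3)
        state = random_state(labels, 1, rng)
        params = rm.ModelParams(K=K, g=1e-4, T=1.0)
        cell = tuple(map(int, state.cells[0]))
        assert rm.delta_energy(
            state, cell, state.value_at(cell), labels, boundary, dist, params
        ) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_recompute(self, wiggly_geometry, seed):
        _, labels, dist, boundary = wiggly_geometry
        rng = np.random.default_rng(seed)
        params = rm.ModelParams(K=K, g=rng.uniform(0, 1e-3), T=1.0)
        state = random_state(labels, 1, rng)
        h0 = rm.total_energy(state, labels, boundary, dist, params)
        for _ in range(50):
            i = rng.integers(state.n_cells)
            cell = tuple(map(int, state.cells[i]))
            x = rng.uniform(0, K)
            dh = rm.delta_energy(state, cell, x, labels, boundary, dist, params)
            mutated = state.copy()
            mutated.values[i] = x
            h1 = rm.total_energy(mutated, labels, boundary, dist, params)
            assert dh == pytest.approx(h1 - h0, rel=1e-12, abs=1e-15)

    def test_isolated_cell_potential_step(self):
        # neighborless single-cell region, d=1, g=1: raising 0 -> K costs
        # exactly the potential term g*d^2*K = K
        labels = rm.GeometryLabels(
            labels=np.array([[1]], dtype=np.int32), region_sizes=[1]
        )
        dist = rm.DistanceField(
            d=np.array([[1]]), m_horiz=np.array([[1]]), a_vert=np.array([[0]])
        )
        boundary = rm.BoundaryCondition(values=np.zeros((1, 1)))
        state = rm.DensityState(
            cells=np.array([[0, 0]]), values=np.array([0.0]), region_id=1
        )
        params = rm.ModelParams(K=K, g=1.0, T=1.0)
        dh = rm.delta_energy(state, (0, 0), K, labels, boundary, dist, params)
        assert dh == pytest.approx(K, rel=1e-12)

    def test_out_of_range_value_rejected(self, wiggly_geometry):
        _, labels, dist, boundary = wiggly_geometry
        state = rm.DensityState.zeros(labels, 1)
        params = rm.ModelParams(K=K, g=0.0, T=1.0)
        cell = tuple(map(int, state.cells[0]))
        with pytest.raises(rm.EnergyError):
            rm.delta_energy(state, cell, 2 * K, labels, boundary, dist, params)


class TestDecoupling:
    @pytest.mark.parametrize("seed", range(20))
    def test_total_equals_sum_of_region_energies(self, wiggly_geometry, seed):
        """Conditioning on the river makes the regions independent: the
        energy of a full off-river state equals the sum of its region
        restrictions' energies."""
        _, labels, dist, boundary = wiggly_geometry
        rng = np.random.default_rng(seed)
        params = rm.ModelParams(K=K, g=rng.uniform(0, 1e-3), T=1.0)
        full = random_state(labels, None, rng)
        total = rm.total_energy(full, labels, boundary, dist, params)
        parts = 0.0
        for i in range(1, labels.n_regions + 1):
            cells = labels.region_cells(i)
            vals = np.array([full.value_at(tuple(c)) for c in cells])
            part = rm.DensityState(cells=cells, values=vals, region_id=i)
            parts += rm.total_energy(part, labels, boundary, dist, params)
        assert total == pytest.approx(parts, rel=1e-12)


class TestLogDensity:
    def test_zero_energy_gives_zero(self, strip_geometry):
        _, labels, dist, boundary = strip_geometry
        params = rm.ModelParams(K=K, g=0.0, T=1e-3)
        state = rm.DensityState.constant(labels, 1, K)
        assert rm.log_unnorm_density(state, labels, boundary, dist, params) == 0.0

    def test_energy_temperature_ratio(self, two_cell_geometry):
        _, labels, dist, boundary = two_cell_geometry
        params = rm.ModelParams(K=K, g=0.0, T=0.005)
        state = rm.DensityState(
            cells=np.array([[0, 1], [0, 2]]), values=np.array([0.013, 0.013]), region_id=1
        )
        h = rm.total_energy(state, labels, boundary, dist, params)
        got = rm.log_unnorm_density(state, labels, boundary, dist, params)
        assert got == pytest.approx(-h / 0.005, rel=1e-12)

    def test_equal_energies_give_equal_values(self, strip_geometry):
        _, labels, dist, boundary = strip_geometry
        params = rm.ModelParams(K=K, g=0.0, T=1e-2)
        a = rm.DensityState.constant(labels, 1, 0.05)
        b = rm.DensityState.constant(labels, 1, 0.05)
        assert rm.log_unnorm_density(
            a, labels, boundary, dist, params
        ) == rm.log_unnorm_density(b, labels, boundary, dist, params)
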