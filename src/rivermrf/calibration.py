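"""Parameter calibration: the density cap K, the annealing temperatures,
and the river-attraction coupling g.

K is the observed year-average density per river cell — total individuals
counted on the transect divided by (transect cells x field trips). The
warmer temperature T1 is selected by running the free (g = 0) chain from
the zero state at each candidate and keeping the one whose tail-average
energy is lowest; the free-case minimizer is known exactly (the constant
boundary state with energy 0), which is what makes it usable for
temperature calibration. The coupling g is then chosen so the simulated
year-average expectation over the surveyed parcels matches the field
value (individuals counted in the parcels / trips): a coarse doubling
scan brackets the target, then bisection refines it, each evaluation
being a T1 chain from zero followed by a colder warm-started T2 chain.
The parcel expectation is assumed (and checked) to be non-increasing in
g — stronger attraction pulls density off the parcels toward the river.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from .energy import BoundaryCondition, DensityState, EnergyError, ModelParams
from .geometry import DistanceField, GeometryError, GeometryLabels, ParcelSet
from .sampler import CellOrdering, run_chain, run_two_stage


class CalibrationError(ValueError):
    """Raised when a calibration target is infeasible or assumptions fail."""


def compute_K(total_river_count: int, n_river_cells: int, n_trips: int) -> float:
    """Year-average density of individuals per river cell per trip.

    Exact rational arithmetic (``total / (cells * trips)``) before any
    formatting; use :func:`format_density` for 3-decimal reports.
    """
    if n_river_cells < 1 or n_trips < 1:
        raise CalibrationError("need at least one river cell and one trip")
    if total_river_count < 0:
        raise CalibrationError("count must be nonnegative")
    return float(Fraction(total_river_count, n_river_cells * n_trips))


def format_density(value: float) -> str:
    """Report formatter: densities rounded to 3 decimals."""
    return f"{value:.3f}"


def transect_cells(transect_length_m: float, cell_size_m: float) -> int:
    """Number of grid cells covering the river transect."""
    if transect_length_m <= 0 or cell_size_m <= 0:
        raise CalibrationError("lengths must be positive")
    ratio = transect_length_m / cell_size_m
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"transect length {transect_length_m} is not a whole number of "
            f"{cell_size_m} m cells; rounding down",
            stacklevel=2,
        )
        return int(ratio)
    return int(round(ratio))


@dataclass
class CalibrationResult:
    """Outcome of the two-temperature coupling calibration."""

    T1: float
    T2: float
    g_hat: float
    achieved_parcel_expectation: float
    target_parcel_expectation: float
    n_evaluations: int
    seeds: list[int] = field(default_factory=list)
    history: list[tuple[float, float]] = field(default_factory=list)  # (g, expectation)

    def __post_init__(self) -> None:
        if self.T2 > self.T1:
            raise CalibrationError("T2 must not exceed T1")


def parcel_expectation(tail_average: DensityState, parcels: ParcelSet) -> float:
    """Expected year-average number of individuals over the parcel cells:
    the sum of the tail-average density at each parcel."""
    try:
        return float(sum(tail_average.value_at(p) for p in parcels.parcels))
    except EnergyError as exc:
        raise GeometryError(f"parcel outside the state's region: {exc}") from exc


def select_T1(
    candidates: list[float],
    ordering: CellOrdering,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    K: float,
    n_sweeps: int,
    tail_sweeps: int,
    seed: int,
) -> tuple[float, DensityState, list[tuple[float, float]]]:
    """Pick the free-case (g = 0) temperature with the lowest tail energy.

    Runs one chain per candidate from the zero state and returns the
    winning temperature, its tail-average state (the warm start for the
    colder stage), and the (T, tail energy) diagnostics table.
    """
    if not candidates:
        raise CalibrationError("need at least one temperature candidate")
    best: tuple[float, DensityState] | None = None
    best_e = float("inf")
    table: list[tuple[float, float]] = []
    zero = DensityState.zeros(labels, ordering.region_id)
    for T in candidates:
        params = ModelParams(K=K, g=0.0, T=float(T))
        res = run_chain(
            zero, params, ordering, n_sweeps, tail_sweeps, seed, labels, boundary, dist
        )
        tail_e = float(res.energy_trace[-tail_sweeps:].mean())
        table.append((float(T), tail_e))
        if tail_e < best_e:
            best_e = tail_e
            best = (float(T), res.tail_average)
    assert best is not None
    return best[0], best[1], table


def estimate_g(
    target: float,
    parcels: ParcelSet,
    T1: float,
    T2: float,
    ordering: CellOrdering,
    labels: GeometryLabels,
    boundary: BoundaryCondition,
    dist: DistanceField,
    K: float,
    n_sweeps: int,
    tail_sweeps: int,
    seed: int,
    tol: float = 0.01,
    rtol: float = 1e-3,
    g_init: float = 1e-10,
    max_scan: int = 200,
    max_bisect: int = 60,
    mono_tol: float | None = None,
) -> CalibrationResult:
    """Calibrate the coupling so the parcel expectation matches ``target``.

    Stage A doubles g from ``g_init`` until the expectation first drops
    below the target, bracketing it; stage B bisects the bracket. Every
    evaluation runs the same seeded two-stage chain (T1 from zero, T2
    warm-started), so the procedure is deterministic given (seed, config).

    ``tol`` is the matching tolerance in expected individuals; ``mono_tol``
    the Monte-Carlo slack allowed before the scan's non-monotonicity is
    treated as an error (default: ``max(tol, 2% of the feasible range)``).
    """
    if target < 0:
        raise CalibrationError("target expectation must be nonnegative")
    if mono_tol is None:
        mono_tol = max(tol, 0.02 * len(parcels.parcels) * K)
    history: list[tuple[float, float]] = []
    seeds = [int(seed)]

    def evaluate(g: float) -> float:
        _, cold = run_two_stage(
            ModelParams(K=K, g=g, T=T1),
            ModelParams(K=K, g=g, T=T2),
            ordering,
            n_sweeps,
            tail_sweeps,
            seed,
            labels,
            boundary,
            dist,
        )
        e = parcel_expectation(cold.tail_average, parcels)
        history.append((g, e))
        return e

    e0 = evaluate(0.0)
    if abs(e0 - target) <= tol:
        return CalibrationResult(
            T1=T1, T2=T2, g_hat=0.0, achieved_parcel_expectation=e0,
            target_parcel_expectation=target, n_evaluations=len(history),
            seeds=seeds, history=history,
        )
    if e0 < target:
        raise CalibrationError(
            f"target {target} exceeds the free-case parcel expectation {e0:.4f}; "
            "attraction to the river can only lower it"
        )

    # stage A: geometric scan for a bracket [g_lo, g_hi]
    g_lo, e_lo = 0.0, e0
    g = g_init
    e = evaluate(g)
    n = 0
    while e >= target and n < max_scan:
        if e > e_lo + mono_tol:
            raise CalibrationError(
                f"parcel expectation increased from {e_lo:.4f} to {e:.4f} as g grew "
                f"to {g:.3g}; monotonicity assumption violated — history: {history}"
            )
        g_lo, e_lo = g, e
        g *= 2.0
        e = evaluate(g)
        n += 1
    if e >= target:
        raise CalibrationError(
            f"could not bracket the target within {max_scan} doublings of g"
        )
    g_hi, e_hi = g, e

    # stage B: bisection
    best_g, best_e = (g_lo, e_lo) if abs(e_lo - target) < abs(e_hi - target) else (g_hi, e_hi)
    for _ in range(max_bisect):
        if abs(best_e - target) <= tol or (g_hi - g_lo) < rtol * g_hi:
            break
        mid = 0.5 * (g_lo + g_hi)
        e_mid = evaluate(mid)
        if abs(e_mid - target) < abs(best_e - target):
            best_g, best_e = mid, e_mid
        if e_mid >= target:
            g_lo = mid
        else:
            g_hi = mid
    return CalibrationResult(
        T1=T1,
        T2=T2,
        g_hat=best_g,
        achieved_parcel_expectation=best_e,
        target_parcel_expectation=target,
        n_evaluations=len(history),
        seeds=seeds,
        history=history,
    )
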