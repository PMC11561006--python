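"""Simulated observations and graphical rendering of the density surface.

The tail-average field ``omega_hat`` estimates the expected year-average
number of individuals per cell. From it:

* whole-year counts — each cell draws ``Poisson(trips * omega_hat)``
  individuals (the year field intensity is trips times the per-trip
  density);
* single-trip presences — each cell is occupied with probability
  ``omega_hat`` (valid because the density cap is below 1);
* the heat map — densities binned into the 7 rainbow colors on the
  half-open intervals ``((s/7) K, ((s+1)/7) K]``, with exact zeros
  assigned to the lowest bin.

River cells are excluded from the draws (their density is the fixed
boundary constant, already summarized by K) and rendered black.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .energy import DensityState, EnergyError
from .geometry import GeometryLabels

RAINBOW = ("red", "orange", "yellow", "green", "cyan", "blue", "violet")
"""Bin colors in ascending color-energy order (bin 0 .. bin 6)."""


@dataclass
class YearRealization:
    """Per-cell simulated whole-year counts (Poisson draws)."""

    cells: np.ndarray
    counts: np.ndarray
    trips: int
    seed: int


@dataclass
class TripRealization:
    """Per-cell simulated single-trip presences (0/1)."""

    cells: np.ndarray
    presence: np.ndarray
    seed: int


@dataclass
class HeatmapBins:
    """Per-cell color-bin indices in 0..6 and the bin edges used."""

    cells: np.ndarray
    bin: np.ndarray
    bin_edges: np.ndarray  # length 8: 0, K/7, ..., K


def year_counts(omega_hat: DensityState, trips: int, seed: int) -> YearRealization:
    """Draw one whole-year observation field: ``Poisson(trips * omega)``
    independently per cell."""
    if trips < 1:
        raise EnergyError("trips must be positive")
    if (omega_hat.values < 0).any():
        raise EnergyError("densities must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(trips * omega_hat.values)
    return YearRealization(
        cells=omega_hat.cells.copy(), counts=counts, trips=trips, seed=int(seed)
    )


def trip_presence(omega_hat: DensityState, seed: int) -> TripRealization:
    """Draw one single-trip presence field: cell occupied iff an
    independent uniform draw is <= its density (Bernoulli(omega))."""
    v = omega_hat.values
    if (v < 0).any() or (v > 1).any():
        raise EnergyError("Bernoulli presences require densities in [0, 1]")
    rng = np.random.default_rng(seed)
    presence = (rng.random(v.size) <= v).astype(np.int64)
    return TripRealization(cells=omega_hat.cells.copy(), presence=presence, seed=int(seed))


def heatmap_bins(omega_hat: DensityState, K: float) -> HeatmapBins:
    """Assign each cell its rainbow bin: s iff omega in ((s/7)K, ((s+1)/7)K];
    an exact zero goes to bin 0."""
    v = omega_hat.values
    if (v < 0).any() or (v > K).any():
        raise EnergyError("densities must lie in [0, K] for binning")
    bins = np.ceil(7.0 * v / K).astype(np.int64) - 1
    bins = np.clip(bins, 0, 6)
    edges = np.linspace(0.0, K, 8)
    return HeatmapBins(cells=omega_hat.cells.copy(), bin=bins, bin_edges=edges)


def _bin_rgb() -> np.ndarray:
    from matplotlib.colors import to_rgb

    base = np.array([to_rgb(c) for c in RAINBOW])
    # intensity rises with color energy: fade low bins toward white
    fade = np.linspace(0.45, 0.0, 7)[:, None]
    return base * (1 - fade) + fade


def render_heatmap(
    bins: HeatmapBins, labels: GeometryLabels, path: str | Path
) -> None:
    """Write the heat-map PNG: rainbow bins off-river, black river cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.ones(labels.shape + (3,))
    rgb = _bin_rgb()
    img[bins.cells[:, 0], bins.cells[:, 1]] = rgb[bins.bin]
    img[labels.river_mask] = 0.0
    fig, ax = plt.subplots(figsize=(6, 6 * labels.shape[0] / labels.shape[1]))
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_dots(
    counts_or_presence: YearRealization | TripRealization,
    labels: GeometryLabels,
    path: str | Path,
    seed: int = 0,
) -> None:
    """Scatter one dot per simulated individual, jittered uniformly inside
    its cell square (within-cell placement carries no information)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(counts_or_presence, YearRealization):
        per_cell = counts_or_presence.counts
    else:
        per_cell = counts_or_presence.presence
    rng = np.random.default_rng(seed)
    cells = counts_or_presence.cells
    xs, ys = [], []
    for (r, c), n in zip(cells, per_cell):
        for _ in range(int(n)):
            xs.append(c + rng.random())
            ys.append(r + rng.random())
    fig, ax = plt.subplots(figsize=(6, 6 * labels.shape[0] / labels.shape[1]))
    river = np.zeros(labels.shape + (4,))
    river[labels.river_mask] = (0, 0, 0, 1)
    ax.imshow(river, interpolation="nearest", extent=(0, labels.shape[1], labels.shape[0], 0))
    ax.scatter(xs, ys, s=4, c="black", marker=".")
    ax.set_xlim(0, labels.shape[1])
    ax.set_ylim(labels.shape[0], 0)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
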