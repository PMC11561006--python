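"""From calibrated parameters to a density map and simulated observations.

Each off-river region is sampled independently (they are decoupled by the
river boundary); the merged tail-average field is binned into the 7
rainbow colors and used to draw whole-year Poisson counts and single-trip
Bernoulli presences.
"""

from pathlib import Path

import numpy as np

import rivermrf as rm

K = 0.113
out = Path("example_output")
out.mkdir(exist_ok=True)

grid = rm.GridSpec(20, 24)
mask = rm.make_river(20, 24, bifurcate=True, seed=3)
labels = rm.label_regions(mask, grid)
dist = rm.distance_field(labels)
boundary = rm.BoundaryCondition.constant(K, labels)

states = []
for rid in range(1, labels.n_regions + 1):
    ordering = rm.make_ordering(labels, rid)
    _, cold = rm.run_two_stage(
        rm.ModelParams(K=K, g=2e-5, T=1e-4),
        rm.ModelParams(K=K, g=2e-5, T=1e-6),
        ordering, 20000, 2000, seed=rid, labels=labels, boundary=boundary, dist=dist,
    )
    states.append(cold.tail_average)
omega = rm.merge_states(states)
print(f"density surface on {omega.n_cells} off-river cells "
      f"(mean {omega.values.mean():.4f}, max {omega.values.max():.4f})")

bins = rm.heatmap_bins(omega, K)
hist = np.bincount(bins.bin, minlength=7)
for s, (color, n) in enumerate(zip(rm.RAINBOW, hist)):
    print(f"  bin {s} ({color:>6}): {n:4d} cells  "
          f"({s}/7*K, {s+1}/7*K] = ({s/7*K:.4f}, {(s+1)/7*K:.4f}]")
rm.render_heatmap(bins, labels, out / "heatmap.png")

year = rm.year_counts(omega, trips=10, seed=1)
trip = rm.trip_presence(omega, seed=2)
print(f"one whole-year realization: {year.counts.sum()} simulated individuals "
      f"(expected {10 * omega.values.sum():.1f})")
print(f"one single-trip realization: {trip.presence.sum()} occupied cells "
      f"(expected {omega.values.sum():.1f})")
rm.render_dots(year, labels, out / "year_dots.png", seed=1)
print(f"figures written to {out}/")
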