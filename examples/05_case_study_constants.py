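"""The case-study field constants and their arithmetic.

The preset carries the published study constants — transect counts, grid,
UTM anchoring, parcel coordinates, and the calibrated temperatures and
coupling — as reference values (the original river raster is not
included, so they parameterize the model but cannot regenerate the
original maps).
"""

import rivermrf as rm

p = rm.tacana_preset()

cells = rm.transect_cells(p.transect_length_m, p.grid.cell_size_m)
K = rm.compute_K(p.transect_river_count, cells, p.trips)
print(f"transect: {p.transect_length_m:g} m of {p.grid.cell_size_m:g} m cells -> {cells} cells")
print(f"density cap K = {p.transect_river_count}/({cells}*{p.trips}) = "
      f"{rm.format_density(K)} individuals per cell per trip")
print(f"parcel target = {p.parcel_total_count}/{p.trips} = "
      f"{p.parcel_total_count / p.trips} expected individuals on the parcels")
print(f"grid: {p.grid.n_rows} x {p.grid.n_cols} cells, UTM-anchored")

# parcel UTM coordinates resolve to the published grid cells
utm_parcels = [
    (595008.5, 1668868.5), (595048.5, 1668903.5), (595068.5, 1668948.5),
    (595113.5, 1668973.5), (595163.5, 1668998.5),
]
for utm, cell in zip(utm_parcels, p.parcel_cells):
    got = rm.utm_to_grid(*utm, p.grid)
    print(f"  parcel at UTM {utm} -> grid {got} (published {cell})")

print(f"calibrated reference values: T1={p.T1:g}, T2={p.T2:g}, g_hat={p.g_hat:g}")
print(f"note: {p.note}")
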