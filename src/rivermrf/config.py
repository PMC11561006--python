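"""Run configuration: a nested key-value (YAML) file driving the pipeline.

Every command writes a resolved config echo into its output directory;
re-running from that echo with the same seeds reproduces every output
file byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as rio
from .geometry import GeometryError, GeometryLabels, GridSpec, ParcelSet, label_regions
from .synthetic import make_river


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise GeometryError(f"config {path} must be a mapping")
        return cls(raw=data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)

    def require(self, *keys: str) -> Any:
        node: Any = self.raw
        trail = []
        for k in keys:
            trail.append(k)
            if not isinstance(node, dict) or k not in node:
                raise GeometryError(f"config is missing key '{'.'.join(trail)}'")
            node = node[k]
        return node

    def get(self, *keys: str, default: Any = None) -> Any:
        node: Any = self.raw
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    # -- resolved objects ------------------------------------------------
    def grid(self) -> GridSpec:
        g = self.require("grid")
        anchor = g.get("utm_anchor")
        if anchor is not None:
            anchor = (tuple(anchor[0]), tuple(anchor[1]))
        return GridSpec(
            n_rows=int(g["rows"]),
            n_cols=int(g["cols"]),
            cell_size_m=float(g.get("cell_size_m", 5.0)),
            utm_anchor=anchor,
        )

    def river_mask(self) -> np.ndarray:
        grid = self.grid()
        geo = self.require("geometry")
        source = geo.get("source", "synthetic")
        if source == "file":
            if "mask_csv" in geo:
                return rio.read_mask_csv(geo["mask_csv"], grid)
            if "mask_raster" in geo:
                return rio.read_mask_raster(geo["mask_raster"], grid)
            raise GeometryError("config geometry.source=file needs mask_csv or mask_raster")
        if source == "synthetic":
            syn = geo.get("synthetic", {})
            return make_river(
                grid.n_rows,
                grid.n_cols,
                width=int(syn.get("width", 1)),
                bifurcate=bool(syn.get("bifurcate", False)),
                seed=int(syn.get("seed", self.seed())),
            )
        raise GeometryError(f"unknown geometry.source '{source}'")

    def labels(self) -> GeometryLabels:
        return label_regions(self.river_mask(), self.grid())

    def parcels(self) -> ParcelSet:
        cal = self.require("calibration")
        if "parcels_csv" in cal:
            cells = rio.read_parcels_csv(cal["parcels_csv"], self.grid())
        elif "parcels" in cal:
            cells = [(int(r), int(c)) for r, c in cal["parcels"]]
        else:
            raise GeometryError("config is missing key 'calibration.parcels'")
        return ParcelSet(
            parcels=tuple(cells),
            total_year_count=int(cal.get("total_year_count", 0)),
            n_trips=int(cal.get("trips", 10)),
        )

    def seed(self) -> int:
        return int(self.raw.get("seed", 0))
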