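"""Ecological-safety zoning and policy partition.

The cumulative-resistance surface (cost distance from the ecological
sources, by default) is classified into five safety levels by natural
breaks — the higher the accumulated resistance, the lower the safety — and
the levels are coarsened into three policy areas:

* restoration  <- low + lower safety (heavily disturbed, rebuild first)
* control      <- medium + higher safety (transition belt, buffer)
* conservation <- high safety (stable, protect what is there)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid import Grid, classify, grid_jenks_breaks

__all__ = ["SafetyZoneMap", "safety_zones", "policy_partition",
           "ZONE_NAMES", "DEFAULT_POLICY_MAPPING"]

#: zone id -> name; 1 = high safety (lowest cumulative resistance)
ZONE_NAMES = {1: "high", 2: "higher", 3: "medium", 4: "lower", 5: "low"}

POLICY_CODES = {"conservation": 1, "control": 2, "restoration": 3}

#: zone id -> policy area
DEFAULT_POLICY_MAPPING = {1: "conservation", 2: "control", 3: "control",
                          4: "restoration", 5: "restoration"}


@dataclass
class SafetyZoneMap:
    """Five-class safety raster (1 = high safety ... 5 = low safety)."""

    zone_grid: Grid
    areas: dict[int, dict[str, float]]
    policy_grid: Grid | None = None
    policy_areas: dict[str, dict[str, float]] = field(default_factory=dict)


def _area_table(grid: Grid, labels) -> dict:
    cell_area = grid.cell_area_km2()
    vals = grid.valid_values()
    total = vals.size * cell_area
    table = {}
    for lab in labels:
        n = int((vals == lab).sum())
        area = n * cell_area
        table[lab] = {"area_km2": area,
                      "percent": 100.0 * area / total if total else 0.0}
    return table


def safety_zones(cost: Grid, n_classes: int = 5) -> SafetyZoneMap:
    """Classify cumulative resistance into safety zones by natural breaks.

    Zone 1 covers the lowest-cost cells (highest safety); zone ids are
    monotone non-decreasing in cost by construction of the break ordering.
    """
    vals = cost.valid_values()
    if vals.size == 0:
        raise ValueError("cost surface has no valid cells")
    if np.unique(vals).size < n_classes:
        raise ValueError(
            f"only {np.unique(vals).size} distinct cost values; "
            f"use a smaller class count than {n_classes}")
    zones = classify(cost, grid_jenks_breaks(cost, n_classes))
    return SafetyZoneMap(zone_grid=zones,
                         areas=_area_table(zones, range(1, n_classes + 1)))


def policy_partition(
    zones: SafetyZoneMap,
    mapping: Mapping[int, str] | None = None,
) -> SafetyZoneMap:
    """Coarsen safety zones into restoration/control/conservation areas."""
    mapping = dict(mapping or DEFAULT_POLICY_MAPPING)
    present = set(int(v) for v in np.unique(zones.zone_grid.valid_values()))
    zone_ids = set(zones.areas)
    missing = zone_ids - set(mapping)
    if missing:
        raise ValueError(f"policy mapping does not cover zones {sorted(missing)}")
    bad = {z: p for z, p in mapping.items() if p not in POLICY_CODES}
    if bad:
        raise ValueError(f"unknown policy names {bad}; use {sorted(POLICY_CODES)}")
    zv = zones.zone_grid.values
    out = np.full(zv.shape, np.nan)
    for zone, policy in mapping.items():
        out[zv == zone] = POLICY_CODES[policy]
    policy_grid = zones.zone_grid.copy(out)
    cell_area = policy_grid.cell_area_km2()
    vals = policy_grid.valid_values()
    total = vals.size * cell_area
    areas = {}
    for name, code in POLICY_CODES.items():
        n = int((vals == code).sum())
        areas[name] = {"area_km2": n * cell_area,
                       "percent": 100.0 * n / vals.size if vals.size else 0.0}
    zones.policy_grid = policy_grid
    zones.policy_areas = areas
    return zones
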