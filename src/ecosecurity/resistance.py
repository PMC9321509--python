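"""Comprehensive ecological resistance surface by weighted overlay.

Five factors impede species movement: land-use type, vegetation coverage
and slope (natural disturbance), and distance to county roads and highways
(human disturbance).  Each factor is reclassified to the resistance scale
{1, 20, 40, 60, 80, 100} through its band table and the five layers are
combined cellwise as sum(w_i * R_i).

The road-distance tables assign resistance 1 — *below* the nearest band's
20 — beyond 800 m (county roads) and 2000 m (highways): far from any road
the landscape is taken as essentially permeable.  This non-monotone step is
kept verbatim by default; ``monotone=True`` replaces the 1 by 20 for
sensitivity analysis.

Band membership is left-open/right-closed: a value exactly on a band edge
falls in the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid import Grid

__all__ = [
    "ResistanceFactor",
    "ResistanceSurface",
    "reclass_factor",
    "weighted_overlay",
    "FACTOR_WEIGHTS",
    "LANDUSE_CODES",
    "LANDUSE_RESISTANCE",
]

RESISTANCE_SCALE = (1, 20, 40, 60, 80, 100)

#: land-use class codes used throughout the pipeline
LANDUSE_CODES = {
    "forest_grass": 1,
    "water": 2,
    "cultivated": 3,
    "bare": 4,
    "construction": 5,
}

LANDUSE_RESISTANCE = {1: 20, 2: 40, 3: 60, 4: 80, 5: 100}

#: (ascending band edges, resistance value per band); the value list has one
#: more entry than the edge list (the last band is open above the last edge)
BAND_TABLES: dict[str, tuple[tuple[float, ...], tuple[int, ...]]] = {
    # high coverage -> low resistance
    "vegcover": ((0.65, 0.50, 0.35, 0.15), (20, 40, 60, 80, 100)),
    "slope": ((5.0, 15.0, 25.0, 35.0), (20, 40, 60, 80, 100)),
    "dist_county_road": ((150.0, 300.0, 450.0, 600.0, 800.0),
                         (20, 40, 60, 80, 100, 1)),
    "dist_highway": ((400.0, 800.0, 1200.0, 1600.0, 2000.0),
                     (20, 40, 60, 80, 100, 1)),
}

#: factor weights in the order (landuse, vegcover, slope, county road, highway)
FACTOR_WEIGHTS = {
    "landuse": 0.095,
    "vegcover": 0.213,
    "slope": 0.236,
    "dist_county_road": 0.118,
    "dist_highway": 0.173,
}

FACTOR_ORDER = tuple(FACTOR_WEIGHTS)


@dataclass
class ResistanceFactor:
    name: str
    grid: Grid
    weight: float

    def __post_init__(self) -> None:
        vals = self.grid.valid_values()
        if vals.size and not np.isin(vals, RESISTANCE_SCALE).all():
            bad = np.setdiff1d(np.unique(vals), RESISTANCE_SCALE)
            raise ValueError(f"factor {self.name} has off-scale values {bad}")


@dataclass
class ResistanceSurface:
    grid: Grid
    weights: dict[str, float]


def reclass_factor(
    raw: Grid,
    name: str,
    weight: float | None = None,
    monotone: bool = False,
    band_tables: Mapping[str, tuple] | None = None,
    landuse_resistance: Mapping[int, int] | None = None,
) -> ResistanceFactor:
    """Map a raw factor layer onto the resistance scale through its bands."""
    if weight is None:
        weight = FACTOR_WEIGHTS[name]
    out = np.full(raw.shape, np.nan)
    if name == "landuse":
        table = dict(landuse_resistance or LANDUSE_RESISTANCE)
        seen = np.unique(raw.valid_values()).astype(int)
        unknown = [c for c in seen if c not in table]
        if unknown:
            raise ValueError(f"unmapped land-use codes {unknown}; mapped: {sorted(table)}")
        for code, value in table.items():
            out[raw.values == code] = value
    else:
        tables = dict(BAND_TABLES)
        if band_tables:
            tables.update(band_tables)
        if name not in tables:
            raise ValueError(f"unknown resistance factor {name!r}")
        edges, values = tables[name]
        values = list(values)
        if monotone:
            values = [max(v, 20) for v in values]
        v = raw.values
        descending = name == "vegcover"
        with np.errstate(invalid="ignore"):
            if descending:
                out = np.full(raw.shape, float(values[-1]))
                for edge, val in zip(reversed(edges), reversed(values[:-1])):
                    out[v > edge] = val
            else:
                out = np.full(raw.shape, float(values[-1]))
                for edge, val in zip(reversed(edges), reversed(values[:-1])):
                    out[v <= edge] = val
        out[~raw.mask] = np.nan
    return ResistanceFactor(name, raw.copy(out), float(weight))


def weighted_overlay(
    factors: Sequence[ResistanceFactor],
    weights: Mapping[str, float] | None = None,
) -> ResistanceSurface:
    """Cellwise sum of weight_i * resistance_i over the five factor layers."""
    if weights is not None:
        factors = [ResistanceFactor(f.name, f.grid, float(weights[f.name]))
                   for f in factors]
    names = [f.name for f in factors]
    missing = [n for n in FACTOR_ORDER if n not in names]
    if missing:
        raise ValueError(f"missing resistance factors: {missing}")
    if len(set(names)) != len(names):
        raise ValueError("duplicate resistance factors")
    factors[0].grid.require_aligned(*(f.grid for f in factors[1:]))
    total = np.zeros(factors[0].grid.shape)
    for f in factors:
        if f.weight <= 0:
            raise ValueError(f"weight for {f.name} must be positive")
        total = total + f.weight * f.grid.values
    return ResistanceSurface(
        grid=factors[0].grid.copy(total),
        weights={f.name: f.weight for f in factors},
    )
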