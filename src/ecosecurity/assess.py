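"""Ecological sensitivity and ecosystem-service importance assessment.

Three sensitivity indices are evaluated on factor layers graded onto the
ordinal scale {1,3,5,7,9} (1 = low sensitivity, 9 = high):

* soil-and-water-loss sensitivity  SSWL = (R*K*LS*C)^(1/4)
* soil-erosion sensitivity         SSE  = mean(LS, R, K, C)
* land-desertification sensitivity SLD  = (I*W*K*C)^(1/4)

where R is rainfall erosivity, K soil texture/erodibility, LS topographic
relief, C vegetation coverage, I the aridity (dryness) index and W annual
sand-blowing days.  The geometric-mean indices are applied to *graded*
values: the ordinal assignment exists precisely to make heterogeneous
factors commensurable before multiplication.

Three service-importance indices are products of inputs normalized to
[0, 1]:

* water retention        WR   = NPPmean * Fsic * Fpre * (1 - Fsio)
* soil conservation      Spro = NPPmean * (1 - K) * (1 - Fsio)
* biodiversity support   Sbio = NPPmean * Fpre * Ftem * (1 - Falt)

with Fsic the soil percolation factor (USDA texture class index / 13),
Fpre mean precipitation, Fsio the slope factor (degrees / 90), Ftem mean
temperature and Falt normalized elevation.

Weighted composites of each triple and their equal-weight superposition
give the integrated ecological-environment score, classified into five
levels by natural breaks (class 5 = extremely important / most sensitive).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Mapping, Sequence

import numpy as np

from .grid import Grid, classify, grid_jenks_breaks, minmax_normalize

__all__ = [
    "GradedFactor",
    "SensitivityLayers",
    "ServiceLayers",
    "EcoAssessment",
    "rainfall_erosivity",
    "grade_factor",
    "grade_soil_texture",
    "sswl",
    "sse",
    "sld",
    "composite_sensitivity",
    "water_retention",
    "soil_conservation",
    "biodiversity_service",
    "composite_importance",
    "superpose_environment",
    "slope_degrees",
]

log = logging.getLogger(__name__)

GRADES = (1, 3, 5, 7, 9)

#: default composite weights for (SSWL, SSE, SLD)
SENSITIVITY_WEIGHTS = (0.43, 0.39, 0.18)
#: default composite weights for (WR, Spro, Sbio)
SERVICE_WEIGHTS = (0.45, 0.30, 0.25)

# Grading bands for continuous factors.  Ascending factors list the four
# interior thresholds from grade 1|3 up to 7|9; band membership is
# left-open/right-closed, so a value exactly on a threshold falls in the
# lower band.  Descending factors (vegetation coverage) grade high raw
# values as LOW sensitivity.
FACTOR_BANDS: dict[str, tuple[tuple[float, ...], str]] = {
    "R": ((532.0, 560.0, 583.0, 604.0), "ascending"),
    "LS": ((70.0, 123.0, 178.0, 248.0), "ascending"),
    "C": ((0.95, 0.85, 0.75, 0.55), "descending"),
    "I": ((0.55, 0.65, 0.75, 0.85), "ascending"),
    "W": ((100.0, 140.0, 190.0, 250.0), "ascending"),
}

# USDA texture class index (as carried by global soil data, 1..13; 1 = heavy
# clay ... 13 = sand) -> sensitivity grade.  Silts grade lowest, loams and
# sandy loams low-to-medium, pure sand and clays high; gravel (not part of
# the 13-class triangle) may be supplied as code 14.
SOIL_TEXTURE_GRADES: dict[int, int] = {
    6: 1,                       # silt
    4: 3, 5: 3, 7: 3, 11: 3, 12: 3,   # silty clay loam, clay loam, silt loam,
                                      # sandy loam, loamy sand
    8: 5, 9: 5, 10: 5,          # sandy clay, loam, sandy clay loam
    1: 7, 2: 7, 3: 7, 13: 7,    # clays and sand
    14: 9,                      # gravel
}

N_TEXTURE_CLASSES = 13


@dataclass
class GradedFactor:
    """A factor raster reclassified onto the ordinal scale {1,3,5,7,9}."""

    grid: Grid
    name: str
    direction: str = "ascending"

    def __post_init__(self) -> None:
        vals = self.grid.valid_values()
        if vals.size and not np.isin(vals, GRADES).all():
            bad = np.setdiff1d(np.unique(vals), GRADES)
            raise ValueError(f"graded factor {self.name} has off-scale values {bad}")


@dataclass
class SensitivityLayers:
    sswl: Grid
    sse: Grid
    sld: Grid
    weights: tuple[float, float, float] = SENSITIVITY_WEIGHTS
    composite: Grid | None = None


@dataclass
class ServiceLayers:
    wr: Grid
    spro: Grid
    sbio: Grid
    weights: tuple[float, float, float] = SERVICE_WEIGHTS
    composite: Grid | None = None


@dataclass
class EcoAssessment:
    """Five-class rasters: 1 = generally important/low sensitivity, 5 = extreme."""

    sensitivity_class: Grid
    importance_class: Grid
    environment_class: Grid
    environment_score: Grid


# ---------------------------------------------------------------------------
# Factor preparation


def rainfall_erosivity(monthly_precip: Sequence[Grid]) -> Grid:
    """Rainfall erosivity R = sum over months of (-2.6398 + 0.3046 * Pi).

    ``monthly_precip`` must hold the 12 long-term monthly-mean rainfall
    layers in millimetres.  Negative monthly terms (Pi < ~8.67 mm) are kept:
    the index is later graded by natural breaks, so its absolute level is
    immaterial.
    """
    if len(monthly_precip) != 12:
        raise ValueError(f"expected 12 monthly layers, got {len(monthly_precip)}")
    first = monthly_precip[0]
    first.require_aligned(*monthly_precip[1:])
    total = np.zeros(first.shape)
    for month in monthly_precip:
        total = total + (-2.6398 + 0.3046 * month.values)
    return first.copy(total)


def grade_factor(
    grid: Grid,
    factor: str,
    bands: Mapping[str, tuple[tuple[float, ...], str]] | None = None,
) -> GradedFactor:
    """Reclassify a continuous factor onto {1,3,5,7,9} by its grading bands."""
    table = dict(FACTOR_BANDS)
    if bands:
        table.update(bands)
    if factor == "soil_texture":
        return grade_soil_texture(grid)
    if factor not in table:
        raise ValueError(f"unknown factor {factor!r}; known: {sorted(table)}")
    t, direction = table[factor]
    v = grid.values
    with np.errstate(invalid="ignore"):
        if direction == "ascending":
            # band edges are left-open/right-closed: a value on a threshold
            # falls in the lower band
            conds = [v <= t[0], v <= t[1], v <= t[2], v <= t[3]]
        else:  # high raw value -> low sensitivity
            conds = [v > t[0], v > t[1], v > t[2], v > t[3]]
    out = np.full(grid.shape, 9.0)
    for grade, cond in zip((7, 5, 3, 1), conds[::-1]):
        out[cond] = grade
    out[~grid.mask] = np.nan
    return GradedFactor(grid.copy(out), factor,
                        "descending" if direction == "descending" else "ascending")


def grade_soil_texture(
    grid: Grid, code_grades: Mapping[int, int] | None = None
) -> GradedFactor:
    """Map soil-texture class codes to sensitivity grades."""
    mapping = dict(SOIL_TEXTURE_GRADES)
    if code_grades:
        mapping.update(code_grades)
    v = grid.values
    out = np.full(grid.shape, np.nan)
    seen = np.unique(v[grid.mask]).astype(int)
    unknown = [c for c in seen if c not in mapping]
    if unknown:
        raise ValueError(f"unknown soil-texture codes {unknown}; mapped: {sorted(mapping)}")
    for code, grade in mapping.items():
        out[v == code] = grade
    return GradedFactor(grid.copy(out), "soil_texture")


def slope_degrees(dem: Grid) -> Grid:
    """Slope in degrees from a DEM by Horn's method on the 3x3 neighbourhood."""
    z = np.where(dem.mask, dem.values, np.nan)
    # pad with edge replication so border cells get a defined gradient
    zp = np.pad(z, 1, mode="edge")
    cs = dem.cellsize
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[~dem.mask] = np.nan
    return dem.copy(slope)


# ---------------------------------------------------------------------------
# Sensitivity indices (on graded layers)


def _geometric_mean4(*factors: GradedFactor) -> Grid:
    a, b, c, d = factors
    a.grid.require_aligned(b.grid, c.grid, d.grid)
    prod = a.grid.values * b.grid.values * c.grid.values * d.grid.values
    return a.grid.copy(prod ** 0.25)


def sswl(r: GradedFactor, k: GradedFactor, ls: GradedFactor, c: GradedFactor) -> Grid:
    """Soil-and-water-loss sensitivity: 4th root of R*K*LS*C grades; in [1, 9]."""
    return _geometric_mean4(r, k, ls, c)


def sse(ls: GradedFactor, r: GradedFactor, k: GradedFactor, c: GradedFactor) -> Grid:
    """Soil-erosion sensitivity: arithmetic mean of the four grades; in [1, 9]."""
    ls.grid.require_aligned(r.grid, k.grid, c.grid)
    mean = (ls.grid.values + r.grid.values + k.grid.values + c.grid.values) / 4.0
    return ls.grid.copy(mean)


def sld(i: GradedFactor, w: GradedFactor, k: GradedFactor, c: GradedFactor) -> Grid:
    """Land-desertification sensitivity: 4th root of I*W*K*C grades; in [1, 9]."""
    return _geometric_mean4(i, w, k, c)


def _convex_combine(grids: Sequence[Grid], weights: Sequence[float]) -> Grid:
    if len(grids) != len(weights):
        raise ValueError("one weight per layer required")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    total = sum(weights)
    if abs(total - 1.0) > 1e-6:
        log.warning("composite weights sum to %.6f, not 1; using as given", total)
    grids[0].require_aligned(*grids[1:])
    out = np.zeros(grids[0].shape)
    for g, w in zip(grids, weights):
        out = out + w * g.values
    return grids[0].copy(out)


def composite_sensitivity(layers: SensitivityLayers) -> Grid:
    """Weighted overlay of SSWL, SSE, SLD (defaults 0.43/0.39/0.18)."""
    comp = _convex_combine([layers.sswl, layers.sse, layers.sld], layers.weights)
    layers.composite = comp
    return comp


# ---------------------------------------------------------------------------
# Service-importance indices (on [0,1]-normalized inputs)


def _check_unit_interval(name: str, grid: Grid) -> None:
    vals = grid.valid_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError(f"{name} must be normalized to [0, 1]; "
                         f"range is [{vals.min():.4g}, {vals.max():.4g}]")


def water_retention(npp: Grid, fsic: Grid, fpre: Grid, fsio: Grid) -> Grid:
    """WR = NPPmean * Fsic * Fpre * (1 - Fsio), all inputs in [0, 1]."""
    npp.require_aligned(fsic, fpre, fsio)
    for name, g in (("NPPmean", npp), ("Fsic", fsic), ("Fpre", fpre), ("Fsio", fsio)):
        _check_unit_interval(name, g)
    return npp.copy(npp.values * fsic.values * fpre.values * (1 - fsio.values))


def soil_conservation(npp: Grid, k_norm: Grid, fsio: Grid) -> Grid:
    """Spro = NPPmean * (1 - K) * (1 - Fsio), all inputs in [0, 1]."""
    npp.require_aligned(k_norm, fsio)
    for name, g in (("NPPmean", npp), ("K", k_norm), ("Fsio", fsio)):
        _check_unit_interval(name, g)
    return npp.copy(npp.values * (1 - k_norm.values) * (1 - fsio.values))


def biodiversity_service(npp: Grid, fpre: Grid, ftem: Grid, falt: Grid) -> Grid:
    """Sbio = NPPmean * Fpre * Ftem * (1 - Falt), all inputs in [0, 1]."""
    npp.require_aligned(fpre, ftem, falt)
    for name, g in (("NPPmean", npp), ("Fpre", fpre), ("Ftem", ftem), ("Falt", falt)):
        _check_unit_interval(name, g)
    return npp.copy(npp.values * fpre.values * ftem.values * (1 - falt.values))


def composite_importance(layers: ServiceLayers) -> Grid:
    """Weighted overlay of WR, Spro, Sbio (defaults 0.45/0.30/0.25)."""
    comp = _convex_combine([layers.wr, layers.spro, layers.sbio], layers.weights)
    layers.composite = comp
    return comp


# ---------------------------------------------------------------------------
# Superposition and classification


def superpose_environment(
    sensitivity: Grid,
    importance: Grid,
    weights: tuple[float, float] = (0.5, 0.5),
    n_classes: int = 5,
) -> EcoAssessment:
    """Integrated ecological-environment evaluation.

    Both composites are min-max normalized (so the superposition is
    scale-free), combined with the given weights (equal by default), and
    each of the three scores is classified into ``n_classes`` levels by
    natural breaks.  Class ``n_classes`` holds the most sensitive / most
    important / extremely-important cells.
    """
    sensitivity.require_aligned(importance)
    sens_n = minmax_normalize(sensitivity)
    imp_n = minmax_normalize(importance)
    ws, wi = weights
    score = sensitivity.copy(ws * sens_n.values + wi * imp_n.values)

    def _five_class(g: Grid) -> Grid:
        return classify(g, grid_jenks_breaks(g, n_classes))

    return EcoAssessment(
        sensitivity_class=_five_class(sensitivity),
        importance_class=_five_class(importance),
        environment_class=_five_class(score),
        environment_score=score,
    )
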