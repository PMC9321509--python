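"""Synthetic landscape bundles and deterministic micro-fixtures.

The generator emulates the statistical structure of the pipeline's real
inputs for a subtropical monsoon river basin: a spatially autocorrelated
DEM with a northwest-high / southeast-low trend, ~1700 mm of annual
rainfall distributed over a seasonal monthly profile and correlated with
elevation, NPP and vegetation coverage positively correlated with each
other and depressed near roads, patchy soil-texture classes, a land-use
mosaic with a forest/grass majority (~80% of cells) and construction
clustered along roads, plus a few road polylines crossing the grid.

High-value habitat patches are *planted*: inside a handful of circular
blobs rainfall, aridity, sand-blowing days and NPP are raised so the
downstream assessment marks them extremely important — the generator
records their centres so structure-recovery tests can check that source
extraction finds them.

All randomness flows from one seeded generator passed explicitly; the same
seed reproduces the bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import Grid, euclidean_distance, rasterize_segments, write_grid, write_segments
from .resistance import LANDUSE_CODES

__all__ = ["LandscapeBundle", "make_landscape", "make_fixture", "FIXTURES"]

ANNUAL_PRECIP_MM = 1700.0
#: fraction of annual rain falling in each month (subtropical monsoon: wet
#: season April-September); sums to 1
MONTH_SHARE = np.array([0.03, 0.045, 0.075, 0.10, 0.13, 0.15,
                        0.13, 0.11, 0.09, 0.06, 0.045, 0.035])
MONTH_SHARE = MONTH_SHARE / MONTH_SHARE.sum()

N_PLANTED_PATCHES = 6
PATCH_RADIUS_CELLS = 5

Segment = tuple[float, float, float, float]


@dataclass
class LandscapeBundle:
    dem: Grid
    monthly_precip: list[Grid]
    npp: Grid
    temperature: Grid
    aridity: Grid
    wind_days: Grid
    soil_texture: Grid
    landuse: Grid
    vegcover: Grid
    county_roads: list[Segment]
    highways: list[Segment]
    truth: dict = dataclass_field(default_factory=dict)

    def grids(self) -> dict[str, Grid]:
        named = {"dem": self.dem, "npp": self.npp, "temperature": self.temperature,
                 "aridity": self.aridity, "wind_days": self.wind_days,
                 "soil_texture": self.soil_texture, "landuse": self.landuse,
                 "vegcover": self.vegcover}
        for m, g in enumerate(self.monthly_precip, start=1):
            named[f"precip_{m:02d}"] = g
        return named

    def save(self, directory: str | Path, format: str = "ascii_grid") -> None:
        import yaml

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        suffix = ".tif" if format == "geotiff" else ".asc"
        for name, g in self.grids().items():
            write_grid(g, directory / f"{name}{suffix}", format)
        write_segments(self.county_roads, directory / "county_roads.txt")
        write_segments(self.highways, directory / "highways.txt")
        manifest = dict(self.truth)
        manifest["format"] = format
        (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized spatially autocorrelated field (truncated Gaussian kernel)."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect",
                                truncate=3.0)
    return (f - f.mean()) / f.std()


def _polyline_segments(points) -> list[Segment]:
    return [(x1, y1, x2, y2) for (x1, y1), (x2, y2) in zip(points, points[1:])]


def make_landscape(
    seed: int,
    n_rows: int = 200,
    n_cols: int = 200,
    cellsize: float = 1000.0,
    n_patches: int = N_PLANTED_PATCHES,
    patch_radius: int = PATCH_RADIUS_CELLS,
) -> LandscapeBundle:
    """Generate a complete, aligned synthetic input bundle.

    ``cellsize`` is in metres; the default 200 x 200 km at 1 km resolution
    matches the analysis scale the pipeline is designed for.
    """
    if n_rows < 32 or n_cols < 32:
        raise ValueError("landscape must be at least 32 x 32 cells")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    origin = (0.0, n_rows * cellsize)

    def as_grid(a: np.ndarray) -> Grid:
        return Grid(a.astype(float), cellsize, origin)

    rows = np.arange(n_rows)[:, None] / max(n_rows - 1, 1)
    cols = np.arange(n_cols)[None, :] / max(n_cols - 1, 1)

    # --- terrain: NW-high / SE-low trend plus two scales of roughness
    trend = 1.0 - (rows + cols) / 2.0          # 1 at NW corner, 0 at SE
    dem = (1500.0 * trend
           + 450.0 * _smooth_field(rng, shape, 10.0)
           + 120.0 * _smooth_field(rng, shape, 3.0))
    rough = 45.0 * _smooth_field(rng, shape, 1.5)  # planted patches are rugged
    dem -= dem.min()
    dem_norm = (dem - dem.min()) / (dem.max() - dem.min())

    # --- roads: one highway west-east with bends, two county roads
    width, height = n_cols * cellsize, n_rows * cellsize

    def road_across(axis: str) -> list[Segment]:
        n_knots = 4
        if axis == "x":
            xs = np.linspace(0, width, n_knots)
            ys = rng.uniform(0.25, 0.75, n_knots) * height
        else:
            ys = np.linspace(0, height, n_knots)
            xs = rng.uniform(0.25, 0.75, n_knots) * width
        return _polyline_segments(list(zip(xs, ys)))

    highways = road_across("x")
    county_roads = road_across("y") + road_across("y")
    template = as_grid(np.zeros(shape))
    dist_road = np.minimum(
        euclidean_distance(template, highways).values,
        euclidean_distance(template, county_roads).values)

    # --- planted high-value patches, kept clear of edges and roads
    centers: list[tuple[int, int]] = []
    margin = patch_radius + 3
    attempts = 0
    while len(centers) < n_patches and attempts < 5000:
        attempts += 1
        r = int(rng.integers(margin, n_rows - margin))
        c = int(rng.integers(margin, n_cols - margin))
        if dist_road[r, c] < (patch_radius + 2) * cellsize:
            continue
        if any(np.hypot(r - r0, c - c0) < 4 * patch_radius for r0, c0 in centers):
            continue
        centers.append((r, c))
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    blob = np.zeros(shape)
    for r0, c0 in centers:
        d = np.hypot(rr - r0, cc - c0)
        # flat plateau out to the nominal radius, then a short linear skirt:
        # the planted object is a coherent habitat patch, not a peak
        blob = np.maximum(blob, np.clip((1.5 * patch_radius - d)
                                        / (0.5 * patch_radius), 0.0, 1.0))

    # --- rainfall: seasonal profile around ~1700 mm/yr, wetter at altitude
    annual = ANNUAL_PRECIP_MM * (
        1.0
        + 0.18 * (dem_norm - dem_norm.mean())
        + 0.08 * _smooth_field(rng, shape, 8.0)
        + 0.35 * blob
    )
    annual = np.clip(annual, 400.0, None)
    monthly = [as_grid(annual * share) for share in MONTH_SHARE]

    # --- temperature: lapse with elevation
    temperature = as_grid(20.0 - 0.005 * dem + 0.8 * _smooth_field(rng, shape, 8.0))

    # --- aridity index and sand-blowing days (desertification drivers)
    aridity = (0.62
               - 0.25 * (annual / ANNUAL_PRECIP_MM - 1.0)
               + 0.08 * _smooth_field(rng, shape, 6.0)
               + 0.30 * blob)
    aridity = as_grid(np.clip(aridity, 0.2, 1.0))
    wind = (130.0 + 60.0 * _smooth_field(rng, shape, 6.0) + 140.0 * blob)
    wind_days = as_grid(np.clip(wind, 20.0, 330.0))

    # --- soil texture: patchy categorical field of USDA class codes
    tex_field = _smooth_field(rng, shape, 5.0)
    tex_codes = (6, 7, 5, 9, 11, 13)       # silt ... sand, patchy mosaic
    tex_edges = np.quantile(tex_field, np.linspace(0, 1, len(tex_codes) + 1)[1:-1])
    soil = np.asarray(tex_codes)[np.searchsorted(tex_edges, tex_field)].astype(float)
    core = blob > 0.7
    soil[core] = 13.0  # planted patches sit on erodible sandy soil
    soil_texture = as_grid(soil)
    dem = dem + np.where(core, np.abs(rough) + 40.0, 0.0)

    # --- land use: forest/grass majority, construction along roads, a river
    lu_field = _smooth_field(rng, shape, 4.0)
    lu = np.full(shape, LANDUSE_CODES["forest_grass"], dtype=float)
    lowland = dem_norm + 0.15 * _smooth_field(rng, shape, 6.0)
    cult_cut = np.quantile(lowland, 0.16)
    lu[lowland <= cult_cut] = LANDUSE_CODES["cultivated"]
    near_road = dist_road < 2.0 * cellsize
    constr_cut = np.quantile(lu_field[near_road], 0.45) if near_road.any() else np.inf
    lu[near_road & (lu_field > constr_cut)] = LANDUSE_CODES["construction"]
    bare_cut = np.quantile(lu_field, 0.997)
    lu[lu_field > bare_cut] = LANDUSE_CODES["bare"]
    river = road_across("x")
    river_mask = rasterize_segments(template, river)
    lu[river_mask] = LANDUSE_CODES["water"]
    landuse = as_grid(lu)

    # --- vegetation coverage, tied to land use and road proximity
    veg_noise = _smooth_field(rng, shape, 5.0)
    veg = np.where(lu == LANDUSE_CODES["forest_grass"], 0.82 + 0.07 * veg_noise,
          np.where(lu == LANDUSE_CODES["cultivated"], 0.55 + 0.10 * veg_noise,
          np.where(lu == LANDUSE_CODES["construction"], 0.15 + 0.08 * veg_noise,
          np.where(lu == LANDUSE_CODES["water"], 0.05,
                   0.10 + 0.05 * veg_noise))))
    veg = veg - 0.10 * np.exp(-dist_road / (3.0 * cellsize))
    # planted patches are sparse grass/shrub habitat: moderate coverage
    veg[core] = np.clip(0.62 + 0.05 * veg_noise[core], 0.56, 0.74)
    vegcover = as_grid(np.clip(veg, 0.0, 1.0))

    # --- NPP: follows coverage and rainfall, depressed near roads, planted boost
    npp = (250.0
           + 650.0 * vegcover.values
           + 0.12 * (annual - ANNUAL_PRECIP_MM)
           - 180.0 * np.exp(-dist_road / (2.0 * cellsize))
           + 60.0 * _smooth_field(rng, shape, 6.0))
    npp = npp * (1.0 + 1.2 * blob)
    npp = as_grid(np.clip(npp, 10.0, None))

    truth = {
        "seed": int(seed),
        "n_rows": n_rows, "n_cols": n_cols, "cellsize": float(cellsize),
        "patch_centers": [[int(r), int(c)] for r, c in centers],
        "patch_radius_cells": int(patch_radius),
        "annual_precip_mm": float(annual.mean()),
    }
    return LandscapeBundle(
        dem=as_grid(dem), monthly_precip=monthly, npp=npp,
        temperature=temperature, aridity=aridity, wind_days=wind_days,
        soil_texture=soil_texture, landuse=landuse, vegcover=vegcover,
        county_roads=county_roads, highways=highways, truth=truth,
    )


# ---------------------------------------------------------------------------
# Hand-written micro-fixtures with exactly known answers


def _fixture_two_patches_300m() -> Grid:
    """12x12 class grid, cellsize 100 m: two class-5 patches 300 m apart."""
    v = np.ones((12, 12))
    v[4:8, 1:4] = 5          # patch A: cols 1-3
    v[4:8, 6:9] = 5          # patch B: cols 6-8 -> nearest centres 300 m apart
    return Grid(v, 100.0)


def _fixture_uniform_surface() -> Grid:
    """10x10 uniform resistance 2.0, cellsize 100 m."""
    return Grid(np.full((10, 10), 2.0), 100.0)


def _fixture_bottleneck_neck() -> Grid:
    """Two 7x4 rooms joined by a single-cell neck; resistance 1, cellsize 100 m.

    Everything outside the rooms and the neck is nodata, so all current
    between the rooms must squeeze through row 3, cols 4-6.
    """
    v = np.full((7, 11), np.nan)
    v[:, 0:4] = 1.0
    v[:, 7:11] = 1.0
    v[3, 4:7] = 1.0
    return Grid(v, 100.0)


def _fixture_jenks_six_values() -> Grid:
    """2x3 grid holding {1,2,3,10,11,12}: optimal 2-class cut between 3 and 10."""
    return Grid(np.array([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]), 100.0)


def _fixture_table1_band_probe() -> Grid:
    """1x5 rainfall-erosivity probe hitting each sensitivity grade once."""
    return Grid(np.array([[500.0, 550.0, 570.0, 590.0, 650.0]]), 1000.0)


FIXTURES = {
    "two_patches_300m": _fixture_two_patches_300m,
    "uniform_surface": _fixture_uniform_surface,
    "bottleneck_neck": _fixture_bottleneck_neck,
    "jenks_six_values": _fixture_jenks_six_values,
    "table1_band_probe": _fixture_table1_band_probe,
}


def make_fixture(name: str) -> Grid:
    """A tiny deterministic grid from the documented catalogue."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; catalogue: {sorted(FIXTURES)}")
    return FIXTURES[name]()
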