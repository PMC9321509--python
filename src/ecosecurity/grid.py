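"""Raster data model and shared spatial primitives.

The :class:`Grid` is the universal currency of the pipeline: a georeferenced
2D array of cell values on square cells, with a nodata sentinel.  All
multi-grid operations (overlay, index formulas, superposition) require the
operands to be *aligned*: identical shape, cell size and top-left origin.

Internally nodata is represented as NaN so that ordinary array arithmetic
propagates it; the sentinel value only appears on disk.

Conventions: row 0 is the northern edge, cell values refer to cell centres,
and areas are counted as ``cells x cellsize**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "BreakSet",
    "read_grid",
    "write_grid",
    "read_segments",
    "write_segments",
    "focal_range",
    "euclidean_distance",
    "minmax_normalize",
    "jenks_breaks",
    "classify",
    "idw_interpolate",
]

DEFAULT_NODATA = -9999.0

#: non-nodata cell count above which natural-breaks classification switches
#: to a deterministic row-major stride subsample of this many values
JENKS_SUBSAMPLE = 10_000


class GridFormatError(ValueError):
    """Raised for unreadable, malformed or unsupported raster files."""


class AlignmentError(ValueError):
    """Raised when a multi-grid operation receives misaligned grids."""


@dataclass
class Grid:
    """A georeferenced square-cell raster.

    Parameters
    ----------
    values
        2D array; nodata cells are NaN.
    cellsize
        Cell edge length in metres (> 0); cells are square.
    origin
        Map coordinates ``(x, y)`` of the *top-left corner* of the grid.
    nodata
        Sentinel written to / read from disk for NaN cells.
    """

    values: np.ndarray
    cellsize: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-dimensional")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        return ~np.isnan(self.values)

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        """A deep copy, optionally with replacement values on the same geometry."""
        v = self.values.copy() if values is None else np.asarray(values, dtype=float)
        return Grid(v, self.cellsize, self.origin, self.nodata)

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.allclose(self.origin, other.origin)
        )

    def require_aligned(self, *others: "Grid") -> None:
        for g in others:
            if not self.aligned_with(g):
                raise AlignmentError(
                    f"grids are not aligned: {self.shape}@{self.origin} vs "
                    f"{g.shape}@{g.origin}"
                )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell centre, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cellsize
        y = y0 - (rows + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def cell_area_km2(self) -> float:
        return self.cellsize**2 / 1e6

    def valid_values(self) -> np.ndarray:
        """All non-nodata values as a flat array (row-major order)."""
        return self.values[self.mask]


@dataclass
class BreakSet:
    """A k-class contiguous partition of a value range.

    ``breaks`` holds the k-1 interior cut values in ascending order; class i
    (1-based, 1 = lowest) is ``breaks[i-2] < x <= breaks[i-1]`` with open
    ends below the first and above the last cut.
    """

    k: int
    breaks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.breaks) != self.k - 1:
            raise ValueError("a k-class BreakSet needs k-1 interior breaks")
        if any(b >= c for b, c in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly ascending")

    @property
    def labels(self) -> list[int]:
        return list(range(1, self.k + 1))

    def classify_value(self, x: float) -> int:
        return 1 + int(np.searchsorted(np.asarray(self.breaks), x, side="left"))


# ---------------------------------------------------------------------------
# I/O

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not rows and key in _ASCII_HEADER_KEYS + ("nodata_value",):
                try:
                    header[key] = float(tokens[1])
                except (IndexError, ValueError) as exc:
                    raise GridFormatError(f"bad header line {line!r}") from exc
            else:
                try:
                    rows.append([float(t) for t in tokens])
                except ValueError as exc:
                    raise GridFormatError(f"non-numeric data line {line!r}") from exc
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"missing header keys: {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.array(rows, dtype=float) if rows else np.empty((0, 0))
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"body shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    values[values == nodata] = np.nan
    cellsize = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cellsize)
    return Grid(values, cellsize, origin, nodata)


def _write_ascii_grid(grid: Grid, path: Path) -> None:
    vals = np.where(grid.mask, grid.values, grid.nodata)
    integral = np.all(vals == np.round(vals))
    x0, ytop = grid.origin
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.n_cols}\n")
        fh.write(f"NROWS {grid.n_rows}\n")
        fh.write(f"XLLCORNER {x0:.6f}\n")
        fh.write(f"YLLCORNER {ytop - grid.n_rows * grid.cellsize:.6f}\n")
        fh.write(f"CELLSIZE {grid.cellsize:.6f}\n")
        nd = grid.nodata
        fh.write(f"NODATA_value {int(nd) if nd == int(nd) else nd}\n")
        fmt = "%d" if integral else "%.10g"
        np.savetxt(fh, vals, fmt=fmt)


# GeoTIFF tag ids: pixel scale, tiepoint, GDAL nodata
_TAG_SCALE, _TAG_TIEPOINT, _TAG_NODATA = 33550, 33922, 42113


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            scale = tags[_TAG_SCALE].value if _TAG_SCALE in tags else None
            tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else None
            nodata_tag = tags[_TAG_NODATA].value if _TAG_NODATA in tags else None
    except (tifffile.TiffFileError, OSError) as exc:
        raise GridFormatError(f"cannot read {path}: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError("only single-band rasters are supported")
    if scale is None or tie is None:
        raise GridFormatError("missing georeferencing tags")
    sx, sy = scale[:2]
    if not np.isclose(sx, sy):
        raise GridFormatError(f"non-square cells: {sx} x {sy}")
    origin = (tie[3] - tie[0] * sx, tie[4] + tie[1] * sy)
    nodata = DEFAULT_NODATA if nodata_tag is None else float(nodata_tag)
    values[values == nodata] = np.nan
    return Grid(values, float(sx), origin, nodata)


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    vals = np.where(grid.mask, grid.values, grid.nodata)
    integral = np.all(vals == np.round(vals)) and np.all(np.abs(vals) < 2**31)
    out = vals.astype(np.int32) if integral else vals.astype(np.float32)
    nd = grid.nodata
    nodata_str = (str(int(nd)) if nd == int(nd) else repr(nd)) + "\x00"
    extratags = [
        (_TAG_SCALE, "d", 3, (grid.cellsize, grid.cellsize, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_NODATA, "s", len(nodata_str), nodata_str),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


_FORMATS = {"ascii_grid": (_read_ascii_grid, _write_ascii_grid),
            "geotiff": (_read_geotiff, _write_geotiff)}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise GridFormatError(f"unknown format {format!r}; use {sorted(_FORMATS)}")
        return format
    suffix = path.suffix.lower()
    return "geotiff" if suffix in (".tif", ".tiff") else "ascii_grid"


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a raster from GeoTIFF or Esri ASCII grid.

    The format is inferred from the suffix (``.tif``/``.tiff`` vs anything
    else) unless given explicitly.  Cells equal to the file's nodata
    sentinel come back as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such file: {path}")
    reader, _ = _FORMATS[_infer_format(path, format)]
    return reader(path)


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write a raster; all-integral value grids are stored as integers."""
    path = Path(path)
    _, writer = _FORMATS[_infer_format(path, format)]
    writer(grid, path)


def read_segments(path: str | Path) -> list[tuple[float, float, float, float]]:
    """Read line features: one ``x1 y1 x2 y2`` segment per line, map units."""
    segments = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) != 4:
                raise GridFormatError(f"expected 'x1 y1 x2 y2', got {line!r}")
            segments.append(tuple(float(t) for t in tokens))
    return segments


def write_segments(segments: Iterable[Sequence[float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(" ".join(f"{v:.6f}" for v in seg) + "\n")


# ---------------------------------------------------------------------------
# Focal and distance operations


def focal_range(grid: Grid, window: int) -> Grid:
    """Per-cell max minus min over a ``window x window`` neighbourhood.

    Edge windows are truncated to the grid; nodata cells are excluded from
    the extremes.  Cells that are themselves nodata stay nodata.  Used for
    topographic relief (the landform roughness factor).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    hi = np.where(grid.mask, grid.values, -np.inf)
    lo = np.where(grid.mask, grid.values, np.inf)
    vmax = ndimage.maximum_filter(hi, size=window, mode="constant", cval=-np.inf)
    vmin = ndimage.minimum_filter(lo, size=window, mode="constant", cval=np.inf)
    rng = vmax - vmin
    rng[~np.isfinite(rng)] = np.nan
    rng[~grid.mask] = np.nan
    return grid.copy(rng)


def rasterize_segments(
    template: Grid, segments: Iterable[Sequence[float]]
) -> np.ndarray:
    """Boolean mask of template cells touched by any line segment.

    Segments are sampled at quarter-cell spacing and each sample snapped to
    the containing cell; adequate for distance rasters at analysis scale.
    """
    marked = np.zeros(template.shape, dtype=bool)
    x0, y0 = template.origin
    cs = template.cellsize
    for x1, y1, x2, y2 in segments:
        length = float(np.hypot(x2 - x1, y2 - y1))
        n = max(2, int(np.ceil(length / (cs / 4))) + 1)
        xs = np.linspace(x1, x2, n)
        ys = np.linspace(y1, y2, n)
        cols = np.floor((xs - x0) / cs).astype(int)
        rows = np.floor((y0 - ys) / cs).astype(int)
        ok = (rows >= 0) & (rows < template.n_rows) & (cols >= 0) & (cols < template.n_cols)
        marked[rows[ok], cols[ok]] = True
    return marked


def euclidean_distance(
    template: Grid,
    features: Iterable[Sequence[float]] | np.ndarray,
) -> Grid:
    """Metres from each cell centre to the nearest feature.

    ``features`` is either a list of ``(x1, y1, x2, y2)`` segments (rasterized
    onto the template first) or a boolean mask of marked cells.
    """
    if isinstance(features, np.ndarray) and features.dtype == bool:
        marked = features
    else:
        features = list(features)
        if not features:
            raise ValueError("at least one feature is required")
        marked = rasterize_segments(template, features)
    if not marked.any():
        raise ValueError("no feature falls inside the grid")
    dist = ndimage.distance_transform_edt(~marked, sampling=template.cellsize)
    return template.copy(dist)


def minmax_normalize(grid: Grid) -> Grid:
    """Affine rescale of the valid cells to [0, 1]; nodata untouched."""
    vals = grid.valid_values()
    if vals.size == 0:
        raise ValueError("grid has no valid cells")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant grid")
    return grid.copy((grid.values - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Natural breaks (Fisher-Jenks optimal 1D classification)


def _interval_sse(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    """Within-class sum of squared deviations of sorted[i:j] via prefix sums."""
    n = j - i
    s = s1[j] - s1[i]
    return float(s2[j] - s2[i] - s * s / n)


def _dnc_layer(prev: np.ndarray, s1: np.ndarray, s2: np.ndarray,
               cur: np.ndarray, arg: np.ndarray,
               jlo: int, jhi: int, ilo: int, ihi: int) -> None:
    # divide-and-conquer over the concave-Monge DP layer:
    # cur[j] = min_{i} prev[i] + SSE(i, j), optimal i monotone in j
    if jlo > jhi:
        return
    jm = (jlo + jhi) // 2
    best, besti = np.inf, ilo
    for i in range(ilo, min(ihi, jm - 1) + 1):
        c = prev[i] + _interval_sse(s1, s2, i, jm)
        if c < best:
            best, besti = c, i
    cur[jm], arg[jm] = best, besti
    _dnc_layer(prev, s1, s2, cur, arg, jlo, jm - 1, ilo, besti)
    _dnc_layer(prev, s1, s2, cur, arg, jm + 1, jhi, besti, ihi)


def jenks_breaks(values: Iterable[float], k: int) -> BreakSet:
    """Optimal k-class natural-breaks partition of a set of values.

    Finds the contiguous partition of the sorted values into k classes
    minimizing total within-class sum of squared deviations (the Fisher
    dynamic program, exact and deterministic).  Interior break values are
    the upper edge (maximum) of each class but the last.

    Raises ``ValueError`` when there are fewer distinct values than classes.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    v = v[~np.isnan(v)]
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(v).size
    if n_distinct < k:
        raise ValueError(f"need at least {k} distinct values, got {n_distinct}")
    if k == 1:
        return BreakSet(1, [])
    n = v.size
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    # layer 1: single class prefix costs
    prev = np.array([_interval_sse(s1, s2, 0, j) if j else 0.0 for j in range(n + 1)])
    splits = np.zeros((k, n + 1), dtype=int)
    for level in range(2, k + 1):
        cur = np.full(n + 1, np.inf)
        arg = np.zeros(n + 1, dtype=int)
        _dnc_layer(prev, s1, s2, cur, arg, level, n, level - 1, n - 1)
        splits[level - 1] = arg
        prev = cur

    # backtrack split positions; cut between v[pos-1] and v[pos]
    cuts = []
    j = n
    for level in range(k, 1, -1):
        j = int(splits[level - 1][j])
        cuts.append(j)
    cuts.reverse()
    breaks = []
    for pos in cuts:
        b = float(v[pos - 1])
        # guard against duplicate break values when classes share an edge value
        if breaks and b <= breaks[-1]:
            b = np.nextafter(breaks[-1], np.inf)
        breaks.append(b)
    return BreakSet(k, breaks)


def grid_jenks_breaks(grid: Grid, k: int, max_sample: int = JENKS_SUBSAMPLE) -> BreakSet:
    """Natural breaks for a raster; large grids use a deterministic subsample.

    When the valid cell count exceeds ``max_sample``, breaks are computed on
    a uniform row-major stride subsample of that size (no randomness), which
    keeps classification reproducible and fast on big rasters.
    """
    vals = grid.valid_values()
    if vals.size > max_sample:
        stride = int(np.ceil(vals.size / max_sample))
        vals = vals[::stride]
    return jenks_breaks(vals, k)


def classify(grid: Grid, breaks: BreakSet) -> Grid:
    """Map a value raster to integer classes 1..k using a BreakSet.

    Values at or below the first break fall in class 1; values above the
    last break fall in class k.  Nodata propagates.
    """
    out = 1.0 + np.searchsorted(np.asarray(breaks.breaks), grid.values, side="left")
    out[~grid.mask] = np.nan
    return grid.copy(out)


# ---------------------------------------------------------------------------
# Station interpolation utility (not on any tested analysis path)


def idw_interpolate(
    template: Grid,
    stations: Sequence[tuple[float, float, float]],
    power: float = 2.0,
) -> Grid:
    """Inverse-distance-weighted surface from (x, y, value) stations."""
    if not stations:
        raise ValueError("at least one station is required")
    xs, ys = template.cell_centers()
    num = np.zeros(template.shape)
    den = np.zeros(template.shape)
    out = np.full(template.shape, np.nan)
    exact = np.zeros(template.shape, dtype=bool)
    for sx, sy, sv in stations:
        d = np.hypot(xs - sx, ys - sy)
        at = d == 0
        exact |= at
        out[at] = sv
        with np.errstate(divide="ignore"):
            w = d**-power
        w[at] = 0
        num += w * sv
        den += w
    fill = ~exact
    out[fill] = num[fill] / den[fill]
    return template.copy(out)
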