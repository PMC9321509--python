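"""Ecological-source identification from the extremely-important class.

Sources anchor the security pattern: connected patches of the top
assessment class are aggregated when closer than a gap threshold (500 m by
default, edge to edge) and kept when larger than a minimum area (8 km^2 by
default, strict).  Merged sources stay multi-part — gap cells remain
background — so area and land-use statistics are not inflated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grid import Grid

__all__ = [
    "Patch",
    "PatchSet",
    "SourceSet",
    "label_patches",
    "merge_nearby",
    "filter_by_area",
    "landuse_composition",
    "patch_min_distance",
    "sources_to_geojson",
]

DEFAULT_MERGE_GAP_M = 500.0
DEFAULT_MIN_AREA_KM2 = 8.0


@dataclass
class Patch:
    id: int
    n_cells: int
    area_km2: float
    bbox: tuple[int, int, int, int]  # row0, col0, row1, col1 (inclusive)


@dataclass
class PatchSet:
    """Labelled patches on a grid; label 0 is background."""

    label_grid: Grid
    patches: list[Patch] = field(default_factory=list)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def total_area_km2(self) -> float:
        return sum(p.area_km2 for p in self.patches)

    def patch_mask(self, patch_id: int) -> np.ndarray:
        return self.label_grid.values == patch_id


@dataclass
class SourceSet(PatchSet):
    """Patches surviving the area filter, with land-use composition."""

    landuse_composition: dict[int, dict[str, float]] = field(default_factory=dict)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def _build_patchset(label_array: np.ndarray, template: Grid) -> PatchSet:
    cell_area = template.cell_area_km2()
    patches = []
    for pid in range(1, int(label_array.max()) + 1):
        mask = label_array == pid
        n = int(mask.sum())
        rows, cols = np.nonzero(mask)
        patches.append(Patch(pid, n, n * cell_area,
                             (int(rows.min()), int(cols.min()),
                              int(rows.max()), int(cols.max()))))
    lab = template.copy(label_array.astype(float))
    lab.values[~template.mask] = np.nan
    return PatchSet(lab, patches)


def label_patches(class_grid: Grid, target_class: int, connectivity: int = 8) -> PatchSet:
    """Connected components of cells equal to ``target_class``.

    Diagonal contact counts under the default 8-connectivity (the usual
    convention for landscape patch delineation).  An absent class yields an
    empty PatchSet, not an error.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    fg = (class_grid.values == target_class)
    labels, _ = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    return _build_patchset(labels, class_grid)


def patch_min_distance(patches: PatchSet, id_a: int, id_b: int) -> float:
    """Minimum edge-to-edge distance in metres between two patches.

    Distance between the nearest cell *centres* of the two patches; two
    orthogonally adjacent cells are one cellsize apart.
    """
    cs = patches.label_grid.cellsize
    dist = ndimage.distance_transform_edt(~patches.patch_mask(id_a), sampling=cs)
    return float(dist[patches.patch_mask(id_b)].min())


def merge_nearby(patches: PatchSet, max_gap: float = DEFAULT_MERGE_GAP_M) -> PatchSet:
    """Union patches transitively whenever their gap is strictly < ``max_gap``.

    Union-find over the pairwise distance predicate; merged patches keep
    only their member cells (area = sum of member areas).  Idempotent, and
    monotone in ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n = patches.n_patches
    if n <= 1:
        return patches
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    cs = patches.label_grid.cellsize
    labels = patches.label_grid.values
    # one distance transform per patch, probed against all higher-id patches
    for pid in range(1, n):
        dist = ndimage.distance_transform_edt(labels != pid, sampling=cs)
        for qid in range(pid + 1, n + 1):
            if dist[labels == qid].min() < max_gap:
                ra, rb = find(pid), find(qid)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    roots = sorted({find(pid) for pid in range(1, n + 1)})
    remap = {root: i + 1 for i, root in enumerate(roots)}
    out = np.zeros_like(labels)
    for pid in range(1, n + 1):
        out[labels == pid] = remap[find(pid)]
    return _build_patchset(out.astype(int), patches.label_grid)


def filter_by_area(
    patches: PatchSet, min_area_km2: float = DEFAULT_MIN_AREA_KM2
) -> SourceSet:
    """Keep patches strictly larger than the area threshold.

    Survivors are relabelled densely from 1 in order of descending area
    (ties broken by original label).  An empty result is allowed.
    """
    if min_area_km2 < 0:
        raise ValueError("min_area_km2 must be >= 0")
    keep = [p for p in patches.patches if p.area_km2 > min_area_km2]
    keep.sort(key=lambda p: (-p.area_km2, p.id))
    labels = patches.label_grid.values
    out = np.zeros(labels.shape)
    new_patches = []
    for new_id, p in enumerate(keep, start=1):
        out[labels == p.id] = new_id
        new_patches.append(Patch(new_id, p.n_cells, p.area_km2, p.bbox))
    lab = patches.label_grid.copy(out)
    return SourceSet(lab, new_patches)


def landuse_composition(
    sources: SourceSet,
    landuse: Grid,
    class_names: Mapping[int, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-land-use-class area (km^2) and percentage over all source cells."""
    sources.label_grid.require_aligned(landuse)
    in_source = sources.label_grid.values > 0
    codes = landuse.values[in_source & landuse.mask]
    cell_area = landuse.cell_area_km2()
    total = codes.size * cell_area
    table: dict[str, dict[str, float]] = {}
    for code in np.unique(codes):
        name = (class_names or {}).get(int(code), str(int(code)))
        area = float((codes == code).sum()) * cell_area
        table[name] = {"area_km2": area,
                       "percent": 100.0 * area / total if total else 0.0}
    sources.landuse_composition = {  # keyed by class code for programmatic use
        int(c): {"area_km2": float((codes == c).sum()) * cell_area,
                 "percent": 100.0 * (codes == c).sum() / codes.size if codes.size else 0.0}
        for c in np.unique(codes)
    }
    return table


def sources_to_geojson(sources: SourceSet, path: str | Path | None = None) -> dict:
    """Export sources as a GeoJSON FeatureCollection of (multi)polygons."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    g = sources.label_grid
    x0, y0 = g.origin
    cs = g.cellsize
    features = []
    for p in sources.patches:
        rows, cols = np.nonzero(sources.patch_mask(p.id))
        cells = [box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
                 for r, c in zip(rows, cols)]
        geom = unary_union(cells)
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"id": p.id, "area_km2": p.area_km2},
        })
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection
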