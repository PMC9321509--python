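"""Least-cost connectivity: cost distance, corridors, and pinch points.

The minimum-cumulative-resistance (MCR) value of a cell is the least total
resistance accumulated along any path from an ecological source,

    MCR = f( min over paths of  sum_ij  D_ij * R_i )

with f a monotone-increasing function taken as the identity (any monotone f
preserves least-cost path ranking).  Movement is modelled on the
8-connected cell graph; the step cost between neighbours i and j is the
mean of their resistances times the step length (cellsize, or cellsize*sqrt(2)
diagonally) — the de-facto grid cost-distance convention.

Corridors are least-cost paths between source pairs.  Pinch points are
found by treating each corridor's low-cost swath as a resistive network
(edge conductance = 1 / step cost), injecting one unit of current at one
source and grounding the other, and solving the graph Laplacian; current
concentrates where the corridor narrows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import spsolve

from .grid import Grid, jenks_breaks
from .resistance import ResistanceSurface
from .sources import PatchSet, Patch, SourceSet, label_patches

__all__ = [
    "CostDistanceResult",
    "Corridor",
    "NodeSet",
    "cost_distance",
    "least_cost_path",
    "corridor_network",
    "current_flow",
    "extract_nodes",
]

log = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))

#: default low-cost swath slack around a corridor (fraction of the pair cost)
DEFAULT_SWATH = 0.05
DEFAULT_NODE_MIN_AREA_KM2 = 1.0


@dataclass
class CostDistanceResult:
    """Minimum cumulative resistance to the nearest source, with allocation."""

    cost: Grid
    allocation: Grid  # nearest-source patch id; nan where unreachable


@dataclass
class Corridor:
    source_a: int
    source_b: int
    path: list[tuple[int, int]]
    cost: float
    length_m: float

    @property
    def connected(self) -> bool:
        return np.isfinite(self.cost)


@dataclass
class NodeSet:
    current: Grid
    important_nodes: PatchSet
    general_nodes: PatchSet


# ---------------------------------------------------------------------------
# Grid graph


def _grid_graph(surface: Grid) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse 8-connected graph over valid cells; returns (graph, node index).

    ``node_index`` maps (row, col) to flat node id, -1 for nodata cells.
    Edge weight = mean endpoint resistance x step length.
    """
    r = surface.values
    valid = surface.mask
    if not valid.any():
        raise ValueError("surface has no valid cells")
    vals = surface.valid_values()
    if (vals <= 0).any():
        raise ValueError("resistance must be strictly positive everywhere")
    node_index = np.full(surface.shape, -1, dtype=np.int64)
    node_index[valid] = np.arange(int(valid.sum()))
    rows_i, rows_j, weights = [], [], []
    cs = surface.cellsize
    for dr, dc, dist in ((0, 1, cs), (1, 0, cs), (1, 1, cs * SQRT2), (1, -1, cs * SQRT2)):
        sl_a = (slice(0, r.shape[0] - dr),
                slice(max(0, -dc), r.shape[1] - max(0, dc)))
        sl_b = (slice(dr, r.shape[0]),
                slice(max(0, dc), r.shape[1] - max(0, -dc)))
        ok = valid[sl_a] & valid[sl_b]
        ia = node_index[sl_a][ok]
        ib = node_index[sl_b][ok]
        w = (r[sl_a][ok] + r[sl_b][ok]) / 2.0 * dist
        rows_i.append(ia)
        rows_j.append(ib)
        weights.append(w)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(weights)
    n = int(valid.sum())
    graph = sparse.coo_matrix((np.concatenate([w, w]),
                               (np.concatenate([i, j]), np.concatenate([j, i]))),
                              shape=(n, n)).tocsr()
    return graph, node_index


def _mask_nodes(node_index: np.ndarray, mask: np.ndarray) -> np.ndarray:
    nodes = node_index[mask]
    return np.sort(nodes[nodes >= 0])


# ---------------------------------------------------------------------------
# Cost distance and corridors


def cost_distance(surface: ResistanceSurface | Grid, sources: SourceSet) -> CostDistanceResult:
    """Multi-source least-cost distance over the resistance surface.

    Cost is 0 exactly on source cells; allocation holds the id of the
    cheapest source patch for every reachable cell.
    """
    grid = surface.grid if isinstance(surface, ResistanceSurface) else surface
    grid.require_aligned(sources.label_grid)
    if sources.n_patches < 1:
        raise ValueError("at least one source is required")
    graph, node_index = _grid_graph(grid)
    src_mask = sources.label_grid.values > 0
    src_nodes = _mask_nodes(node_index, src_mask)
    if src_nodes.size == 0:
        raise ValueError("no source cell lies on a valid surface cell")
    dist, _, src_of = csgraph.dijkstra(
        graph, directed=False, indices=src_nodes,
        min_only=True, return_predecessors=True,
    )
    # map winning source node -> its patch id
    flat_labels = sources.label_grid.values[grid.mask]
    cost = np.full(grid.shape, np.nan)
    alloc = np.full(grid.shape, np.nan)
    reach = np.isfinite(dist)
    cost_vals = np.where(reach, dist, np.nan)
    alloc_vals = np.full(dist.shape, np.nan)
    alloc_vals[reach] = flat_labels[src_of[reach]]
    cost[grid.mask] = cost_vals
    alloc[grid.mask] = alloc_vals
    return CostDistanceResult(cost=grid.copy(cost), allocation=grid.copy(alloc))


def _path_between(
    graph: sparse.csr_matrix,
    node_index: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    cellsize: float,
) -> tuple[list[tuple[int, int]], float, float]:
    """Least-cost node path from region a to region b (helper)."""
    a_nodes = _mask_nodes(node_index, mask_a)
    b_nodes = _mask_nodes(node_index, mask_b)
    if a_nodes.size == 0 or b_nodes.size == 0:
        raise ValueError("both source regions must contain valid cells")
    dist, pred, _ = csgraph.dijkstra(
        graph, directed=False, indices=a_nodes,
        min_only=True, return_predecessors=True,
    )
    db = dist[b_nodes]
    if not np.isfinite(db).any():
        return [], np.inf, 0.0
    end = int(b_nodes[int(np.argmin(db))])  # ties: smallest flat id = (row, col) order
    cost = float(dist[end])
    # backtrack
    chain = [end]
    while pred[chain[-1]] >= 0:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    # flat node id -> (row, col)
    rc = np.argwhere(node_index >= 0)
    order = node_index[node_index >= 0]
    lookup = np.empty((order.size, 2), dtype=int)
    lookup[order] = rc
    path = [tuple(lookup[n]) for n in chain]
    length = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        length += cellsize * (SQRT2 if (r0 != r1 and c0 != c1) else 1.0)
    return path, cost, length


def least_cost_path(
    surface: ResistanceSurface | Grid,
    sources: SourceSet,
    id_a: int,
    id_b: int,
) -> Corridor:
    """Minimum-cost corridor between two source patches.

    Cost is measured from any cell of patch a to any cell of patch b.  An
    unreachable pair yields an explicit disconnected corridor (infinite
    cost), not an exception.  Two ids labelling the same cells give a
    zero-cost empty path.
    """
    grid = surface.grid if isinstance(surface, ResistanceSurface) else surface
    mask_a = sources.patch_mask(id_a)
    mask_b = sources.patch_mask(id_b)
    if (mask_a & mask_b).any() or id_a == id_b:
        return Corridor(id_a, id_b, [], 0.0, 0.0)
    graph, node_index = _grid_graph(grid)
    path, cost, length = _path_between(graph, node_index, mask_a, mask_b, grid.cellsize)
    return Corridor(id_a, id_b, path, cost, length)


def corridor_network(
    surface: ResistanceSurface | Grid,
    sources: SourceSet,
    mode: str = "adjacent_pairs",
) -> list[Corridor]:
    """Corridors between source pairs.

    ``adjacent_pairs`` (default) links only pairs whose cost-allocation
    regions touch (the core-adjacency rule used by corridor-mapping
    tooling); ``all_pairs`` links every pair.  Disconnected pairs are kept
    in the list with infinite cost.
    """
    if mode not in ("adjacent_pairs", "all_pairs"):
        raise ValueError("mode must be 'adjacent_pairs' or 'all_pairs'")
    grid = surface.grid if isinstance(surface, ResistanceSurface) else surface
    if sources.n_patches < 2:
        log.warning("corridor network needs >= 2 sources; got %d", sources.n_patches)
        return []
    ids = [p.id for p in sources.patches]
    if mode == "all_pairs":
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    else:
        alloc = cost_distance(surface, sources).allocation.values
        pairs_set: set[tuple[int, int]] = set()
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            sl_a = (slice(0, alloc.shape[0] - dr),
                    slice(max(0, -dc), alloc.shape[1] - max(0, dc)))
            sl_b = (slice(dr, alloc.shape[0]),
                    slice(max(0, dc), alloc.shape[1] - max(0, -dc)))
            a, b = alloc[sl_a], alloc[sl_b]
            ok = ~np.isnan(a) & ~np.isnan(b) & (a != b)
            for pa, pb in zip(a[ok].astype(int), b[ok].astype(int)):
                pairs_set.add((min(pa, pb), max(pa, pb)))
        pairs = sorted(pairs_set)
    graph, node_index = _grid_graph(grid)
    corridors = []
    for a, b in pairs:
        path, cost, length = _path_between(
            graph, node_index, sources.patch_mask(a), sources.patch_mask(b),
            grid.cellsize)
        corridors.append(Corridor(a, b, path, cost, length))
    return corridors


def corridors_to_geojson(corridors, template: Grid, path=None) -> dict:
    """Corridor centrelines as GeoJSON LineStrings (cell-centre vertices)."""
    import json
    from pathlib import Path as _P

    x0, y0 = template.origin
    cs = template.cellsize
    features = []
    for c in corridors:
        if not c.connected or len(c.path) < 2:
            continue
        coords = [[x0 + (col + 0.5) * cs, y0 - (row + 0.5) * cs]
                  for row, col in c.path]
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": {"source_a": c.source_a, "source_b": c.source_b,
                           "cost": c.cost, "length_m": c.length_m},
        })
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        _P(path).write_text(json.dumps(collection))
    return collection


# ---------------------------------------------------------------------------
# Circuit-theory current flow


def current_flow(
    surface: ResistanceSurface | Grid,
    sources: SourceSet,
    id_a: int,
    id_b: int,
    swath_percentile: float = DEFAULT_SWATH,
) -> Grid | None:
    """Current-density map for the corridor between two source patches.

    The corridor swath (cells whose through-cost exceeds the pair cost by at
    most ``swath_percentile``) is treated as a resistive network with edge
    conductance 1/step-cost.  All cells of patch a are contracted into one
    injection node carrying unit current; patch b is the ground.  Cell
    current is half the sum of absolute currents on incident edges (interior
    cells of a series chain carry exactly 1).

    Returns None when the two patches are not connected within the swath.
    """
    grid = surface.grid if isinstance(surface, ResistanceSurface) else surface
    mask_a = sources.patch_mask(id_a)
    mask_b = sources.patch_mask(id_b)
    graph, node_index = _grid_graph(grid)
    a_nodes = _mask_nodes(node_index, mask_a)
    b_nodes = _mask_nodes(node_index, mask_b)
    dist_a, _, _ = csgraph.dijkstra(graph, directed=False, indices=a_nodes,
                                    min_only=True, return_predecessors=True)
    dist_b, _, _ = csgraph.dijkstra(graph, directed=False, indices=b_nodes,
                                    min_only=True, return_predecessors=True)
    pair_cost = float(dist_a[b_nodes].min())
    if not np.isfinite(pair_cost):
        return None
    through = dist_a + dist_b
    in_swath = through <= pair_cost * (1.0 + swath_percentile) + 1e-9

    # contract patches to supernodes A and B over the swath subgraph
    n = graph.shape[0]
    contract = np.full(n, -1, dtype=np.int64)
    swath_ids = np.flatnonzero(in_swath)
    a_set = np.zeros(n, dtype=bool); a_set[a_nodes] = True
    b_set = np.zeros(n, dtype=bool); b_set[b_nodes] = True
    plain = swath_ids[~a_set[swath_ids] & ~b_set[swath_ids]]
    contract[plain] = np.arange(plain.size)
    node_A = plain.size
    node_B = plain.size + 1
    contract[a_set] = node_A
    contract[b_set] = node_B
    m = plain.size + 2

    coo = graph.tocoo()
    keep = in_swath[coo.row] & in_swath[coo.col] & (coo.row < coo.col)
    ei, ej, ew = coo.row[keep], coo.col[keep], coo.data[keep]
    ci, cj = contract[ei], contract[ej]
    off = ci != cj
    ei, ej, ew, ci, cj = ei[off], ej[off], ew[off], ci[off], cj[off]
    cond = 1.0 / ew

    lap = sparse.coo_matrix(
        (np.concatenate([-cond, -cond, cond, cond]),
         (np.concatenate([ci, cj, ci, cj]), np.concatenate([cj, ci, ci, cj]))),
        shape=(m, m)).tocsr()

    # check A and B are in one component of the swath network
    adj = sparse.coo_matrix((cond, (ci, cj)), shape=(m, m))
    ncomp, comp = csgraph.connected_components(adj, directed=False)
    if comp[node_A] != comp[node_B]:
        return None
    live = comp == comp[node_A]

    # solve L v = i with ground v[B] = 0, unit injection at A
    inj = np.zeros(m)
    inj[node_A] = 1.0
    unknowns = np.flatnonzero(live & (np.arange(m) != node_B))
    sub = lap[np.ix_(unknowns, unknowns)].tocsc()
    v_sub = spsolve(sub, inj[unknowns])
    volts = np.zeros(m)
    volts[unknowns] = v_sub

    # per-original-cell current: half the absolute incident edge currents
    edge_cur = cond * np.abs(volts[ci] - volts[cj])
    cell_cur = np.zeros(n)
    np.add.at(cell_cur, ei, edge_cur / 2.0)
    np.add.at(cell_cur, ej, edge_cur / 2.0)

    out = np.full(grid.shape, np.nan)
    out[grid.mask] = cell_cur
    out[~grid.mask] = np.nan
    result = grid.copy(out)
    # cells outside the swath carry no current but stay valid zeros
    return result


def extract_nodes(
    currents: list[Grid],
    min_area_km2: float = DEFAULT_NODE_MIN_AREA_KM2,
    connectivity: int = 8,
) -> NodeSet:
    """Pinch-point extraction from per-corridor current maps.

    The cellwise maximum over corridors is split into general/important by a
    2-class natural-breaks cut of the positive-current cells; important
    patches larger than ``min_area_km2`` are the important ecological
    nodes.  A constant current field cannot be split: everything is general.
    """
    if not currents:
        raise ValueError("at least one current grid is required")
    base = currents[0]
    base.require_aligned(*currents[1:])
    stack = np.stack([np.where(c.mask, c.values, 0.0) for c in currents])
    peak = stack.max(axis=0)
    peak_grid = base.copy(peak)
    peak_grid.values[~base.mask] = np.nan
    pos = peak[base.mask & (peak > 0)]
    empty = PatchSet(base.copy(np.zeros(base.shape)), [])
    if pos.size == 0:
        return NodeSet(peak_grid, empty, empty)
    try:
        cut = jenks_breaks(pos, 2).breaks[0]
    except ValueError:  # constant positive current: no split possible
        return NodeSet(peak_grid, empty,
                       _positive_patches(peak_grid, peak > 0, connectivity))
    important_mask = peak > cut
    general_mask = (peak > 0) & ~important_mask
    important = _positive_patches(peak_grid, important_mask, connectivity)
    big = [p for p in important.patches if p.area_km2 > min_area_km2]
    labels = important.label_grid.values
    out = np.zeros(base.shape)
    kept = []
    for new_id, p in enumerate(sorted(big, key=lambda p: (-p.area_km2, p.id)), start=1):
        out[labels == p.id] = new_id
        kept.append(Patch(new_id, p.n_cells, p.area_km2, p.bbox))
    important_set = PatchSet(base.copy(out), kept)
    general_set = _positive_patches(peak_grid, general_mask, connectivity)
    return NodeSet(peak_grid, important_set, general_set)


def _positive_patches(template: Grid, mask: np.ndarray, connectivity: int) -> PatchSet:
    marker = template.copy(np.where(mask, 1.0, 0.0))
    marker.values[~template.mask] = np.nan
    return label_patches(marker, 1, connectivity)
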