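import numpy as np
import pytest

from ecosecurity.ahp import PairwiseMatrix, parse_matrix
from ecosecurity.grid import Grid

#: the published five-criterion comparison matrix (land use, vegetation
#: coverage, slope, county-road distance, highway distance)
FIVE_FACTOR_MATRIX_TEXT = """\
1 1/5 1/6 1/3 1/4
5 1 1/2 4 3
6 2 1 3 2
3 1/4 1/3 1 1/2
4 1/3 1/2 2 1
"""


@pytest.fixture(scope="session")
def five_factor_matrix() -> PairwiseMatrix:
    return parse_matrix(FIVE_FACTOR_MATRIX_TEXT)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_grid(values, cellsize=100.0, origin=None, nodata=-9999.0) -> Grid:
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cellsize)
    return Grid(values, cellsize, origin, nodata)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)


def brute_force_dijkstra(resistance, cellsize, source_cells):
    """Textbook heapq Dijkstra over an explicit edge list.

    8-connected; step cost = mean endpoint resistance x step length.
    Returns (cost, nearest-source-cell map) dicts keyed by (row, col).
    NaN resistance cells are untraversable.
    """
    import heapq
    import math

    n_rows, n_cols = len(resistance), len(resistance[0])
    valid = {(r, c) for r in range(n_rows) for c in range(n_cols)
             if not math.isnan(resistance[r][c])}
    edges = {}
    for r, c in valid:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in valid:
                    d = cellsize * (math.sqrt(2) if dr and dc else 1.0)
                    w = (resistance[r][c] + resistance[nb[0]][nb[1]]) / 2 * d
                    edges.setdefault((r, c), []).append((nb, w))
    dist = {cell: math.inf for cell in valid}
    origin = {}
    heap = []
    for s in source_cells:
        if s in valid:
            dist[s] = 0.0
            origin[s] = s
            heapq.heappush(heap, (0.0, s))
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in edges.get(u, []):
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                origin[v] = origin[u]
                heapq.heappush(heap, (nd, v))
    return dist, origin


def enumerate_jenks(values, k):
    """Exhaustive search over all contiguous k-partitions of the sorted values.

    Returns (best SSD, list of class value-lists).  Only feasible for tiny n.
    """
    from itertools import combinations

    v = sorted(values)
    n = len(v)

    def ssd(chunk):
        m = sum(chunk) / len(chunk)
        return sum((x - m) ** 2 for x in chunk)

    best, best_parts = None, None
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        parts = [v[a:b] for a, b in zip(bounds, bounds[1:])]
        total = sum(ssd(p) for p in parts)
        if best is None or total < best - 1e-12:
            best, best_parts = total, parts
    return best, best_parts


def dense_current_solve(nodes, edges, source_nodes, ground_nodes):
    """Dense Laplacian solve for unit current from sources to grounds.

    ``edges`` is a list of (u, v, conductance) over hashable node ids.
    Source/ground node sets are each contracted to one terminal.  Returns a
    dict node -> voltage (terminals included, ground at 0).
    """
    import numpy as np

    source_nodes, ground_nodes = set(source_nodes), set(ground_nodes)
    plain = [n for n in nodes if n not in source_nodes and n not in ground_nodes]
    index = {n: i for i, n in enumerate(plain)}
    A, B = len(plain), len(plain) + 1
    m = len(plain) + 2

    def node_id(n):
        if n in source_nodes:
            return A
        if n in ground_nodes:
            return B
        return index[n]

    L = np.zeros((m, m))
    for u, v, g in edges:
        iu, iv = node_id(u), node_id(v)
        if iu == iv:
            continue
        L[iu, iu] += g
        L[iv, iv] += g
        L[iu, iv] -= g
        L[iv, iu] -= g
    inj = np.zeros(m)
    inj[A] = 1.0
    keep = [i for i in range(m) if i != B]
    volts = np.zeros(m)
    volts[keep] = np.linalg.solve(L[np.ix_(keep, keep)], inj[keep])
    return {n: volts[node_id(n)] for n in nodes}
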