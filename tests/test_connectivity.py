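"""Cost distance, corridors, current flow and node extraction."""

import numpy as np
import pytest

from ecosecurity.connectivity import (
    SQRT2, corridor_network, cost_distance, current_flow, extract_nodes,
    least_cost_path,
)
from ecosecurity.sources import filter_by_area, label_patches
from ecosecurity.synth import make_fixture
from conftest import brute_force_dijkstra, dense_current_solve, make_grid


def sources_from_mask(mask, template):
    marker = template.copy(np.where(mask, 5.0, 1.0))
    marker.values[~template.mask] = np.nan
    return filter_by_area(label_patches(marker, 5), 0.0)


# ---------------------------------------------------------------------------
# Cost distance


def test_uniform_surface_single_source_neighbours():
    g = make_grid(np.full((5, 5), 3.0), cellsize=100.0)
    mask = np.zeros((5, 5), dtype=bool); mask[2, 2] = True
    res = cost_distance(g, sources_from_mask(mask, g))
    assert res.cost.values[2, 2] == 0.0
    assert res.cost.values[2, 3] == pytest.approx(300.0)       # r * cellsize
    assert res.cost.values[1, 1] == pytest.approx(300.0 * SQRT2)


def test_cost_distance_matches_brute_force_oracle(rng):
    for trial in range(8):
        r = rng.uniform(0.5, 10.0, (6, 6))
        g = make_grid(r, cellsize=50.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[rng.integers(0, 6), rng.integers(0, 6)] = True
        mask[rng.integers(0, 6), rng.integers(0, 6)] = True
        res = cost_distance(g, sources_from_mask(mask, g))
        oracle, _ = brute_force_dijkstra(r.tolist(), 50.0, list(map(tuple, np.argwhere(mask))))
        for (rr, cc), d in oracle.items():
            assert res.cost.values[rr, cc] == pytest.approx(d)


def test_cost_distance_allocation_and_zero_on_sources(rng):
    r = rng.uniform(1, 5, (8, 8))
    g = make_grid(r, cellsize=100.0)
    mask = np.zeros((8, 8), dtype=bool)
    mask[0, 0] = mask[7, 7] = True
    srcs = sources_from_mask(mask, g)
    res = cost_distance(g, srcs)
    assert res.cost.values[0, 0] == 0.0 and res.cost.values[7, 7] == 0.0
    assert res.allocation.values[0, 0] != res.allocation.values[7, 7]
    # allocation defined wherever cost is finite
    assert np.isnan(res.allocation.values).sum() == np.isnan(res.cost.values).sum()


def test_bellman_condition_holds_everywhere(rng):
    r = rng.uniform(0.5, 8.0, (7, 7))
    g = make_grid(r, cellsize=10.0)
    mask = np.zeros((7, 7), dtype=bool); mask[3, 3] = True
    cost = cost_distance(g, sources_from_mask(mask, g)).cost.values
    for rr in range(7):
        for cc in range(7):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0 or not (0 <= rr + dr < 7 and 0 <= cc + dc < 7):
                        continue
                    step = (r[rr, cc] + r[rr + dr, cc + dc]) / 2 * 10.0 \
                        * (SQRT2 if dr and dc else 1.0)
                    assert cost[rr, cc] <= cost[rr + dr, cc + dc] + step + 1e-9


# ---------------------------------------------------------------------------
# Least-cost paths


def test_same_patch_gives_zero_cost_empty_path():
    g = make_grid(np.ones((5, 5)))
    mask = np.zeros((5, 5), dtype=bool); mask[2, 2] = True
    srcs = sources_from_mask(mask, g)
    c = least_cost_path(g, srcs, 1, 1)
    assert c.cost == 0.0 and c.path == []


def test_straight_corridor_on_uniform_surface():
    surface = make_fixture("uniform_surface")  # resistance 2, cellsize 100
    mask = np.zeros((10, 10), dtype=bool)
    mask[5, 1] = mask[5, 8] = True
    srcs = sources_from_mask(mask, surface)
    c = least_cost_path(surface, srcs, 1, 2)
    assert c.cost == pytest.approx(2.0 * 100.0 * 7)
    assert [rc[0] for rc in c.path] == [5] * 8  # straight along the row
    assert c.length_m == pytest.approx(700.0)


def test_path_cost_matches_oracle_and_is_symmetric(rng):
    for _ in range(6):
        r = rng.uniform(0.5, 9.0, (8, 8))
        g = make_grid(r, cellsize=25.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, rng.integers(0, 8)] = True
        mask[7, rng.integers(0, 8)] = True
        srcs = sources_from_mask(mask, g)
        ab = least_cost_path(g, srcs, 1, 2)
        ba = least_cost_path(g, srcs, 2, 1)
        a_cells = list(map(tuple, np.argwhere(srcs.patch_mask(1))))
        b_cells = [tuple(x) for x in np.argwhere(srcs.patch_mask(2))]
        oracle, _ = brute_force_dijkstra(r.tolist(), 25.0, a_cells)
        assert ab.cost == pytest.approx(min(oracle[b] for b in b_cells))
        assert ba.cost == pytest.approx(ab.cost)


def test_disconnected_pair_reports_infinite_cost():
    v = np.ones((5, 5))
    v[:, 2] = np.nan  # impassable wall
    g = make_grid(v)
    mask = np.zeros((5, 5), dtype=bool); mask[2, 0] = mask[2, 4] = True
    srcs = sources_from_mask(mask, g)
    c = least_cost_path(g, srcs, 1, 2)
    assert not c.connected and c.path == []


def test_scaling_resistance_scales_costs_not_paths(rng):
    r = rng.uniform(1, 5, (7, 7))
    g1 = make_grid(r)
    g3 = make_grid(3 * r)
    mask = np.zeros((7, 7), dtype=bool); mask[0, 0] = mask[6, 6] = True
    s1, s3 = sources_from_mask(mask, g1), sources_from_mask(mask, g3)
    c1 = least_cost_path(g1, s1, 1, 2)
    c3 = least_cost_path(g3, s3, 1, 2)
    assert c3.cost == pytest.approx(3 * c1.cost)
    assert c3.path == c1.path


# ---------------------------------------------------------------------------
# Corridor networks


def test_three_collinear_sources_adjacent_pairs():
    g = make_grid(np.ones((7, 19)), cellsize=100.0)
    mask = np.zeros((7, 19), dtype=bool)
    mask[3, 2] = mask[3, 9] = mask[3, 16] = True
    srcs = sources_from_mask(mask, g)
    net = corridor_network(g, srcs, "adjacent_pairs")
    pairs = {(c.source_a, c.source_b) for c in net}
    assert len(net) == 2
    # the middle source's allocation region separates the two end regions
    middle = int(srcs.label_grid.values[3, 9])
    assert all(middle in p for p in pairs)


def test_all_pairs_count(rng):
    g = make_grid(rng.uniform(1, 3, (10, 10)))
    mask = np.zeros((10, 10), dtype=bool)
    mask[0, 0] = mask[0, 9] = mask[9, 0] = mask[9, 9] = True
    srcs = sources_from_mask(mask, g)
    net = corridor_network(g, srcs, "all_pairs")
    assert len(net) == 4 * 3 // 2
    assert all(c.connected for c in net)


def test_corridor_cost_exceeds_straight_line_lower_bound(rng):
    r = rng.uniform(1, 6, (9, 9))
    g = make_grid(r, cellsize=100.0)
    mask = np.zeros((9, 9), dtype=bool); mask[0, 0] = mask[8, 8] = True
    srcs = sources_from_mask(mask, g)
    c = least_cost_path(g, srcs, 1, 2)
    gap = np.hypot(8, 8) * 100.0
    assert c.cost >= r.min() * gap * 0.999


def test_single_source_network_is_empty():
    g = make_grid(np.ones((5, 5)))
    mask = np.zeros((5, 5), dtype=bool); mask[2, 2] = True
    assert corridor_network(g, sources_from_mask(mask, g)) == []


# ---------------------------------------------------------------------------
# Current flow


def chain_sources(surface):
    """Sources at the two ends of the bottleneck fixture's rooms."""
    mask_a = np.zeros(surface.shape, dtype=bool)
    mask_b = np.zeros(surface.shape, dtype=bool)
    mask_a[:, 0] = surface.mask[:, 0]
    mask_b[:, -1] = surface.mask[:, -1]
    marker = surface.copy(np.where(mask_a | mask_b, 5.0, 1.0))
    marker.values[~surface.mask] = np.nan
    return filter_by_area(label_patches(marker, 5), 0.0)


def test_series_chain_carries_unit_current():
    v = np.full((1, 7), 2.0)
    g = make_grid(v, cellsize=100.0)
    mask = np.zeros((1, 7), dtype=bool)
    mask[0, 0] = mask[0, 6] = True
    srcs = sources_from_mask(mask, g)
    cur = current_flow(g, srcs, 1, 2, swath_percentile=0.0)
    np.testing.assert_allclose(cur.values[0, 1:6], 1.0, atol=1e-10)


def test_parallel_chains_split_current_evenly():
    v = np.full((3, 7), np.nan)
    v[0, :] = 1.0
    v[2, :] = 1.0
    v[0, 0] = v[1, 0] = v[2, 0] = 1.0   # left junction column
    v[0, 6] = v[1, 6] = v[2, 6] = 1.0   # right junction column
    g = make_grid(v, cellsize=100.0)
    mask_a = np.zeros((3, 7), dtype=bool); mask_a[:, 0] = True
    mask_b = np.zeros((3, 7), dtype=bool); mask_b[:, 6] = True
    marker = g.copy(np.where(mask_a | mask_b, 5.0, 1.0))
    marker.values[~g.mask] = np.nan
    srcs = filter_by_area(label_patches(marker, 5), 0.0)
    cur = current_flow(g, srcs, 1, 2, swath_percentile=1.0)
    np.testing.assert_allclose(cur.values[0, 2:5], 0.5, atol=1e-8)
    np.testing.assert_allclose(cur.values[2, 2:5], 0.5, atol=1e-8)


def test_current_matches_dense_laplacian_oracle(rng):
    r = rng.uniform(0.5, 4.0, (5, 6))
    g = make_grid(r, cellsize=100.0)
    mask = np.zeros((5, 6), dtype=bool)
    mask[:, 0] = True
    mask_b = np.zeros((5, 6), dtype=bool)
    mask_b[:, 5] = True
    marker = g.copy(np.where(mask, 5.0, np.where(mask_b, 5.0, 1.0)))
    srcs = filter_by_area(label_patches(marker, 5), 0.0)
    ids = sorted(p.id for p in srcs.patches)
    cur = current_flow(g, srcs, ids[0], ids[1], swath_percentile=10.0)

    # oracle: dense solve over the full 30-node network
    nodes = [(rr, cc) for rr in range(5) for cc in range(6)]
    edges = []
    for rr, cc in nodes:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (rr + dr, cc + dc)
            if 0 <= nb[0] < 5 and 0 <= nb[1] < 6:
                d = 100.0 * (SQRT2 if dr and dc else 1.0)
                w = (r[rr, cc] + r[nb]) / 2 * d
                edges.append(((rr, cc), nb, 1.0 / w))
    a_cells = {tuple(x) for x in np.argwhere(srcs.patch_mask(ids[0]))}
    b_cells = {tuple(x) for x in np.argwhere(srcs.patch_mask(ids[1]))}
    volts = dense_current_solve(nodes, edges, a_cells, b_cells)
    expected = {n: 0.0 for n in nodes}
    for u, v, gcond in edges:
        if volts[u] == volts[v]:
            continue
        i_edge = gcond * abs(volts[u] - volts[v])
        expected[u] += i_edge / 2
        expected[v] += i_edge / 2
    for rr, cc in nodes:
        assert cur.values[rr, cc] == pytest.approx(expected[(rr, cc)], abs=1e-8)


def test_bottleneck_neck_carries_maximal_current():
    surface = make_fixture("bottleneck_neck")
    srcs = chain_sources(surface)
    cur = current_flow(surface, srcs, 1, 2, swath_percentile=5.0)
    neck = cur.values[3, 4:7]
    np.testing.assert_allclose(neck, 1.0, atol=1e-8)  # all current in series
    interior = cur.values.copy()
    assert np.nanmax(interior) == pytest.approx(np.nanmax(neck))


def test_current_flow_disconnected_returns_none():
    v = np.ones((3, 5))
    v[:, 2] = np.nan
    g = make_grid(v)
    mask = np.zeros((3, 5), dtype=bool); mask[1, 0] = mask[1, 4] = True
    srcs = sources_from_mask(mask, g)
    assert current_flow(g, srcs, 1, 2) is None


# ---------------------------------------------------------------------------
# Node extraction


def test_constant_current_yields_no_important_nodes():
    v = np.full((1, 9), 1.0)
    g = make_grid(v, cellsize=100.0)
    mask = np.zeros((1, 9), dtype=bool); mask[0, 0] = mask[0, 8] = True
    srcs = sources_from_mask(mask, g)
    cur = current_flow(g, srcs, 1, 2, swath_percentile=0.0)
    # interior current is exactly 1 everywhere except the terminals
    nodes = extract_nodes([cur], min_area_km2=0.0)
    # terminals carry ~0.5+, interior 1.0: a 2-class split may exist, but a
    # strictly constant field must not
    flat = cur.copy(np.where(cur.values > 0, 1.0, 0.0))
    nodes_flat = extract_nodes([flat], min_area_km2=0.0)
    assert nodes_flat.important_nodes.n_patches == 0


def test_bottleneck_neck_lands_in_important_class():
    surface = make_fixture("bottleneck_neck")
    srcs = chain_sources(surface)
    cur = current_flow(surface, srcs, 1, 2, swath_percentile=5.0)
    nodes = extract_nodes([cur], min_area_km2=0.0)
    important = nodes.important_nodes.label_grid.values
    assert np.all(important[3, 4:7] > 0)


def test_min_area_larger_than_grid_removes_all():
    surface = make_fixture("bottleneck_neck")
    srcs = chain_sources(surface)
    cur = current_flow(surface, srcs, 1, 2, swath_percentile=5.0)
    nodes = extract_nodes([cur], min_area_km2=1e9)
    assert nodes.important_nodes.n_patches == 0


def test_extract_nodes_takes_max_over_corridors():
    g = make_grid(np.zeros((2, 2)))
    a = g.copy(np.array([[1.0, 0.0], [0.0, 0.0]]))
    b = g.copy(np.array([[0.5, 2.0], [0.0, 0.0]]))
    nodes = extract_nodes([a, b], min_area_km2=0.0)
    np.testing.assert_array_equal(nodes.current.values,
                                  [[1.0, 2.0], [0.0, 0.0]])
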