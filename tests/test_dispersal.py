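import itertools
import math

import numpy as np
import pytest

from rangeshift.dispersal import (
    BARRIER_COST, CostSurface, cost_distance, jenks_breaks, jenks_objective,
    limit_mask, mosaic_max, reclassify, suitability_cost,
    _weighted_fisher_jenks,
)
from rangeshift.grid import AlignmentError, Grid
from rangeshift.occurrences import OccurrenceSet


def mk_grid(values, mask=None, res=0.1):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.zeros(values.shape, bool)
    return Grid(values=values, nodata_mask=mask,
                origin=(0.0, values.shape[0] * res), resolution=res)


def cost_surface(values, **kw):
    return CostSurface(grid=mk_grid(values, **kw))


def cell_center_occ(grid, cells):
    lons = [grid.west + (c + 0.5) * grid.resolution for _, c in cells]
    lats = [grid.north - (r + 0.5) * grid.resolution for r, _ in cells]
    return OccurrenceSet(np.array(lons), np.array(lats))


class TestReclassify:
    def test_first_matching_rule_wins_and_boundaries_are_half_open(self):
        layer = mk_grid([[50.0, 100.0], [150.0, 0.0]])
        rules = [(0.0, 100.0, 1.0), (100.0, 1e9, BARRIER_COST)]
        cs = reclassify(layer, rules)
        assert cs.grid.values[0, 0] == 1.0
        assert cs.grid.values[0, 1] == BARRIER_COST  # boundary goes up
        assert cs.grid.values[1, 0] == BARRIER_COST

    def test_urban_cover_is_insurmountable(self):
        urban = mk_grid([[0.0, 5.0], [80.0, 0.0]])
        rules = [(0.0, 1e-9, 1.0), (1e-9, 101.0, BARRIER_COST)]
        cs = reclassify(urban, rules, name="urban")
        assert (cs.grid.values[urban.values > 0] == BARRIER_COST).all()

    def test_uncovered_value_is_reported(self):
        layer = mk_grid([[5.0, -1.0]])
        with pytest.raises(ValueError, match="-1"):
            reclassify(layer, [(0.0, 10.0, 1.0)], name="lyr")


class TestSuitabilityCost:
    def test_endpoints_and_barrier(self):
        suit = mk_grid([[1.0, 0.2, 0.5175 - 1e-9]])
        cs = suitability_cost(suit, mtss=0.5175)
        assert cs.grid.values[0, 0] == 1.0
        assert cs.grid.values[0, 1] == BARRIER_COST
        assert cs.grid.values[0, 2] == BARRIER_COST

    def test_log_midpoint_cost(self):
        mtss = 0.5175
        mid = (mtss + 1.0) / 2.0
        cs = suitability_cost(mk_grid([[mid]]), mtss=mtss)
        assert cs.grid.values[0, 0] == pytest.approx(round(math.sqrt(1000)))

    def test_non_increasing_in_suitability(self):
        s = np.linspace(0.52, 1.0, 50).reshape(1, -1)
        cs = suitability_cost(mk_grid(s), mtss=0.5175)
        assert (np.diff(cs.grid.values[0]) <= 0).all()


class TestMosaic:
    def test_cellwise_maximum(self):
        a = cost_surface([[1.0, 50.0]])
        b = cost_surface([[BARRIER_COST, 2.0]])
        out = mosaic_max([a, b])
        assert out.grid.values.tolist() == [[BARRIER_COST, 50.0]]

    def test_single_input_identity_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        surfaces = [cost_surface(rng.integers(1, 1000, (4, 5)).astype(float))
                    for _ in range(3)]
        single = mosaic_max([surfaces[0]])
        np.testing.assert_array_equal(single.grid.values,
                                      surfaces[0].grid.values)
        for perm in itertools.permutations(surfaces):
            np.testing.assert_array_equal(
                mosaic_max(list(perm)).grid.values,
                mosaic_max(surfaces).grid.values)

    def test_alignment_enforced(self):
        a = cost_surface([[1.0]])
        b = CostSurface(grid=mk_grid([[1.0]], res=0.2))
        with pytest.raises(AlignmentError):
            mosaic_max([a, b])


class TestCostDistance:
    def test_one_dimensional_hand_dijkstra(self):
        cs = cost_surface([[1.0, 1.0, 1e6, 1.0]])
        src = cell_center_occ(cs.grid, [(0, 0)])
        acc = cost_distance(cs, src)
        np.testing.assert_allclose(acc.values[0],
                                   [0.0, 1.0, 500001.5, 1000002.0])

    def test_uniform_cost_gives_chamfer_distance(self):
        n = 9
        cs = cost_surface(np.ones((n, n)))
        src = cell_center_occ(cs.grid, [(4, 4)])
        acc = cost_distance(cs, src)
        rows, cols = np.mgrid[0:n, 0:n]
        dr = np.abs(rows - 4)
        dc = np.abs(cols - 4)
        chamfer = np.minimum(dr, dc) * math.sqrt(2) + np.abs(dr - dc)
        np.testing.assert_allclose(acc.values, chamfer, atol=1e-12)

    def test_two_sources_is_cellwise_min_of_singles(self):
        rng = np.random.default_rng(1)
        cs = cost_surface(rng.integers(1, 100, (8, 8)).astype(float))
        a = cell_center_occ(cs.grid, [(0, 0)])
        b = cell_center_occ(cs.grid, [(7, 7)])
        both = cell_center_occ(cs.grid, [(0, 0), (7, 7)])
        acc_a = cost_distance(cs, a).values
        acc_b = cost_distance(cs, b).values
        acc_ab = cost_distance(cs, both).values
        np.testing.assert_allclose(acc_ab, np.minimum(acc_a, acc_b))

    def test_matches_networkx_oracle_on_random_grids(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            vals = rng.integers(1, 500, (n, n)).astype(float)
            cs = cost_surface(vals)
            src_cell = (int(rng.integers(n)), int(rng.integers(n)))
            acc = cost_distance(cs, cell_center_occ(cs.grid, [src_cell]))
            g = nx.Graph()
            for r in range(n):
                for c in range(n):
                    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < n and 0 <= c2 < n:
                            w = (vals[r, c] + vals[r2, c2]) / 2
                            if dr and dc:
                                w *= math.sqrt(2)
                            g.add_edge((r, c), (r2, c2), weight=w)
            dist = nx.single_source_dijkstra_path_length(g, src_cell)
            for (r, c), d in dist.items():
                assert acc.values[r, c] == pytest.approx(d, rel=1e-12)

    def test_raising_a_cell_cost_never_shortens_paths(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(1, 50, (7, 7)).astype(float)
        cs = cost_surface(vals)
        src = cell_center_occ(cs.grid, [(0, 0)])
        base = cost_distance(cs, src).values
        for _ in range(5):
            vals2 = vals.copy()
            r, c = rng.integers(7), rng.integers(7)
            vals2[r, c] += rng.integers(1, 1000)
            acc2 = cost_distance(cost_surface(vals2), src).values
            assert (acc2 >= base - 1e-9).all()

    def test_sources_on_nodata_rejected(self):
        mask = np.ones((3, 3), bool)
        mask[1, 1] = False
        cs = CostSurface(grid=mk_grid(np.ones((3, 3)), mask=mask))
        src = cell_center_occ(cs.grid, [(0, 0)])  # masked cell
        with pytest.raises(ValueError, match="source"):
            cost_distance(cs, src)


def brute_force_jenks(values, k):
    """Exhaustive search over contiguous partitions of the sorted values."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    best, best_breaks = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = list(cuts) + [n]
        start, sse = 0, 0.0
        uppers = []
        for b in bounds:
            seg = v[start:b]
            sse += ((seg - seg.mean()) ** 2).sum()
            uppers.append(seg[-1])
            start = b
        if sse < best - 1e-12:
            best, best_breaks = sse, uppers
    return best, best_breaks


class TestJenks:
    def test_two_obvious_clusters(self):
        breaks = jenks_breaks(np.array([1, 2, 3, 10, 11, 12]), 2)
        np.testing.assert_array_equal(breaks, [3.0, 12.0])

    def test_each_distinct_value_its_own_class(self):
        vals = np.array([4.0, 1.0, 9.0, 2.5])
        breaks = jenks_breaks(vals, 4)
        np.testing.assert_array_equal(breaks, np.sort(vals))
        assert jenks_objective(vals, breaks) == 0.0

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            jenks_breaks(np.array([1.0, 1.0, 2.0]), 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        k = int(rng.integers(2, 5))
        vals = np.round(rng.normal(size=n) * 10, 1)
        if len(np.unique(vals)) < k:
            return
        breaks = jenks_breaks(vals, k)
        best, _ = brute_force_jenks(vals, k)
        assert jenks_objective(vals, breaks) == pytest.approx(best, abs=1e-9)

    def test_binned_approximation_stays_close_to_exact(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(0, 1, 300), rng.normal(50, 3, 300)])
        exact = jenks_breaks(vals, 4)
        binned = jenks_breaks(vals, 4, max_exact=10, max_exact_unique=10,
                              n_bins=256)
        exact_obj = jenks_objective(vals, exact)
        binned_obj = jenks_objective(vals, binned)
        assert binned_obj <= exact_obj * 1.05


class TestLimitMask:
    def test_bimodal_costs_keep_low_cluster(self):
        rng = np.random.default_rng(4)
        low = rng.uniform(5, 15, 40)
        high = rng.uniform(9e5, 1.1e6, 40)
        vals = np.concatenate([low, high]).reshape(8, 10)
        acc = mk_grid(vals)
        limit = limit_mask(acc, n_classes=7)
        assert limit.mask[vals <= 15].all()
        assert not limit.mask[vals >= 9e5].any()

    def test_source_cells_always_reachable(self):
        cs = cost_surface(np.full((6, 6), 10.0))
        src = cell_center_occ(cs.grid, [(2, 3)])
        acc = cost_distance(cs, src)
        limit = limit_mask(acc, n_classes=3)
        assert limit.mask[2, 3]

    def test_constant_accumulated_cost_reports_jenks_error(self):
        acc = mk_grid(np.full((4, 4), 5.0))
        with pytest.raises(ValueError, match="distinct"):
            limit_mask(acc, n_classes=7)

    def test_infinite_cells_never_reachable(self):
        vals = np.array([[0.0, 1.0, np.inf, 7.0]])
        acc = Grid(values=vals, nodata_mask=~np.isfinite(vals),
                   origin=(0.0, 0.1), resolution=0.1)
        limit = limit_mask(acc, n_classes=2)
        assert not limit.mask[0, 2]
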