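"""Tree metrics: asymmetry, cumulative size distribution, Strahler statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopnest import (
    MetricSeries,
    NestingTree,
    adjusted_csd,
    averaged_asymmetry,
    bifurcation_ratio,
    csd_probability,
    cumulative_size_distribution,
    fit_bifurcation_ratio,
    fit_slope,
    partition_asymmetry,
    strahler_orders,
    stream_counts,
    subtree_asymmetry,
    subtree_degree,
)
from loopnest.metrics import node_areas, partition_asymmetries, subtree_asymmetries

from tests.conftest import random_binary_tree


class TestPartitionAsymmetry:
    @pytest.mark.parametrize("r,s,q", [(1, 1, 0.0), (3, 3, 0.0), (4, 2, 0.5),
                                       (2, 1, 1.0), (7, 1, 1.0), (5, 3, 1 / 3)])
    def test_values(self, r, s, q):
        assert partition_asymmetry(r, s) == pytest.approx(q)

    def test_symmetry_and_bounds_exhaustive(self):
        for r in range(1, 7):
            for s in range(1, 7):
                q = partition_asymmetry(r, s)
                assert q == partition_asymmetry(s, r)
                assert 0.0 <= q <= 1.0
                if r + s > 2:
                    assert q == pytest.approx(abs(r - s) / (r + s - 2))

    def test_degree_sum_variant(self):
        assert partition_asymmetry(4, 2, "degree_sum") == pytest.approx(1 / 3)
        assert partition_asymmetry(1, 1, "degree_sum") == 0.0

    def test_rejects_nonpositive_degrees(self):
        with pytest.raises(ValueError):
            partition_asymmetry(0, 3)


class TestSubtreeAsymmetry:
    @pytest.mark.parametrize("d", [2, 3, 4, 8, 16, 64])
    def test_caterpillar_closed_form(self, d):
        t = NestingTree.caterpillar(d)
        assert subtree_asymmetry(t, t.root) == pytest.approx((d - 2) / (d - 1))

    @pytest.mark.parametrize("depth", [1, 3, 5])
    def test_complete_binary_is_exactly_zero(self, depth):
        t = NestingTree.complete_binary(depth)
        assert subtree_asymmetry(t, t.root) == 0.0

    def test_leaf_is_undefined(self):
        t = NestingTree.caterpillar(4)
        leaf = next(n.id for n in t.nodes.values() if n.is_leaf)
        with pytest.raises(ValueError):
            subtree_asymmetry(t, leaf)

    def test_root_only_weighting_returns_root_partition(self):
        t = NestingTree.caterpillar(5)
        w = lambda n: 1.0 if n.id == t.root else 0.0
        assert subtree_asymmetry(t, t.root, weight_fn=w) == pytest.approx(
            partition_asymmetry(4, 1)
        )

    def test_subtree_degrees(self):
        t = NestingTree.caterpillar(6)
        assert subtree_degree(t, t.root) == 6
        for n in t.internal_nodes():
            assert n.degree == sum(t.nodes[c].degree for c in n.children)


class TestAveragedAsymmetry:
    def test_single_bifurcation_is_zero(self):
        t = NestingTree.caterpillar(2)
        assert averaged_asymmetry(t, 2) == 0.0

    def test_caterpillar_window_containing_only_root(self):
        t = NestingTree.caterpillar(8)
        assert averaged_asymmetry(t, 8, window_halfwidth_log2=0.05) == pytest.approx(6 / 7)

    def test_empty_window_is_nan_not_error(self):
        t = NestingTree.caterpillar(4)
        assert math.isnan(averaged_asymmetry(t, 1024.0, window_halfwidth_log2=0.1))

    def test_monotone_in_degree_for_caterpillar(self):
        # additive architecture: Lambda(d) = (d-2)/(d-1) increases with d
        t = NestingTree.caterpillar(64)
        vals = [averaged_asymmetry(t, 2.0 ** k, window_halfwidth_log2=0.25)
                for k in range(1, 7)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_exact_degree_variant_matches_binned_mean(self):
        t = NestingTree.caterpillar(8)
        A = subtree_asymmetries(t)
        d4 = [A[n.id] for n in t.internal_nodes() if n.degree == 4]
        assert averaged_asymmetry(t, 4, variant="exact") == pytest.approx(np.mean(d4))


class TestCSD:
    def test_caterpillar_multiset_and_probabilities(self):
        t = NestingTree.caterpillar(4, leaf_area=0.25)
        areas = np.sort(node_areas(t))
        assert areas == pytest.approx([0.25, 0.25, 0.25, 0.25, 0.5, 0.75, 1.0])
        s = cumulative_size_distribution(t)
        assert csd_probability(s, 0.3) == pytest.approx(3 / 7)
        assert csd_probability(s, 0.0) == 1.0
        assert csd_probability(s, 1.0) == 0.0

    def test_non_increasing_and_bounded(self):
        t = NestingTree.caterpillar(16)
        s = cumulative_size_distribution(t)
        assert np.all(np.diff(s.y) <= 0)
        assert np.all((s.y >= 0) & (s.y <= 1))
        assert s.y[-1] == 0.0

    def test_exact_power_law_adjusted_is_constant(self):
        a = np.logspace(-3, 0, 50)
        s = MetricSeries(a, 0.01 / a)
        adj = adjusted_csd(s)
        assert adj.y == pytest.approx(np.full(50, 0.01))
        fit = fit_slope(adj, axes="loglog")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_fit_slope_recovers_exact_line(self):
        x = np.linspace(0, 1, 20)
        fit = fit_slope(MetricSeries(x, 3.0 - 0.5 * x), axes="linear")
        assert fit.slope == pytest.approx(-0.5)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_fit_slope_recovers_power_exponent(self):
        x = np.logspace(-2, 0, 20)
        fit = fit_slope(MetricSeries(x, 5 * x ** -1.7), axes="loglog")
        assert fit.slope == pytest.approx(-1.7)


class TestStrahler:
    def test_orders_complete_binary(self):
        t = NestingTree.complete_binary(3)
        orders = strahler_orders(t)
        assert orders[t.root] == 4
        assert list(stream_counts(t)) == [8, 4, 2, 1]

    def test_orders_caterpillar(self):
        t = NestingTree.caterpillar(16)
        orders = strahler_orders(t)
        assert orders[t.root] == 2
        assert list(stream_counts(t)) == [16, 1]

    def test_single_bifurcation(self):
        t = NestingTree.caterpillar(2)
        assert list(stream_counts(t)) == [2, 1]

    def test_complete_binary_ratio_exact(self):
        fit = bifurcation_ratio(NestingTree.complete_binary(3))
        assert fit.ratio == pytest.approx(2.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)
        assert not fit.two_point

    def test_constructed_geometric_progression(self):
        fit = fit_bifurcation_ratio([125, 25, 5, 1])
        assert fit.ratio == pytest.approx(5.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_caterpillar_two_point_fallback(self):
        fit = bifurcation_ratio(NestingTree.caterpillar(16))
        assert fit.two_point
        assert fit.ratio == pytest.approx(16.0)


# --------------------------------------------------------------------------
# naive re-derivations used as an independent check on random trees
# --------------------------------------------------------------------------

def _naive_asymmetry(t, nid):
    qs = []

    def walk(i):
        n = t.nodes[i]
        if n.is_leaf:
            return
        c1, c2 = (t.nodes[c] for c in n.children)
        qs.append(partition_asymmetry(c1.degree, c2.degree))
        walk(c1.id)
        walk(c2.id)

    walk(nid)
    return sum(qs) / len(qs)


def _naive_strahler(t, nid):
    n = t.nodes[nid]
    if n.is_leaf:
        return 1
    o1, o2 = (_naive_strahler(t, c) for c in n.children)
    return o1 + 1 if o1 == o2 else max(o1, o2)


def _naive_streams(t):
    orders = {n.id: _naive_strahler(t, n.id) for n in t.nodes.values()}
    heads = [n.id for n in t.nodes.values()
             if t.parent(n.id) is None or orders[t.parent(n.id)] != orders[n.id]]
    counts = {}
    for h in heads:
        counts[orders[h]] = counts.get(orders[h], 0) + 1
    return [counts.get(w, 0) for w in range(1, max(counts) + 1)]


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(4, 12), st.integers(0, 10_000))
def test_metrics_match_naive_recomputation_on_random_trees(n_leaves, seed):
    t = random_binary_tree(n_leaves, seed)
    A = subtree_asymmetries(t)
    orders = strahler_orders(t)
    for n in t.internal_nodes():
        assert A[n.id] == pytest.approx(_naive_asymmetry(t, n.id))
        assert orders[n.id] == _naive_strahler(t, n.id)
    assert list(stream_counts(t)) == _naive_streams(t)
    assert stream_counts(t)[0] == n_leaves
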