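import itertools
import math

import networkx as nx
import numpy as np
import pytest
import statsmodels.api as sm

from ancientborder import (
    Bipartition, contiguous_bipartitions, fit_side_glm, haplogroup_bias,
    random_bipartition_null, scan_border,
)
from ancientborder.borderscan import is_contiguous


def _brute_contiguous(graph, min_side=1):
    nodes = sorted(graph.nodes)
    out = set()
    for r in range(1, len(nodes)):
        for side in itertools.combinations(nodes, r):
            a, b = set(side), set(nodes) - set(side)
            if len(a) < min_side or len(b) < min_side:
                continue
            if (nx.is_connected(graph.subgraph(a))
                    and nx.is_connected(graph.subgraph(b))):
                out.add(Bipartition(frozenset(a), frozenset(b)).key())
    return out


def test_path_graph_bipartitions():
    g = nx.path_graph(["A", "B", "C"])
    keys = {b.key() for b in contiguous_bipartitions(g)}
    assert keys == {(("A",), ("B", "C")), (("A", "B"), ("C",))}


def test_triangle_keeps_all_splits():
    g = nx.complete_graph(["A", "B", "C"])
    assert len(contiguous_bipartitions(g)) == 3


@pytest.mark.parametrize("n", [4, 6, 9])
def test_path_of_n_nodes_has_n_minus_1_cuts(n):
    g = nx.path_graph([f"n{i:02d}" for i in range(n)])
    assert len(contiguous_bipartitions(g)) == n - 1


def test_enumeration_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for trial in range(12):
        n = int(rng.integers(4, 11))
        while True:
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2 ** 31)))
            if nx.is_connected(g):
                break
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for min_side in (1, 2):
            got = {b.key() for b in contiguous_bipartitions(g, min_side=min_side)}
            assert got == _brute_contiguous(g, min_side=min_side)


def test_enumeration_invariant_to_relabeling():
    g = nx.path_graph(["A", "B", "C", "D"])
    relabeled = nx.relabel_nodes(g, {"A": "D2", "B": "C2", "C": "B2", "D": "A2"})
    n1 = len(contiguous_bipartitions(g))
    n2 = len(contiguous_bipartitions(relabeled))
    assert n1 == n2 == 3


def test_oversized_graph_refused():
    g = nx.path_graph(30)
    with pytest.raises(ValueError, match="sampl"):
        contiguous_bipartitions(nx.relabel_nodes(g, str))


# --- GLM ---------------------------------------------------------------------

def test_glm_equal_frequencies_null():
    fit = fit_side_glm([10, 10, 10, 10], [50, 50, 50, 50],
                       [True, True, False, False])
    assert abs(fit.beta) < 1e-8
    assert fit.p == pytest.approx(1.0, abs=1e-6)


def test_glm_matches_pooled_2x2_closed_form(rng):
    for _ in range(20):
        k = int(rng.integers(2, 8))
        totals = rng.integers(20, 90, size=k)
        succ = rng.binomial(totals, rng.uniform(0.1, 0.9))
        side = np.zeros(k, bool)
        side[: max(1, k // 2)] = True
        a = succ[side].sum(); b = (totals - succ)[side].sum()
        c = succ[~side].sum(); d = (totals - succ)[~side].sum()
        if min(a, b, c, d) == 0:
            continue
        fit = fit_side_glm(succ, totals, side)
        log_or = math.log((a / b) / (c / d))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert fit.converged
        assert fit.beta == pytest.approx(log_or, abs=1e-6)
        assert fit.se == pytest.approx(se, abs=1e-6)


def test_glm_cross_checked_against_statsmodels():
    succ = np.array([12, 9, 30, 41, 35])
    totals = np.array([60, 55, 70, 80, 75])
    side = np.array([True, True, False, False, False])
    fit = fit_side_glm(succ, totals, side)
    X = sm.add_constant(side.astype(float))
    ref = sm.GLM(np.column_stack([succ, totals - succ]), X,
                 family=sm.families.Binomial()).fit()
    assert fit.beta == pytest.approx(ref.params[1], abs=1e-8)
    assert fit.se == pytest.approx(ref.bse[1], rel=1e-4)
    assert fit.p == pytest.approx(ref.pvalues[1], rel=1e-4)


def test_glm_separation_flagged():
    fit = fit_side_glm([0, 0, 10, 12], [30, 30, 30, 30],
                       [True, True, False, False])
    assert not fit.converged
    assert fit.p == 1.0


# --- scan --------------------------------------------------------------------

def _toy_counts(graph, side_a, p_hunt_a, p_hunt_b, p_farm_a, p_farm_b, n, rng):
    hunt, farm, totals = {}, {}, {}
    for node in graph.nodes:
        on_a = node in side_a
        hunt[node] = int(rng.binomial(n, p_hunt_a if on_a else p_hunt_b))
        farm[node] = int(rng.binomial(n, p_farm_a if on_a else p_farm_b))
        totals[node] = n
    return hunt, farm, totals


def test_single_edge_path_scan():
    g = nx.path_graph(["A", "B"])
    res = scan_border({"A": 5, "B": 20}, {"A": 25, "B": 10},
                      {"A": 50, "B": 50}, g)
    assert len(res.all_scores) == 1
    assert res.best.key() == (("A",), ("B",))


def test_scan_recovers_strong_planted_border(graph13, rng):
    from ancientborder import finland_partition
    part = finland_partition()
    planted = Bipartition(frozenset(part.codes("SW")), frozenset(part.codes("NE")))
    hits = 0
    for rep in range(10):
        hunt, farm, totals = _toy_counts(
            graph13, planted.side_a, 0.10, 0.45, 0.60, 0.25, 200, rng)
        res = scan_border(hunt, farm, totals, graph13)
        hits += res.best.key() == planted.key()
    assert hits >= 9  # very strong effect, large n


def test_scan_deterministic_under_seed(graph13, rng):
    hunt, farm, totals = _toy_counts(graph13, {"AL", "TU", "HA"},
                                     0.2, 0.3, 0.5, 0.45, 60, rng)
    r1 = scan_border(hunt, farm, totals, graph13, null_draws=5, seed=3)
    r2 = scan_border(hunt, farm, totals, graph13, null_draws=5, seed=3)
    assert r1.best.key() == r2.best.key()
    assert r1.null_products == r2.null_products


def test_null_draws_are_noncontiguous_and_reproducible(graph13):
    hunt = {n: 10 for n in graph13.nodes}
    farm = {n: 20 for n in graph13.nodes}
    totals = {n: 60 for n in graph13.nodes}
    splits, prods = random_bipartition_null(graph13, hunt, farm, totals,
                                            k=10, seed=9)
    assert len(splits) == len(prods) == 10
    for s in splits:
        assert not is_contiguous(graph13, s)
    splits2, prods2 = random_bipartition_null(graph13, hunt, farm, totals,
                                              k=10, seed=9)
    assert prods == prods2 and [s.key() for s in splits] == [s.key() for s in splits2]


def test_all_contiguous_graph_rejected_for_null():
    g = nx.complete_graph(["A", "B", "C", "D"])
    with pytest.raises(ValueError, match="contiguous"):
        random_bipartition_null(g, {n: 1 for n in g}, {n: 1 for n in g},
                                {n: 10 for n in g}, k=3, seed=0)


# --- haplogroup bias ---------------------------------------------------------

def test_bias_equal_frequencies_near_zero():
    counts = {"U": {"A": 20, "B": 20}}
    fits = haplogroup_bias(counts, {"A": 100, "B": 100}, side_a_nodes={"A"})
    assert abs(fits[0].beta) < 1e-8


def test_bias_matches_published_2x2_cells():
    # haplogroup U: 70 of 389 in SW vs 132 of 443 in NE
    counts = {"U": {"SW": 70, "NE": 132}}
    fits = haplogroup_bias(counts, {"SW": 389, "NE": 443}, side_a_nodes={"SW"})
    expected = math.log((70 / 319) / (132 / 311))
    assert fits[0].beta == pytest.approx(expected, abs=1e-6)
    assert fits[0].label == "U"
    assert fits[0].p < 0.001 and fits[0].tier == "***"


def test_bias_separation_flagged_and_small_groups_skipped():
    counts = {"onlyB": {"B": 30}, "rare": {"A": 2, "B": 3}}
    fits = haplogroup_bias(counts, {"A": 100, "B": 100}, side_a_nodes={"A"})
    by = {f.label: f for f in fits}
    assert "rare" not in by          # below min_count
    assert not by["onlyB"].converged  # separation: zero successes in side A
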