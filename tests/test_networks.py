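"""Graph construction, exact maximum clique, paracliques, topology, enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bxdnet.datatypes import ConfigurationError
from bxdnet.networks import (ParacliqueExtractor, build_graph,
                             correlation_pvalue, ergen_call,
                             extract_paracliques, maximum_clique,
                             node_topology, overlap_test, Paraclique)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_max_clique_size(G: nx.Graph) -> int:
    """Exhaustive subset-DP over bitmasks (exact for n <= 15)."""
    nodes = list(G.nodes)
    n = len(nodes)
    adj = [0] * n
    idx = {v: i for i, v in enumerate(nodes)}
    for u, v in G.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    best = 1 if n else 0
    is_clique = np.zeros(1 << n, dtype=bool)
    is_clique[0] = True
    for s in range(1, 1 << n):
        low = (s & -s).bit_length() - 1
        rest = s & (s - 1)
        if is_clique[rest] and (adj[low] & rest) == rest:
            is_clique[s] = True
            best = max(best, s.bit_count())
    return best


def brute_force_betweenness(G: nx.Graph) -> dict:
    """All-pairs shortest-path enumeration (exact for small n)."""
    out = {v: 0.0 for v in G.nodes}
    nodes = list(G.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def hypergeom_tail_sum(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    from math import comb
    return sum(comb(n, i) * comb(M - n, N - i) / comb(M, N)
               for i in range(k, min(n, N) + 1))


# ---------------------------------------------------------------------------

class TestBuildGraph:
    def test_strong_negative_correlation_is_an_edge(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, -x + np.linspace(0, 1.2, 10)],
                            index=["a", "b"])
        G = build_graph(expr, t=0.7)
        assert G.has_edge("a", "b")

    def test_threshold_boundary_inclusive(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        # construct y with sample correlation exactly 0.7
        e = rng.normal(size=40)
        xs = (x - x.mean()) / x.std()
        es = e - e.mean()
        es -= xs * (es @ xs) / (xs @ xs)
        es /= es.std()
        r0 = 0.7
        y = r0 * xs + np.sqrt(1 - r0 ** 2) * es
        expr = pd.DataFrame([x, y], index=["a", "b"])
        assert abs(np.corrcoef(x, y)[0, 1] - 0.7) < 1e-12
        assert build_graph(expr, t=0.7).has_edge("a", "b")

    def test_analytic_threshold_pvalue(self):
        assert correlation_pvalue(0.7, 27) == pytest.approx(4.8e-5,
                                                            rel=0.05)

    def test_zero_variance_rows_dropped(self):
        expr = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["flat", "b"])
        G = build_graph(expr)
        assert "flat" not in G


class TestMaximumClique:
    def test_complete_graph(self):
        assert maximum_clique(nx.complete_graph(5)) == {0, 1, 2, 3, 4}

    def test_five_cycle_lexicographic_tie_break(self):
        assert maximum_clique(nx.cycle_graph(5)) == {0, 1}

    def test_empty_graph(self):
        assert maximum_clique(nx.Graph()) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        G = nx.gnp_random_graph(n, 0.5, seed=seed)
        assert len(maximum_clique(G)) == brute_force_max_clique_size(G)


class TestParacliques:
    def _k10_plus_pendant(self, k_edges: int) -> nx.Graph:
        G = nx.complete_graph(10)
        for u in range(k_edges):
            G.add_edge("v", u)
        return G

    def test_glom_admits_vertex_at_exact_threshold(self):
        # ceil(0.7 * 10) = 7 core edges suffice
        out = extract_paracliques(self._k10_plus_pendant(7), min_size=5)
        assert len(out) == 1 and len(out[0]) == 11

    def test_glom_rejects_vertex_below_threshold(self):
        out = extract_paracliques(self._k10_plus_pendant(6), min_size=5)
        assert len(out) == 1 and len(out[0]) == 10

    def test_disjoint_cliques_extracted_in_size_order(self):
        G = nx.union(nx.complete_graph(8),
                     nx.relabel_nodes(nx.complete_graph(6),
                                      {i: f"b{i}" for i in range(6)}))
        out = extract_paracliques(G, min_size=5)
        assert [len(p) for p in out] == [8, 6]
        assert not set(out[0].members) & set(out[1].members)

    def test_min_core_stops_extraction(self):
        out = extract_paracliques(nx.complete_graph(4), min_core=5)
        assert out == []

    def test_invalid_glom_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_paracliques(nx.complete_graph(6), g=0.0)


class TestNodeTopology:
    def test_complete_subgraph(self):
        G = nx.complete_graph(6)
        P = Paraclique("p", list(range(6)), list(range(6)), 0.7)
        node_topology(P, G, G)
        assert set(P.degree.values()) == {5}
        assert set(P.betweenness.values()) == {0.0}

    def test_star_closed_form(self):
        n = 7
        G = nx.star_graph(n - 1)  # node 0 center
        P = Paraclique("p", list(G.nodes), list(G.nodes), 0.7)
        node_topology(P, G, G)
        assert P.betweenness[0] == pytest.approx((n - 1) * (n - 2) / 2)
        assert all(P.betweenness[v] == 0 for v in range(1, n))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_oracle(self, seed):
        G = nx.gnp_random_graph(11, 0.3, seed=seed)
        P = Paraclique("p", list(G.nodes), list(G.nodes), 0.7)
        node_topology(P, G, G)
        oracle = brute_force_betweenness(G)
        for v in G.nodes:
            assert P.betweenness[v] == pytest.approx(oracle[v], abs=1e-9)


class TestOverlap:
    def test_identical_sets_extreme_enrichment(self):
        A = set(range(50))
        odds, p = overlap_test(A, A, 1000)
        assert p == pytest.approx(hypergeom_tail_sum(50, 1000, 50, 50),
                                  rel=1e-9)
        assert p < 1e-50

    def test_expected_overlap_gives_odds_near_one(self):
        # |A| = 100, |B| = 100, background 1000 -> expected overlap 10
        A = set(range(100))
        B = set(range(90, 190))
        odds, _ = overlap_test(A, B, 1000)
        assert odds == pytest.approx(1.0, abs=0.15)

    def test_independent_random_sets_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(300):
            A = set(rng.choice(500, 40, replace=False))
            B = set(rng.choice(500, 40, replace=False))
            ps.append(overlap_test(A, B, 500)[1])
        # discrete p-values are conservative; check super-uniformity
        assert np.mean(np.array(ps) <= 0.05) < 0.08

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigurationError):
            overlap_test({1}, {1}, 0)


class TestErgen:
    def test_responsive_paraclique_enriched(self):
        responsive = set(range(100))  # 10% of background
        P = Paraclique("p", list(range(20)), list(range(20)), 0.7)
        out = ergen_call([P], responsive, 1000)
        assert out[0].enriched

    def test_random_paraclique_not_enriched(self):
        rng = np.random.default_rng(2)
        members = list(rng.choice(1000, 30, replace=False))
        responsive = set(range(100))
        out = ergen_call([Paraclique("p", members, members, 0.7)],
                         responsive, 1000)
        assert not out[0].enriched

    def test_single_paraclique_bonferroni_is_identity(self):
        P = Paraclique("p", list(range(10)), list(range(10)), 0.7)
        out = ergen_call([P], set(range(5)), 100)
        assert out[0].adjusted_p == pytest.approx(out[0].p_value)


class TestExtractor:
    def test_recovers_planted_modules(self, dataset):
        px = ParacliqueExtractor().fit(dataset.saline)
        modules = {m: set(v["genes"])
                   for m, v in dataset.truth.modules.items()}
        recovered = set()
        for P in px.paracliques_:
            for name, genes in modules.items():
                overlap = len(genes & set(P.members))
                if overlap >= 0.6 * len(genes):
                    recovered.add(name)
                    # paracliques are pure: members come from the one module
                    assert overlap >= 0.95 * len(P.members)
        assert recovered == set(modules)

    def test_extraction_deterministic(self, dataset):
        a = ParacliqueExtractor().fit(dataset.saline)
        b = ParacliqueExtractor().fit(dataset.saline)
        assert [p.members for p in a.paracliques_] == \
               [p.members for p in b.paracliques_]
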