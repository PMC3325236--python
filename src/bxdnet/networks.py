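"""Co-expression graphs, paraclique extraction, hubs and enrichment.

Co-expression structure is represented as an unweighted graph: vertices are
probe-sets and an edge is present whenever the absolute Pearson correlation
of two expression profiles across strains meets a threshold (default |r| >=
0.7; across 27 strains that corresponds to a two-sided correlation p of
about 5e-5).  The natural dense subgraph — a clique — is too brittle for
noisy expression data, so modules are extracted as *paracliques*: a maximum
clique core plus every remaining vertex adjacent to at least a fixed
proportion (the glom factor) of the core.  Extraction is iterative and the
resulting paracliques are vertex-disjoint.

Maximum clique is found exactly by branch-and-bound with a greedy-coloring
bound (Tomita-style, over bitset adjacency); among equally large cliques the
lexicographically smallest vertex-id set is returned, which makes extraction
fully deterministic.

Node importance within a paraclique combines degree (connectivity) on the
construction-threshold subgraph with betweenness centrality computed on a
more stringent |r| >= 0.9 subgraph, where bridging nodes between densely
interconnected subnetworks stand out.  Enrichment of paracliques for a set
of responsive probe-sets uses the one-tailed hypergeometric (Fisher's exact)
test with Bonferroni correction over the number of paracliques.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import ConfigurationError, DataError

__all__ = [
    "correlation_pvalue",
    "build_graph",
    "maximum_clique",
    "extract_paracliques",
    "node_topology",
    "overlap_test",
    "ergen_call",
    "Paraclique",
    "ErGeNResult",
    "ParacliqueExtractor",
]

logger = logging.getLogger(__name__)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t-transform.

    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom.
    """
    if n < 3:
        raise ConfigurationError("need n >= 3 for a correlation p-value")
    r = float(r)
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def build_graph(expr: pd.DataFrame, t: float = 0.7) -> nx.Graph:
    """Thresholded absolute-correlation graph over expression rows.

    Zero-variance rows are dropped with a warning; all remaining probe-sets
    become vertices and pairs with |Pearson r| >= t (inclusive) are joined.
    The graph records ``threshold`` and ``n_strains`` attributes.
    """
    if expr.shape[1] < 3:
        raise DataError("need at least 3 strains to build a correlation graph")
    var = expr.var(axis=1)
    keep = var > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d zero-variance row(s)", dropped)
    X = expr.loc[keep]
    ids = list(X.index)
    n = expr.shape[1]
    logger.info("edge threshold |r| >= %.3g at n = %d strains: "
                "correlation p = %.3g", t, n, correlation_pvalue(t, n))
    G = nx.Graph(threshold=float(t), n_strains=n)
    G.add_nodes_from(ids)
    if len(ids) >= 2:
        r = np.corrcoef(X.to_numpy())
        iu, ju = np.triu_indices(len(ids), k=1)
        hit = np.abs(r[iu, ju]) >= t
        G.add_edges_from((ids[i], ids[j])
                         for i, j in zip(iu[hit], ju[hit]))
    return G


# ---------------------------------------------------------------------------
# exact maximum clique (branch and bound with greedy-coloring bound)

def _greedy_color(cand: int, adj: list[int]) -> tuple[list[int], list[int]]:
    """Order candidate vertices by greedy color class; returns (order, bound).

    Vertices in the same color class are pairwise non-adjacent, so any clique
    contains at most one per class; a vertex's class number is an upper bound
    on the clique extension through it and the list is emitted in
    non-decreasing bound order.
    """
    order, bounds = [], []
    uncolored = cand
    color = 0
    while uncolored:
        color += 1
        avail = uncolored
        while avail:
            v = (avail & -avail).bit_length() - 1
            order.append(v)
            bounds.append(color)
            avail &= ~adj[v]
            avail &= ~(1 << v)
            uncolored &= ~(1 << v)
    return order, bounds


def _bb_max_clique(adj: list[int], cand: int, stop_at: int | None = None
                   ) -> tuple[int, int]:
    """Largest clique (as bitmask) within ``cand``; early exit at stop_at.

    Returns ``(size, mask)`` of the first maximum clique encountered under
    the coloring order (ties NOT lexicographically resolved here).
    """
    best_size = 0
    best_mask = 0

    def expand(current: int, size: int, cand: int):
        nonlocal best_size, best_mask
        if stop_at is not None and best_size >= stop_at:
            return
        if cand == 0:
            if size > best_size:
                best_size, best_mask = size, current
            return
        order, bounds = _greedy_color(cand, adj)
        for i in range(len(order) - 1, -1, -1):
            if size + bounds[i] <= best_size:
                return
            if stop_at is not None and best_size >= stop_at:
                return
            v = order[i]
            expand(current | (1 << v), size + 1, cand & adj[v])
            cand &= ~(1 << v)

    expand(0, 0, cand)
    return best_size, best_mask


def _node_key(v):
    # total order even for graphs mixing int and str vertex ids
    return (v.__class__.__name__, v)


def maximum_clique(G: nx.Graph) -> set:
    """Exact maximum clique; ties broken to the lexicographically smallest set.

    Vertex ids are compared under their natural sort order.  Empty graph
    yields the empty set.
    """
    nodes = sorted(G.nodes, key=_node_key)
    if not nodes:
        return set()
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in G.edges:
        if u == v:
            continue
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    full = (1 << len(nodes)) - 1
    omega, _ = _bb_max_clique(adj, full)

    # lexicographic refinement: greedily commit the smallest-id vertex whose
    # neighborhood still admits a clique of the remaining size
    chosen: list[int] = []
    cand = full
    while len(chosen) < omega:
        need = omega - len(chosen) - 1
        mask = cand
        while mask:
            v = (mask & -mask).bit_length() - 1
            sub = cand & adj[v]
            size, _ = _bb_max_clique(adj, sub, stop_at=need)
            if size >= need:
                chosen.append(v)
                cand = sub
                break
            mask &= mask - 1
    return {nodes[i] for i in chosen}


@dataclass
class Paraclique:
    """A maximum-clique core plus glommed members, with topology scores."""

    id: str
    core: list
    members: list
    glom_factor: float
    edge_density: float = float("nan")
    degree: dict = field(default_factory=dict)
    betweenness: dict = field(default_factory=dict)
    scaled_degree: dict = field(default_factory=dict)
    scaled_betweenness: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def _density(G: nx.Graph, members) -> float:
    sub = G.subgraph(members)
    n = sub.number_of_nodes()
    if n < 2:
        return 1.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def extract_paracliques(G: nx.Graph, g: float = 0.7, min_core: int = 5,
                        min_size: int = 10) -> list[Paraclique]:
    """Iteratively extract vertex-disjoint paracliques.

    Loop: find the maximum clique; stop when its size drops below
    ``min_core``.  In a single pass, glom every remaining vertex adjacent to
    at least ``ceil(g * |core|)`` core vertices (boundary inclusive).  Emit
    the paraclique if it has at least ``min_size`` members, remove its
    members either way, repeat.  Edge densities refer to the construction
    graph.
    """
    if not 0 < g <= 1:
        raise ConfigurationError("glom factor must be in (0, 1]")
    H = G.copy()
    out: list[Paraclique] = []
    serial = 0
    while H.number_of_nodes() > 0:
        core = maximum_clique(H)
        if len(core) < min_core:
            break
        need = ceil(g * len(core))
        glommed = [v for v in H.nodes if v not in core
                   and sum(1 for u in core if H.has_edge(v, u)) >= need]
        members = sorted(core, key=_node_key) + sorted(glommed, key=_node_key)
        if len(members) >= min_size:
            serial += 1
            out.append(Paraclique(
                id=f"PC{serial}", core=sorted(core, key=_node_key),
                members=members,
                glom_factor=g, edge_density=_density(G, members)))
        H.remove_nodes_from(members)
    return out


def node_topology(P: Paraclique, G07: nx.Graph, G09: nx.Graph) -> Paraclique:
    """Fill per-node degree and betweenness scores of a paraclique in place.

    Degree counts edges to other members in the induced construction-
    threshold subgraph; betweenness uses shortest-path counting in the
    induced stringent-threshold subgraph (disconnected pairs contribute 0).
    Scaled variants are normalized to [0, 1] by (n-1) and (n-1)(n-2)/2.
    """
    members = [v for v in P.members if v in G07]
    n = len(members)
    sub07 = G07.subgraph(members)
    sub09 = G09.subgraph([v for v in P.members if v in G09])
    deg = dict(sub07.degree())
    btw = nx.betweenness_centrality(sub09, normalized=False)
    P.degree = {v: int(deg.get(v, 0)) for v in P.members}
    P.betweenness = {v: float(btw.get(v, 0.0)) for v in P.members}
    dmax = n - 1 if n > 1 else 1
    bmax = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    P.scaled_degree = {v: d / dmax for v, d in P.degree.items()}
    P.scaled_betweenness = {v: b / bmax for v, b in P.betweenness.items()}
    return P


def overlap_test(setA, setB, background: int) -> tuple[float, float]:
    """Enrichment of the overlap of two sets drawn from a finite universe.

    Returns ``(odds_ratio, p)`` where p is the one-tailed hypergeometric
    upper tail P(overlap >= observed) and the odds ratio comes from the
    2x2 membership table (inf when a zero cell makes it unbounded).
    """
    if background <= 0:
        raise ConfigurationError("background universe must be non-empty")
    A, B = set(setA), set(setB)
    a = len(A & B)
    b = len(A) - a
    c = len(B) - a
    d = background - len(A) - len(B) + a
    if d < 0:
        raise DataError("sets exceed the stated background universe")
    p = float(stats.hypergeom.sf(a - 1, background, len(B), len(A)))
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return odds, p


@dataclass
class ErGeNResult:
    """Responsive-gene enrichment verdict for one paraclique."""

    paraclique_id: str
    overlap: int
    size: int
    p_value: float
    adjusted_p: float
    enriched: bool


def ergen_call(paracliques: list[Paraclique], responsive_set,
               background: int, alpha: float = 0.05) -> list[ErGeNResult]:
    """Flag paracliques enriched for responsive probe-sets.

    Bonferroni adjustment over the number of paracliques tested; enriched
    when the adjusted p-value is <= ``alpha``.
    """
    responsive = set(responsive_set)
    m = len(paracliques)
    out = []
    for P in paracliques:
        _, p = overlap_test(P.members, responsive, background)
        adj = min(1.0, p * m)
        out.append(ErGeNResult(P.id, len(set(P.members) & responsive),
                               len(P.members), p, adj, adj <= alpha))
    return out


class ParacliqueExtractor(BaseEstimator):
    """Extract co-expression paracliques from an expression matrix.

    Clustering-style estimator: fit on a probe-set x strain DataFrame; the
    fitted object carries the construction and stringent graphs, the list of
    vertex-disjoint paracliques with per-node topology scores, and a member
    table.

    Parameters
    ----------
    edge_threshold : float, default 0.7
        |r| threshold for the construction graph.
    stringent_threshold : float, default 0.9
        |r| threshold of the subgraph used for betweenness centrality.
    glom_factor : float, default 0.7
        Minimum fraction of core-clique edges a vertex needs to be glommed.
    min_core, min_size : int
        Smallest admissible core clique and emitted paraclique.

    Attributes
    ----------
    graph_, stringent_graph_ : networkx.Graph
    paracliques_ : list of Paraclique
    labels_ : pandas.Series mapping member probe-sets to paraclique ids.
    """

    def __init__(self, edge_threshold: float = 0.7,
                 stringent_threshold: float = 0.9, glom_factor: float = 0.7,
                 min_core: int = 5, min_size: int = 10):
        self.edge_threshold = edge_threshold
        self.stringent_threshold = stringent_threshold
        self.glom_factor = glom_factor
        self.min_core = min_core
        self.min_size = min_size

    def fit(self, X: pd.DataFrame, y=None):
        self.graph_ = build_graph(X, t=self.edge_threshold)
        self.stringent_graph_ = build_graph(X, t=self.stringent_threshold)
        self.paracliques_ = extract_paracliques(
            self.graph_, g=self.glom_factor, min_core=self.min_core,
            min_size=self.min_size)
        for P in self.paracliques_:
            node_topology(P, self.graph_, self.stringent_graph_)
        self.labels_ = pd.Series(
            {v: P.id for P in self.paracliques_ for v in P.members},
            dtype=object, name="paraclique")
        return self

    def member_table(self) -> pd.DataFrame:
        """Tidy per-member topology table across all fitted paracliques."""
        rows = []
        for P in self.paracliques_:
            for v in P.members:
                rows.append({
                    "paraclique": P.id, "probe_set": v,
                    "in_core": v in set(P.core),
                    "degree": P.degree.get(v),
                    "betweenness": P.betweenness.get(v),
                    "scaled_degree": P.scaled_degree.get(v),
                    "scaled_betweenness": P.scaled_betweenness.get(v),
                })
        return pd.DataFrame(rows)
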