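"""Node-scoring methods, hub aggregation and over-representation analysis.

Implements the eleven local/global centrality scores used for hub calling
(MCC, DMNC, MNC, EPC, Radiality, Degree, Closeness, Betweenness,
EdgeBetweenness, ClusteringCoefficient, Stress; BottleNeck is additionally
available), top-k extraction with deterministic tie rules, frequency-of-
occurrence hub aggregation, the one-sided hypergeometric over-representation
test with Benjamini-Hochberg control, and enrichment-map construction from
gene-set similarity (Jaccard / overlap coefficient).

All scores are computed on the undirected simple projection.  Definitions:

* MCC(v)   = sum over maximal cliques C (|C| >= 2) containing v of (|C|-1)!
* MNC(v)   = node count of the largest connected component of the subgraph
             induced by N(v) (v excluded)
* DMNC(v)  = |E| / |V|**eps of that component, eps = 1.7; 0 when |V| < 2
* EPC(v)   = mean, over seeded percolation realizations keeping each edge
             independently with probability 1/2, of the size of the
             component containing v
* Radiality(v) = sum_{u in C_v} (diam(C_v) + 1 - d(v,u)) / (|V_G| - 1)
* Stress(v) = number of shortest paths (over all ordered source/target
              pairs, halved) passing through v as an interior node
* EdgeBetweenness(v) = sum of unnormalized edge betweenness over incident edges
* BottleNeck(v) = number of source nodes s for which more than |T_s|/4 of the
              shortest-path tree T_s (smallest-id predecessor) routes through v
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .netcore import as_undirected

METHODS = (
    "MCC", "DMNC", "MNC", "EPC", "Radiality", "Degree", "Closeness",
    "Betweenness", "EdgeBetweenness", "ClusteringCoefficient", "Stress",
)

DMNC_EPS = 1.7
EPC_REALIZATIONS = 1000


@dataclass
class NodeScoreTable:
    """Scores and min-tie ranks for one method (rank 1 = best)."""
    method: str
    scores: dict[str, float]
    higher_is_better: bool = True
    ranks: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        sign = -1.0 if self.higher_is_better else 1.0
        vals = {n: sign * s for n, s in self.scores.items()}
        ordered = sorted(vals.values())
        self.ranks = {n: ordered.index(v) + 1 for n, v in vals.items()}


@dataclass(frozen=True)
class HubSummary:
    node: str
    occurrence: int
    methods: tuple[str, ...]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    p_value: float
    adjusted_p: float
    cluster_frequency: float
    overlap: int


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _bfs(g: nx.Graph, source) -> tuple[dict, dict, dict, list]:
    """Distances, path counts, predecessor lists and reverse finishing order."""
    dist = {source: 0}
    sigma = {source: 1}
    preds: dict = {source: []}
    order = []
    q = deque([source])
    while q:
        v = q.popleft()
        order.append(v)
        for w in g[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                preds[w] = []
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, preds, order


def _neighbor_component(g: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the subgraph induced by N(v)."""
    sub = g.subgraph(list(g[v]))
    if sub.number_of_nodes() == 0:
        return sub
    comps = sorted(nx.connected_components(sub),
                   key=lambda c: (-len(c), -sub.subgraph(c).number_of_edges(),
                                  min(map(str, c))))
    return sub.subgraph(comps[0])


def _mcc(g: nx.Graph) -> dict:
    scores = {v: 0.0 for v in g}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def _mnc(g: nx.Graph) -> dict:
    return {v: float(_neighbor_component(g, v).number_of_nodes()) for v in g}


def _dmnc(g: nx.Graph, eps: float = DMNC_EPS) -> dict:
    out = {}
    for v in g:
        comp = _neighbor_component(g, v)
        nv = comp.number_of_nodes()
        out[v] = comp.number_of_edges() / nv ** eps if nv >= 2 else 0.0
    return out


def _epc(g: nx.Graph, realizations: int, seed: int) -> dict:
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))
    eidx = [(index[a], index[b]) for a, b in edges]
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(nodes))
    parent = np.empty(len(nodes), dtype=np.intp)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for _ in range(realizations):
        keep = rng.random(len(edges)) < 0.5
        parent[:] = np.arange(len(nodes))
        for (a, b), k in zip(eidx, keep):
            if k:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
        roots = np.fromiter((find(i) for i in range(len(nodes))), dtype=np.intp)
        sizes = np.bincount(roots, minlength=len(nodes))
        totals += sizes[roots]
    return {v: float(totals[index[v]] / realizations) for v in nodes}


def _radiality(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    out = {v: 0.0 for v in g}
    if n < 2:
        return out
    for comp_nodes in nx.connected_components(g):
        comp = g.subgraph(comp_nodes)
        if comp.number_of_nodes() < 2:
            continue
        ecc = nx.eccentricity(comp)
        diam = max(ecc.values())
        for v in comp:
            dist = nx.single_source_shortest_path_length(comp, v)
            out[v] = sum(diam + 1 - d for u, d in dist.items() if u != v) / (n - 1)
    return out


def _stress(g: nx.Graph) -> dict:
    """Brandes-style accumulation of shortest-path counts through each node."""
    stress = {v: 0.0 for v in g}
    for s in g:
        dist, sigma, preds, order = _bfs(g, s)
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
            if w != s:
                stress[w] += delta[w]
    return {v: x / 2.0 for v, x in stress.items()}


def _edge_betweenness_node(g: nx.Graph) -> dict:
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    out = {v: 0.0 for v in g}
    for (a, b), val in eb.items():
        out[a] += val
        out[b] += val
    return out


def _bottleneck(g: nx.Graph) -> dict:
    scores = {v: 0.0 for v in g}
    for s in g:
        dist, sigma, preds, order = _bfs(g, s)
        tree_size = len(order)
        if tree_size < 2:
            continue
        # shortest-path tree with deterministic smallest-id predecessor
        parent = {v: min(preds[v], key=str) for v in order if v != s}
        load = {v: 1 for v in order}          # each node carries itself
        for v in reversed(order):
            if v != s:
                load[parent[v]] += load[v]
        for v in order:
            if v != s and load[v] > tree_size / 4.0:
                scores[v] += 1
    return scores


def score_nodes(net, method: str, *, seed: int = 0,
                epc_realizations: int = EPC_REALIZATIONS,
                dmnc_eps: float = DMNC_EPS) -> NodeScoreTable:
    """Score every node with one of the 11 methods (plus ``BottleNeck``).

    Deterministic except EPC, which averages ``epc_realizations`` seeded
    edge-percolation draws.  Isolated nodes score 0 for neighborhood methods.
    """
    g = as_undirected(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot score an empty network")
    if method == "MCC":
        scores = _mcc(g)
    elif method == "DMNC":
        scores = _dmnc(g, dmnc_eps)
    elif method == "MNC":
        scores = _mnc(g)
    elif method == "EPC":
        scores = _epc(g, epc_realizations, seed)
    elif method == "Radiality":
        scores = _radiality(g)
    elif method == "Degree":
        scores = {v: float(d) for v, d in g.degree()}
    elif method == "Closeness":
        scores = nx.closeness_centrality(g, wf_improved=False)
    elif method == "Betweenness":
        scores = nx.betweenness_centrality(g, normalized=False)
    elif method == "EdgeBetweenness":
        scores = _edge_betweenness_node(g)
    elif method == "ClusteringCoefficient":
        scores = nx.clustering(g)
    elif method == "Stress":
        scores = _stress(g)
    elif method == "BottleNeck":
        scores = _bottleneck(g)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return NodeScoreTable(method=method, scores={v: float(s) for v, s in scores.items()})


def top_k(table: NodeScoreTable, k: int = 10) -> list[str]:
    """Best k nodes by the table's orientation; ties broken by node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sign = -1.0 if table.higher_is_better else 1.0
    ordered = sorted(table.scores, key=lambda v: (sign * table.scores[v], str(v)))
    return ordered[:k]


def aggregate_hubs(lists: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
                   n_hubs: int = 5) -> list[HubSummary]:
    """Rank nodes by how many methods' top-k lists contain them.

    ``lists`` maps method name -> top-k node list (or is a plain sequence of
    lists).  Order of supply does not matter; ties break by node id.
    """
    if isinstance(lists, Mapping):
        items = list(lists.items())
    else:
        items = [(f"method{i}", lst) for i, lst in enumerate(lists)]
    if not items:
        raise ValueError("need at least one top-k list")
    membership: dict[str, list[str]] = {}
    for name, lst in items:
        for node in lst:
            membership.setdefault(node, []).append(name)
    summaries = [
        HubSummary(node=n, occurrence=len(ms), methods=tuple(sorted(ms)))
        for n, ms in membership.items()
    ]
    summaries.sort(key=lambda h: (-h.occurrence, str(h.node)))
    return summaries[:n_hubs]


# ---------------------------------------------------------------------------
# over-representation and enrichment map
# ---------------------------------------------------------------------------

def term_enrichment(query: Iterable[str], annotation: Mapping[str, Sequence[str]],
                    universe: Iterable[str], alpha: float = 0.05,
                    significant_only: bool = True) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation with BH step-up.

    For a term covering K of N universe genes and a query of size n with k
    hits, p = P(X >= k), X ~ Hypergeom(N, K, n).  BH is applied across
    exactly the terms with nonzero query overlap.  Results are sorted by
    adjusted then raw p; ``significant_only`` keeps adjusted_p <= alpha.
    """
    universe = set(universe)
    query = set(query)
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_univ = len(universe)
    rows = []
    for term, genes in annotation.items():
        members = set(genes) & universe
        k = len(query & members)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, n_univ, len(members), len(query)))
        rows.append((term, members, k, min(p, 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term=term, description=term, p_value=p,
                         adjusted_p=float(max(a, p)), overlap=k,
                         cluster_frequency=k / len(query))
        for (term, members, k, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term))
    if significant_only:
        results = [r for r in results if r.adjusted_p <= alpha]
    return results


def set_similarity(a: Iterable[str], b: Iterable[str], kind: str = "jaccard") -> float:
    a, b = set(a), set(b)
    inter = len(a & b)
    if kind == "jaccard":
        union = len(a | b)
        return inter / union if union else 0.0
    if kind == "overlap":
        m = min(len(a), len(b))
        return inter / m if m else 0.0
    raise ValueError(f"unknown similarity {kind!r}")


def enrichment_map(sets: Mapping[str, tuple[Sequence[str], float]],
                   similarity: str = "jaccard", cutoff: float = 0.25) -> nx.Graph:
    """Gene-set similarity graph: nodes carry set size and p-value, edges the
    Jaccard or overlap coefficient; edges below ``cutoff`` are omitted."""
    g = nx.Graph()
    names = list(sets)
    for name in names:
        genes, p = sets[name]
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        g.add_node(name, size=len(set(genes)), p_value=p)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            w = set_similarity(sets[a][0], sets[b][0], similarity)
            if w >= cutoff and w > 0:
                g.add_edge(a, b, weight=w)
    return g
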