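"""Bipartite miRNA-target network model, I/O, global statistics and ordering.

The regulatory network is a directed bipartite graph: miRNA nodes point at
their target genes.  Summary statistics (the eleven rows reported by desktop
network tools: node/edge counts, average neighbors, diameter, radius,
characteristic path length, clustering coefficient, density, components,
heterogeneity, centralization) are computed on the undirected simple
projection; the degree filter uses directed out-degree, mirroring how the
two views are used in practice.

Path statistics (diameter, radius, characteristic path length) are computed
within the largest connected component - on a multi-component graph they are
undefined globally; the convention is recorded in ``NetworkStats.conventions``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from . import io as _io

MIRNA = "miRNA"
TARGET = "target"


class PartitionError(ValueError):
    """A node id appears in both partitions."""


class BipartiteNetwork:
    """Directed bipartite graph of miRNA -> target regulatory edges.

    Duplicate edges collapse; self edges are impossible because partitions
    must be disjoint (the same id on both sides raises ``PartitionError``).
    Node insertion order is preserved for deterministic output.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 mirnas: Iterable[str] = (), targets: Iterable[str] = ()):
        self._g = nx.DiGraph()
        for m in mirnas:
            self.add_mirna(m)
        for t in targets:
            self.add_target(t)
        for m, t in edges:
            self.add_edge(m, t)

    # -- construction ------------------------------------------------------
    def add_mirna(self, node: str) -> None:
        self._check(node, MIRNA)
        self._g.add_node(node, partition=MIRNA)

    def add_target(self, node: str) -> None:
        self._check(node, TARGET)
        self._g.add_node(node, partition=TARGET)

    def add_edge(self, mirna: str, target: str) -> None:
        if mirna == target:
            raise PartitionError(f"self edge {mirna!r}: a node cannot be in both partitions")
        self.add_mirna(mirna)
        self.add_target(target)
        self._g.add_edge(mirna, target)

    def _check(self, node: str, part: str) -> None:
        existing = self._g.nodes.get(node, {}).get("partition")
        if existing is not None and existing != part:
            raise PartitionError(f"node {node!r} appears as both {existing} and {part}")

    # -- views -------------------------------------------------------------
    @property
    def mirnas(self) -> list[str]:
        return [n for n, d in self._g.nodes(data=True) if d["partition"] == MIRNA]

    @property
    def targets(self) -> list[str]:
        return [n for n, d in self._g.nodes(data=True) if d["partition"] == TARGET]

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def partition_of(self, node: str) -> str:
        return self._g.nodes[node]["partition"]

    def out_degree(self, mirna: str) -> int:
        return self._g.out_degree(mirna)

    def to_directed(self) -> nx.DiGraph:
        return self._g.copy()

    def to_undirected(self) -> nx.Graph:
        return nx.Graph(self._g)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (set(self.edges) == set(other.edges)
                and set(self.mirnas) == set(other.mirnas)
                and set(self.targets) == set(other.targets))

    def __repr__(self) -> str:
        return f"BipartiteNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def as_undirected(net: "BipartiteNetwork | nx.Graph | nx.DiGraph") -> nx.Graph:
    """Undirected simple-graph view of a bipartite network or a bare graph."""
    if isinstance(net, BipartiteNetwork):
        return net.to_undirected()
    if isinstance(net, nx.DiGraph):
        return nx.Graph(net)
    return net


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_network(path, dialect: str = "tsv") -> BipartiteNetwork:
    """Read an edge list (``tsv``: miRNA<TAB>target per line; ``sif``:
    source relation target...).  Duplicate records collapse."""
    if dialect == "tsv":
        edges = _io.read_edge_tsv(path)
    elif dialect == "sif":
        edges = _io.read_sif(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return BipartiteNetwork(edges)


def write_network(net: BipartiteNetwork, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _io.write_edge_tsv(net.edges, path)
    elif dialect == "sif":
        _io.write_sif(net.edges, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# global statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    radius: int
    char_path_length: float
    clustering_coefficient: float
    density: float
    n_components: int
    heterogeneity: float
    centralization: float
    conventions: dict = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_nodes", "n_edges", "avg_neighbors", "diameter", "radius",
            "char_path_length", "clustering_coefficient", "density",
            "n_components", "heterogeneity", "centralization")}
        return d


def _largest_component(g: nx.Graph) -> set:
    # deterministic pick: most nodes, then the one containing the smallest id
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(map(str, c))))
    return comps[0]


def global_statistics(net: BipartiteNetwork | nx.Graph) -> NetworkStats:
    """Eleven summary statistics of the undirected simple projection.

    avg_neighbors is the mean distinct-neighbor count; density is
    2E/(N(N-1)); local clustering of degree<2 nodes counts as 0 and enters
    the mean; heterogeneity is sqrt(var(k))/mean(k) (population variance);
    centralization is (N/(N-2)) * (k_max/(N-1) - density).
    """
    g = as_undirected(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("statistics of an empty network are undefined")
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)

    avg_neighbors = float(degrees.mean())
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    clustering = float(np.mean(list(nx.clustering(g).values())))
    n_components = nx.number_connected_components(g)

    giant = g.subgraph(_largest_component(g))
    if giant.number_of_nodes() > 1:
        ecc = nx.eccentricity(giant)
        diameter = max(ecc.values())
        radius = min(ecc.values())
        cpl = nx.average_shortest_path_length(giant)
    else:
        diameter = radius = 0
        cpl = 0.0

    mean_k = degrees.mean()
    heterogeneity = float(math.sqrt(degrees.var()) / mean_k) if mean_k > 0 else 0.0
    if n > 2:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    else:
        centralization = 0.0

    return NetworkStats(
        n_nodes=n, n_edges=e, avg_neighbors=avg_neighbors,
        diameter=int(diameter), radius=int(radius), char_path_length=float(cpl),
        clustering_coefficient=clustering, density=float(density),
        n_components=n_components, heterogeneity=heterogeneity,
        centralization=float(centralization),
        conventions={
            "projection": "undirected simple graph",
            "path_stats": "largest connected component",
            "clustering_deg_lt_2": "counted as 0, included in mean",
            "heterogeneity_variance": "population (ddof=0)",
        },
    )


# ---------------------------------------------------------------------------
# filters and components
# ---------------------------------------------------------------------------

def filter_by_out_degree(net: BipartiteNetwork, min_deg: int, max_deg: int) -> BipartiteNetwork:
    """Keep miRNA nodes whose out-degree lies in [min_deg, max_deg]
    (bounds inclusive); targets left orphaned are dropped."""
    if min_deg > max_deg:
        raise ValueError(f"min_deg {min_deg} > max_deg {max_deg}")
    kept_mirnas = [m for m in net.mirnas if min_deg <= net.out_degree(m) <= max_deg]
    kept = set(kept_mirnas)
    edges = [(m, t) for m, t in net.edges if m in kept]
    out = BipartiteNetwork(mirnas=kept_mirnas)
    for m, t in edges:
        out.add_edge(m, t)
    return out


def connected_components(net: BipartiteNetwork | nx.Graph) -> list[list[str]]:
    """Undirected components, each sorted, ordered by smallest member id."""
    g = as_undirected(net)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


# ---------------------------------------------------------------------------
# simulated-annealing node ordering
# ---------------------------------------------------------------------------

def anneal_order(net: BipartiteNetwork | nx.Graph, *, t_start: float = 1.0,
                 cooling: float = 0.95, proposals_per_node: int = 100,
                 seed: int = 0) -> list[str]:
    """Order nodes so the most clustered/heavily connected sit last ("bottom").

    Maximizes sum_i position(i) * w(i) with w = degree * (1 + local
    clustering) by a seeded Metropolis schedule with geometric cooling
    (T <- 0.95 T, 100*N transposition proposals), followed by a
    deterministic adjacent-swap polish.  Equal-energy proposals are
    rejected, so an all-tied weight vector leaves the input order intact.
    """
    g = as_undirected(net)
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot order an empty network")
    clust = nx.clustering(g)
    w = np.array([g.degree(v) * (1.0 + clust[v]) for v in nodes], dtype=float)

    order = np.arange(n)
    rng = np.random.default_rng(seed)
    temp = t_start
    n_props = proposals_per_node * n
    # energy = -sum(position * weight); swap of positions i<j changes it by
    # (w[order[i]] - w[order[j]]) * (j - i)
    for step in range(n_props):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        if i > j:
            i, j = j, i
        delta = (w[order[i]] - w[order[j]]) * (j - i)
        if delta < 0 or (delta > 0 and rng.random() < math.exp(-delta / max(temp, 1e-12))):
            order[i], order[j] = order[j], order[i]
        if (step + 1) % n == 0:
            temp *= cooling

    # deterministic polish: stable adjacent swaps until locally optimal
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            if w[order[i]] > w[order[i + 1]]:
                order[i], order[i + 1] = order[i + 1], order[i]
                improved = True
    return [nodes[k] for k in order]
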