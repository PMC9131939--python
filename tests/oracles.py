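"""Independent brute-force oracles for small graphs, sequences and networks.

Everything here is deliberately naive (Floyd-Warshall distances, exhaustive
path / subset enumeration, plain loops) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = float("inf")


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def floyd_warshall(nodes, edges):
    dist = {(a, b): (0 if a == b else INF) for a in nodes for b in nodes}
    for a, b in edges:
        dist[a, b] = dist[b, a] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def all_shortest_paths(adj, dist, s, t):
    """Every shortest s-t path as a node tuple, by exhaustive DFS."""
    if dist[s, t] == INF:
        return []
    out = []

    def walk(path):
        v = path[-1]
        if v == t:
            out.append(tuple(path))
            return
        for w in adj[v]:
            if dist[s, w] == len(path) and dist[w, t] == dist[s, t] - len(path):
                walk(path + [w])

    walk([s])
    return out


def components(nodes, edges):
    adj = adjacency(nodes, edges)
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# centrality oracles
# ---------------------------------------------------------------------------

def maximal_cliques(nodes, edges):
    eset = {frozenset(e) for e in edges}
    nodes = list(nodes)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(frozenset(p) in eset for p in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


def mcc(nodes, edges):
    cl = maximal_cliques(nodes, edges)
    return {v: float(sum(math.factorial(len(c) - 1) for c in cl if v in c))
            for v in nodes}


def _neighbor_comp(nodes, edges, v):
    adj = adjacency(nodes, edges)
    nbrs = adj[v]
    sub_edges = [(a, b) for a, b in edges if a in nbrs and b in nbrs]
    if not nbrs:
        return set(), []
    comps = components(sorted(nbrs, key=str), sub_edges)
    comps.sort(key=lambda c: (-len(c),
                              -sum(1 for a, b in sub_edges if a in c and b in c),
                              min(map(str, c))))
    best = comps[0]
    return best, [(a, b) for a, b in sub_edges if a in best and b in best]


def mnc(nodes, edges):
    return {v: float(len(_neighbor_comp(nodes, edges, v)[0])) for v in nodes}


def dmnc(nodes, edges, eps=1.7):
    out = {}
    for v in nodes:
        comp, comp_edges = _neighbor_comp(nodes, edges, v)
        out[v] = len(comp_edges) / len(comp) ** eps if len(comp) >= 2 else 0.0
    return out


def degree(nodes, edges):
    adj = adjacency(nodes, edges)
    return {v: float(len(adj[v])) for v in nodes}


def closeness(nodes, edges):
    dist = floyd_warshall(nodes, edges)
    out = {}
    for v in nodes:
        reach = [dist[v, u] for u in nodes if u != v and dist[v, u] < INF]
        out[v] = len(reach) / sum(reach) if reach and sum(reach) > 0 else 0.0
    return out


def betweenness(nodes, edges):
    adj = adjacency(nodes, edges)
    dist = floyd_warshall(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def stress(nodes, edges):
    adj = adjacency(nodes, edges)
    dist = floyd_warshall(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        for p in all_shortest_paths(adj, dist, s, t):
            for v in p[1:-1]:
                out[v] += 1.0
    return out


def edge_betweenness_node(nodes, edges):
    adj = adjacency(nodes, edges)
    dist = floyd_warshall(nodes, edges)
    eb = {frozenset(e): 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, dist, s, t)
        for p in paths:
            for a, b in zip(p, p[1:]):
                eb[frozenset((a, b))] += 1.0 / len(paths)
    out = {v: 0.0 for v in nodes}
    for e, val in eb.items():
        for v in e:
            out[v] += val
    return out


def clustering(nodes, edges):
    adj = adjacency(nodes, edges)
    eset = {frozenset(e) for e in edges}
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(adj[v], 2)
                    if frozenset((a, b)) in eset)
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def radiality(nodes, edges):
    n = len(nodes)
    dist = floyd_warshall(nodes, edges)
    out = {v: 0.0 for v in nodes}
    if n < 2:
        return out
    for comp in components(nodes, edges):
        if len(comp) < 2:
            continue
        diam = max(dist[a, b] for a in comp for b in comp)
        for v in comp:
            out[v] = sum(diam + 1 - dist[v, u] for u in comp if u != v) / (n - 1)
    return out


def epc(nodes, edges, realizations, seed):
    """Same seeded percolation draws as the implementation (edges sorted by
    id, one uniform vector per realization), components found naively."""
    nodes = list(nodes)
    edges = sorted(edges, key=lambda e: (str(e[0]), str(e[1])))
    rng = np.random.default_rng(seed)
    totals = {v: 0.0 for v in nodes}
    for _ in range(realizations):
        keep = rng.random(len(edges)) < 0.5
        kept = [e for e, k in zip(edges, keep) if k]
        for comp in components(nodes, kept):
            for v in comp:
                totals[v] += len(comp)
    return {v: t / realizations for v, t in totals.items()}


def epc_exact(nodes, edges):
    """Exact expected component size by enumerating every edge subset."""
    nodes = list(nodes)
    edges = list(edges)
    totals = {v: 0.0 for v in nodes}
    for keep in itertools.product([False, True], repeat=len(edges)):
        kept = [e for e, k in zip(edges, keep) if k]
        for comp in components(nodes, kept):
            for v in comp:
                totals[v] += len(comp)
    scale = 2.0 ** len(edges)
    return {v: t / scale for v, t in totals.items()}


def bottleneck(nodes, edges):
    """Tree-load bottleneck with smallest-id BFS predecessors."""
    adj = adjacency(nodes, edges)
    dist = floyd_warshall(nodes, edges)
    out = {v: 0.0 for v in nodes}
    for s in nodes:
        tree = [v for v in nodes if dist[s, v] < INF]
        if len(tree) < 2:
            continue
        parent = {}
        for v in tree:
            if v == s:
                continue
            preds = [u for u in adj[v] if dist[s, u] == dist[s, v] - 1]
            parent[v] = min(preds, key=str)
        load = {v: 1 for v in tree}
        for v in sorted(tree, key=lambda u: -dist[s, u]):
            if v != s:
                load[parent[v]] += load[v]
        for v in tree:
            if v != s and load[v] > len(tree) / 4.0:
                out[v] += 1
    return out


ORACLES = {
    "MCC": mcc, "DMNC": dmnc, "MNC": mnc, "Radiality": radiality,
    "Degree": degree, "Closeness": closeness, "Betweenness": betweenness,
    "EdgeBetweenness": edge_betweenness_node,
    "ClusteringCoefficient": clustering, "Stress": stress,
    "BottleNeck": bottleneck,
}


# ---------------------------------------------------------------------------
# sequences, enrichment, Boolean dynamics
# ---------------------------------------------------------------------------

def naive_search(pattern, text):
    """1-based occurrences by the quadratic sliding check; U == T."""
    p = pattern.upper().replace("T", "U")
    t = text.upper().replace("T", "U")
    return [i + 1 for i in range(len(t) - len(p) + 1) if t[i:i + len(p)] == p]


def naive_prefix_function(pattern):
    """Longest proper border by trying every border length."""
    out = []
    for i in range(1, len(pattern) + 1):
        pre = pattern[:i]
        k = 0
        for j in range(1, i):
            if pre[:j] == pre[i - j:]:
                k = j
        out.append(k)
    return out


def running_sum_es(order_is_hit, weights, weight_p=0.0):
    """Explicit O(N) running-sum ES: returns (es, vector)."""
    n = len(order_is_hit)
    w = [abs(x) ** weight_p for x in weights]
    hit_total = sum(wi for wi, h in zip(w, order_is_hit) if h)
    n_miss = n - sum(order_is_hit)
    rs, cur = [], 0.0
    for wi, h in zip(w, order_is_hit):
        cur += (wi / hit_total) if h else (-1.0 / n_miss)
        rs.append(cur)
    es = max(rs, key=abs)
    return es, rs


def boolean_attractors(update, n):
    """Brute-force synchronous attractors over every one of the 2**n states.

    ``update`` maps a state tuple to the next state tuple.  Returns a set of
    frozensets of cycle states, plus {cycle: basin size}.
    """
    succ = {}
    for bits in itertools.product((0, 1), repeat=n):
        succ[bits] = update(bits)
    cycles = {}
    assign = {}
    for start in succ:
        path = []
        v = start
        while v not in assign and v not in path:
            path.append(v)
            v = succ[v]
        if v in assign:
            cyc = assign[v]
        else:
            cyc = frozenset(path[path.index(v):])
            cycles.setdefault(cyc, 0)
        for u in path:
            assign[u] = cyc
    for v, cyc in assign.items():
        cycles[cyc] += 1
    return cycles


def random_graph_family(n_graphs=200, max_nodes=8, seed=0):
    """Seeded family of small random graphs (node lists + edge lists),
    spanning sparse, dense and disconnected cases."""
    rng = np.random.default_rng(seed)
    graphs = []
    for k in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = rng.uniform(0.1, 0.9)
        nodes = list(range(n))
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < p]
        graphs.append((nodes, edges))
    return graphs
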