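"""Brute-force oracles, independent of the library's implementations.

Everything here is written directly from the definitions (neighbour-pair
enumeration, Floyd–Warshall, BFS component labelling) and deliberately
avoids the code paths under test.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def bf_distance_matrix(G: nx.Graph, nodes: list) -> np.ndarray:
    """Floyd–Warshall hop distances over the given node order."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in G.edges:
        if u in idx and v in idx:
            d[idx[u], idx[v]] = 1.0
            d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def connected_nodes(G: nx.Graph) -> list:
    return [v for v in G if G.degree(v) >= 1]


def bf_components(G: nx.Graph, nodes=None) -> list[set]:
    """BFS labelling from scratch; returns components as sets of nodes."""
    if nodes is None:
        nodes = list(G)
    nodes = set(nodes)
    seen: set = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            v = queue.pop()
            for w in G.adj[v]:
                if w in nodes and w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def bf_gcc_sizes(G: nx.Graph, connected_only: bool = True) -> tuple[int, int]:
    nodes = connected_nodes(G) if connected_only else list(G)
    sizes = sorted((len(c) for c in bf_components(G, nodes)), reverse=True)
    return (sizes[0] if sizes else 0, sizes[1] if len(sizes) > 1 else 0)


def bf_clustering(G: nx.Graph) -> float:
    """Average over connected nodes of (closed neighbour pairs)/(all pairs)."""
    nodes = connected_nodes(G)
    if not nodes:
        return float("nan")
    total = 0.0
    for v in nodes:
        nbrs = list(G.adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if G.has_edge(a, b)
        )
        total += closed / (k * (k - 1) / 2)
    return total / len(nodes)


def bf_path_length_gcc(G: nx.Graph) -> float:
    comps = bf_components(G, connected_nodes(G))
    gcc = sorted(max(comps, key=len), key=str)
    d = bf_distance_matrix(G, gcc)
    vals = [d[i, j] for i in range(len(gcc)) for j in range(i + 1, len(gcc))]
    return float(np.mean(vals))


def bf_global_efficiency(G: nx.Graph) -> float:
    nodes = connected_nodes(G)
    if len(nodes) < 2:
        return float("nan")
    d = bf_distance_matrix(G, nodes)
    vals = [
        (1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0)
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
    ]
    return float(np.mean(vals))


def bf_local_efficiency(G: nx.Graph) -> float:
    nodes = connected_nodes(G)
    if not nodes:
        return float("nan")
    total = 0.0
    for v in nodes:
        nbrs = list(G.adj[v])
        if len(nbrs) < 2:
            continue
        sub = G.subgraph(nbrs)
        d = bf_distance_matrix(sub, nbrs)
        vals = [
            (1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0)
            for i in range(len(nbrs))
            for j in range(i + 1, len(nbrs))
        ]
        total += float(np.mean(vals))
    return total / len(nodes)


def bf_reduce_c_pairs(G: nx.Graph) -> set[frozenset]:
    """C-pairs joined directly or via B-only internal paths (per-pair BFS)."""
    c_nodes = [v for v in G if G.nodes[v]["cls"] == "C"]
    pairs: set[frozenset] = set()
    for s, t in itertools.combinations(c_nodes, 2):
        # BFS from s allowed to traverse only B internal nodes
        queue = [s]
        seen = {s}
        found = False
        while queue and not found:
            v = queue.pop()
            for w in G.adj[v]:
                if w == t:
                    found = True
                    break
                if w not in seen and G.nodes[w]["cls"] == "B":
                    seen.add(w)
                    queue.append(w)
        if found:
            pairs.add(frozenset((s, t)))
    return pairs
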