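"""Two-class spatial graphs for clustered neuronal cultures.

A culture at a given age is represented as an undirected spatial graph
with two node classes:

``C``
    neurons or clusters of neurons (cluster centroids) — the objects the
    topological statistics are ultimately computed on;
``B``
    neurite branch / connection points, i.e. places where neurite paths
    meet without a soma being present.

Links are unweighted and undirected (edge length and directionality are
ignored), so the graph is fully described by a symmetric adjacency matrix
with an empty diagonal. Node positions are 2-D coordinates in micrometres
with the origin at the substrate centre. Edges may optionally carry a
scalar ``tension`` attribute (mechanical force accumulated along the
neurite bundle), used by the growth model.

The module provides construction/validation, the reduction of the
two-class graph to its C-node subgraph (C-nodes become adjacent when they
are joined directly or through a path of B-nodes only), connected
component bookkeeping, and GraphML / edge-list file I/O.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

#: node class tags
CLUSTER = "C"
BRANCH = "B"
NODE_CLASSES = (CLUSTER, BRANCH)


class GraphInputError(ValueError):
    """Raised when node/edge input violates the culture-graph contract."""


class CultureGraph:
    """Undirected spatial culture graph.

    Thin wrapper around :class:`networkx.Graph` enforcing the culture
    conventions: every node has a ``cls`` attribute in ``{"C", "B"}`` and
    float ``x``/``y`` positions (µm); edges are simple (no self-loops,
    no parallels) and may carry a ``tension`` attribute.

    Instances are normally built through :func:`build_graph`, the growth
    simulator, or the file readers.
    """

    def __init__(self, g: nx.Graph | None = None):
        self.nx: nx.Graph = g if g is not None else nx.Graph()

    # -- basic accessors -------------------------------------------------
    def nodes(self) -> list:
        return list(self.nx.nodes)

    def edges(self) -> list[tuple]:
        return list(self.nx.edges)

    @property
    def n_nodes(self) -> int:
        return self.nx.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.nx.number_of_edges()

    def node_class(self, n) -> str:
        return self.nx.nodes[n]["cls"]

    def position(self, n) -> tuple[float, float]:
        d = self.nx.nodes[n]
        return (d["x"], d["y"])

    def tension(self, u, v) -> float | None:
        return self.nx.edges[u, v].get("tension")

    def copy(self) -> "CultureGraph":
        return CultureGraph(self.nx.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CultureGraph):
            return NotImplemented
        return nx.utils.graphs_equal(self.nx, other.nx)

    def __repr__(self) -> str:
        nc = sum(1 for n in self.nx if self.nx.nodes[n]["cls"] == CLUSTER)
        return (
            f"CultureGraph(C={nc}, B={self.n_nodes - nc}, "
            f"edges={self.n_edges})"
        )


def as_nx(g) -> nx.Graph:
    """Accept either a CultureGraph or a bare networkx graph."""
    return g.nx if isinstance(g, CultureGraph) else g


def build_graph(
    nodes: Iterable[tuple],
    edges: Iterable[tuple] = (),
) -> CultureGraph:
    """Build a validated culture graph.

    Parameters
    ----------
    nodes
        iterable of ``(id, cls, (x, y))`` triples; ids must be unique and
        ``cls`` one of ``"C"``/``"B"``.
    edges
        iterable of id pairs, optionally ``(u, v, tension)``. Duplicate
        pairs (in either orientation) collapse to a single undirected
        edge; self-pairs and unknown endpoints are input errors.
    """
    g = nx.Graph()
    for entry in nodes:
        nid, cls, pos = entry
        if nid in g:
            raise GraphInputError(f"duplicate node id {nid!r}")
        if cls not in NODE_CLASSES:
            raise GraphInputError(f"node {nid!r}: unknown class {cls!r}")
        x, y = pos
        g.add_node(nid, cls=cls, x=float(x), y=float(y))
    for entry in edges:
        if len(entry) == 3:
            u, v, tension = entry
        else:
            u, v = entry
            tension = None
        if u == v:
            raise GraphInputError(f"self-loop pair ({u!r}, {v!r})")
        for endpoint in (u, v):
            if endpoint not in g:
                raise GraphInputError(f"unknown endpoint {endpoint!r}")
        if tension is None:
            g.add_edge(u, v)
        else:
            g.add_edge(u, v, tension=float(tension))
    return CultureGraph(g)


def reduce_to_cluster_graph(g: CultureGraph | nx.Graph) -> CultureGraph:
    """Project the two-class graph onto its C-nodes.

    Two C-nodes are adjacent in the reduced graph iff they share a direct
    edge in ``g`` or are joined by a path whose internal nodes are all of
    class B. Positions are preserved; B-only chains with no terminal
    C-node carry no information and are dropped. The operation is
    idempotent and never links C-nodes from different components of ``g``.
    """
    G = as_nx(g)
    c_nodes = [n for n in G if G.nodes[n]["cls"] == CLUSTER]
    out = nx.Graph()
    for n in c_nodes:
        out.add_node(n, cls=CLUSTER, x=G.nodes[n]["x"], y=G.nodes[n]["y"])
    # direct C-C edges
    for u, v in G.edges:
        if G.nodes[u]["cls"] == CLUSTER and G.nodes[v]["cls"] == CLUSTER:
            out.add_edge(u, v)
    # each connected component of the B-induced subgraph acts as one
    # junction: all C-nodes touching it become pairwise adjacent
    b_sub = G.subgraph(n for n in G if G.nodes[n]["cls"] == BRANCH)
    for comp in nx.connected_components(b_sub):
        attached = set()
        for b in comp:
            for nb in G.adj[b]:
                if G.nodes[nb]["cls"] == CLUSTER:
                    attached.add(nb)
        attached = sorted(attached, key=str)
        for i, u in enumerate(attached):
            for v in attached[i + 1:]:
                out.add_edge(u, v)
    return CultureGraph(out)


def gcc_sizes(
    g: CultureGraph | nx.Graph, connected_only: bool = True
) -> tuple[int, int]:
    """Sizes (node counts) of the largest and second-largest components.

    With ``connected_only`` (default) isolated nodes are excluded before
    counting, matching the convention of restricting statistics to nodes
    having at least one link; set it to False to count isolated nodes as
    size-1 components. Returns ``(0, 0)`` on an empty graph and a second
    value of 0 when fewer than two components remain.
    """
    G = as_nx(g)
    if connected_only:
        G = G.subgraph(n for n in G if G.degree(n) >= 1)
    sizes = sorted((len(c) for c in nx.connected_components(G)), reverse=True)
    s1 = sizes[0] if sizes else 0
    s2 = sizes[1] if len(sizes) > 1 else 0
    return (s1, s2)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_graphml(g: CultureGraph | nx.Graph, path: str | Path) -> None:
    """Write the graph as GraphML (node attrs cls/x/y, edge attr tension)."""
    nx.write_graphml(as_nx(g), str(path))


def read_graphml(path: str | Path) -> CultureGraph:
    """Read a GraphML culture graph and validate its node classes."""
    G = nx.read_graphml(str(path))
    out = nx.Graph()
    for n, d in G.nodes(data=True):
        nid = _coerce_id(n)
        if d.get("cls") not in NODE_CLASSES:
            raise GraphInputError(f"node {n!r}: missing/unknown class")
        out.add_node(nid, cls=d["cls"], x=float(d["x"]), y=float(d["y"]))
    for u, v, d in G.edges(data=True):
        attrs = {}
        if "tension" in d:
            attrs["tension"] = float(d["tension"])
        out.add_edge(_coerce_id(u), _coerce_id(v), **attrs)
    return CultureGraph(out)


def _coerce_id(n):
    """GraphML stores ids as strings; restore integer ids when possible."""
    if isinstance(n, str):
        try:
            return int(n)
        except ValueError:
            return n
    return n


def write_edgelist(
    g: CultureGraph | nx.Graph, edge_path: str | Path, node_path: str | Path
) -> None:
    """Write plain-text edge list plus a CSV node table (id,cls,x,y)."""
    G = as_nx(g)
    with open(edge_path, "w") as fh:
        for u, v in G.edges:
            fh.write(f"{u} {v}\n")
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "cls", "x", "y"])
        for n, d in G.nodes(data=True):
            w.writerow([n, d["cls"], repr(d["x"]), repr(d["y"])])


def read_edgelist(
    edge_path: str | Path, node_path: str | Path
) -> CultureGraph:
    """Read the edge-list + node-table pair written by :func:`write_edgelist`."""
    nodes: list[tuple] = []
    with open(node_path, newline="") as fh:
        for row in csv.DictReader(fh):
            nodes.append(
                (_coerce_id(row["id"]), row["cls"],
                 (float(row["x"]), float(row["y"])))
            )
    edges: list[tuple] = []
    with open(edge_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise GraphInputError(f"malformed edge line: {line!r}")
            edges.append((_coerce_id(parts[0]), _coerce_id(parts[1])))
    return build_graph(nodes, edges)
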