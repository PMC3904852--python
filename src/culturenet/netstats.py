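"""Topological observables of culture graphs at a single developmental stage.

All statistics follow the conventions used for anatomical culture
networks: they are computed on the set of nodes having at least one link,
the average shortest path length is restricted to pairs inside the giant
connected component (GCC), and the global/local efficiencies
(Latora–Marchiori) are averaged over *all* pairs, with 1/∞ = 0 for
disconnected ones — efficiency is used precisely because it tolerates
disconnectedness.

Degree-law and degree-mixing fits:

* the cumulative degree distribution P_c(k) = Σ_{k'>=k} P(k') is fitted to
  a single-scale exponential law P_c(k) ∝ exp(−k/k*) by least squares on
  ln P_c(k) vs k; for homogeneous (single-scale) networks the recovered
  scale k* is close to the mean degree ⟨k⟩;
* degree-degree correlations are quantified per node via the average
  neighbour degree k_nn and the power-law fit k_nn ∝ k^α; α is the mixing
  exponent (linear/sub-linear/super-linear) and r the Pearson coefficient
  of the log-log fit (r > 0: assortative, r < 0: disassortative).

Shortest-path based quantities are computed with scipy's sparse-graph BFS
for speed; correctness is pinned to brute-force oracles in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.stats import linregress

from .spatial_graph import as_nx, gcc_sizes

# NullEnsembleSummary (null_models) is consumed duck-typed here to keep the
# stats layer import-independent of the null-model layer.

logger = logging.getLogger(__name__)

NA = float("nan")


class EdgelessGraphError(ValueError):
    """Raised when a statistic is undefined on a graph without edges."""


class DegenerateFitError(ValueError):
    """Raised when a regression has no variance to fit (e.g. regular graph)."""


@dataclass
class StatsRecord:
    """All topological observables of one graph at one developmental stage.

    Degenerate quantities (fits on regular graphs, path length of an
    edgeless graph, ...) are stored as NaN markers rather than failing the
    record. The three small-world ratio fields are filled only when a
    null-model summary is supplied.
    """

    n_connected: int = 0          # nodes with >= 1 link
    n_edges: int = 0
    link_density: float = NA
    gcc_size: int = 0             # S1
    gcc2_size: int = 0            # S2
    mean_degree: float = NA
    clustering: float = NA        # C (Watts-Strogatz average)
    path_length: float = NA       # L over GCC pairs
    global_efficiency: float = NA
    local_efficiency: float = NA
    ccdf_scale: float = NA        # k* of the exponential CCDF fit
    ccdf_r2: float = NA
    assortativity_exponent: float = NA   # alpha of k_nn ~ k^alpha
    assortativity_r: float = NA          # Pearson r of the log-log fit
    c_over_crand: float = NA
    l_over_lrand: float = NA
    l_over_llattice: float = NA

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


#: numeric StatsRecord columns, in file order
STAT_FIELDS = [f.name for f in dc_fields(StatsRecord)]


def _connected_subgraph(g) -> nx.Graph:
    G = as_nx(g)
    return G.subgraph(n for n in G if G.degree(n) >= 1)


def link_density(g) -> float:
    """2E / (N(N−1)) with N the number of nodes having ≥ 1 link; 0 if N < 2."""
    G = _connected_subgraph(g)
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def mean_degree(g) -> float:
    """Average degree over nodes having ≥ 1 link (NaN on edgeless graphs)."""
    G = _connected_subgraph(g)
    n = G.number_of_nodes()
    if n == 0:
        return NA
    return 2.0 * G.number_of_edges() / n


def clustering_coefficient(g) -> float:
    """Watts–Strogatz average clustering over nodes with ≥ 1 link.

    Nodes of degree < 2 contribute zero. NaN on edgeless graphs.
    """
    G = _connected_subgraph(g)
    if G.number_of_nodes() == 0:
        return NA
    vals = nx.clustering(G)
    return float(sum(vals.values()) / len(vals))


def _distance_matrix(G: nx.Graph) -> np.ndarray:
    """All-pairs hop distances (np.inf for disconnected pairs)."""
    adj = nx.to_scipy_sparse_array(G, format="csr", dtype=float)
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def path_length_gcc(g) -> float:
    """Mean shortest-path length over unordered pairs inside the GCC."""
    G = _connected_subgraph(g)
    if G.number_of_edges() == 0:
        raise EdgelessGraphError("path length undefined on an edgeless graph")
    gcc = max(nx.connected_components(G), key=len)
    sub = G.subgraph(gcc)
    d = _distance_matrix(sub)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def global_efficiency(g) -> float:
    """Mean of 1/d(i,j) over all unordered pairs of connected nodes.

    Disconnected pairs contribute 0 (1/∞); NaN when fewer than two nodes
    carry a link.
    """
    G = _connected_subgraph(g)
    n = G.number_of_nodes()
    if n < 2:
        return NA
    d = _distance_matrix(G)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g) -> float:
    """Mean over nodes of the global efficiency of the neighbour subgraph.

    The node itself is excluded from its neighbour subgraph; nodes of
    degree ≤ 1 contribute 0. Averaged over nodes with ≥ 1 link.
    """
    G = _connected_subgraph(g)
    if G.number_of_nodes() == 0:
        return NA
    total = 0.0
    for n in G:
        nbrs = list(G.adj[n])
        if len(nbrs) < 2:
            continue
        sub = G.subgraph(nbrs)
        d = _distance_matrix(sub)
        m = d.shape[0]
        iu = np.triu_indices(m, k=1)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d[iu]
        inv[~np.isfinite(inv)] = 0.0
        total += float(inv.mean())
    return total / G.number_of_nodes()


# ---------------------------------------------------------------------------
# degree-distribution and degree-mixing fits
# ---------------------------------------------------------------------------

def fit_ccdf_points(k: Sequence[float], pc: Sequence[float]) -> tuple[float, float]:
    """Least-squares line fit of ln P_c(k) vs k; returns (k*, R²).

    k* = −1/slope of the fitted line; the degree scale of the exponential
    law P_c(k) ∝ exp(−k/k*).
    """
    k = np.asarray(k, dtype=float)
    pc = np.asarray(pc, dtype=float)
    keep = pc > 0
    k, pc = k[keep], pc[keep]
    if len(np.unique(k)) < 3:
        raise DegenerateFitError("need >= 3 distinct degrees for a CCDF fit")
    res = linregress(k, np.log(pc))
    if res.slope == 0:
        return (math.inf, res.rvalue**2)
    return (-1.0 / res.slope, res.rvalue**2)


def fit_exponential_ccdf(g) -> tuple[float, float]:
    """Fit the cumulative degree distribution to an exponential law.

    P_c(k) = fraction of connected nodes with degree ≥ k, evaluated at the
    distinct observed degrees; returns ``(k*, R²)``. Raises
    :class:`DegenerateFitError` when fewer than three distinct positive
    degrees exist (e.g. on regular graphs).
    """
    G = _connected_subgraph(g)
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    if degrees.size == 0:
        raise DegenerateFitError("edgeless graph has no degree distribution")
    ks = np.unique(degrees)
    pc = np.array([(degrees >= k).mean() for k in ks])
    return fit_ccdf_points(ks, pc)


def fit_geometric_mle(g) -> float:
    """Maximum-likelihood geometric cross-check of the degree scale.

    Models degrees (on nodes with ≥ 1 link) as geometric on {1, 2, ...};
    returns the implied exponential scale −1/ln(1−p̂) with p̂ = 1/⟨k⟩.
    Used only as an independent sanity check of the log-LS CCDF fit.
    """
    G = _connected_subgraph(g)
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    if degrees.size == 0 or degrees.mean() <= 1:
        raise DegenerateFitError("geometric MLE needs mean degree > 1")
    p = 1.0 / degrees.mean()
    return -1.0 / math.log(1.0 - p)


def average_neighbor_degrees(g) -> dict:
    """k_nn per node with degree ≥ 1: mean degree of its neighbours."""
    G = _connected_subgraph(g)
    return {
        n: float(np.mean([G.degree(m) for m in G.adj[n]])) for n in G
    }


def assortativity_fit(g, binned: bool = False) -> tuple[float, float]:
    """Fit k_nn ∝ k^α over per-node points; return (α, Pearson r).

    The regression runs on (ln k, ln k_nn); r is the Pearson correlation
    of those log points, so r > 0 marks an assortative network. With
    ``binned=True`` the per-node points are first averaged per distinct
    degree (degree-binned variant). Raises :class:`DegenerateFitError`
    when all degrees are equal (zero variance, undefined r).
    """
    G = _connected_subgraph(g)
    knn = average_neighbor_degrees(G)
    if len(knn) < 3:
        raise DegenerateFitError("need >= 3 connected nodes")
    k = np.array([G.degree(n) for n in knn], dtype=float)
    y = np.array([knn[n] for n in knn], dtype=float)
    if binned:
        ks = np.unique(k)
        y = np.array([y[k == kk].mean() for kk in ks])
        k = ks
    if len(np.unique(k)) < 2:
        raise DegenerateFitError("all degrees equal; assortativity undefined")
    res = linregress(np.log(k), np.log(y))
    return (float(res.slope), float(res.rvalue))


def correlation_regime(alpha: float, tol: float = 0.1) -> str:
    """Classify the mixing exponent: linear / sub-linear / super-linear."""
    if abs(alpha - 1.0) <= tol:
        return "linear"
    return "sub-linear" if alpha < 1.0 else "super-linear"


# ---------------------------------------------------------------------------
# small-world normalization
# ---------------------------------------------------------------------------

def smallworld_ratios(g, null_summary) -> tuple[float, float, float]:
    """Normalize C and L by a degree-matched null ensemble and a lattice.

    Returns ``(C/C_rand, L/L_rand, L/L_lattice)`` where C_rand and L_rand
    are the null-ensemble means and L_lattice = S1/(2⟨k⟩) is the regular
    lattice reference (S1 the GCC size, ⟨k⟩ the mean degree). A
    small-world stage shows C/C_rand ≫ 1 with L/L_rand ≈ 1 and
    L/L_lattice ≪ 1.
    """
    c = clustering_coefficient(g)
    length = path_length_gcc(g)
    if null_summary.clustering_mean == 0:
        logger.warning("null ensemble clustering is 0; C/C_rand reported as inf")
        c_ratio = math.inf
    else:
        c_ratio = c / null_summary.clustering_mean
    l_ratio = length / null_summary.path_length_mean
    s1, _ = gcc_sizes(g)
    kbar = mean_degree(g)
    l_lattice = s1 / (2.0 * kbar)
    return (c_ratio, l_ratio, length / l_lattice)


def compute_stats(g, null_summary=None) -> StatsRecord:
    """Fill a complete StatsRecord for one graph.

    Degenerate fits and undefined quantities become NaN markers instead of
    failing the record; the small-world ratio fields are filled only when
    ``null_summary`` is given.
    """
    G = _connected_subgraph(g)
    rec = StatsRecord(
        n_connected=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        link_density=link_density(g),
    )
    rec.gcc_size, rec.gcc2_size = gcc_sizes(g)
    if rec.n_connected == 0:
        return rec
    rec.mean_degree = mean_degree(g)
    rec.clustering = clustering_coefficient(g)
    rec.global_efficiency = global_efficiency(g)
    rec.local_efficiency = local_efficiency(g)
    try:
        rec.path_length = path_length_gcc(g)
    except EdgelessGraphError:
        pass
    try:
        rec.ccdf_scale, rec.ccdf_r2 = fit_exponential_ccdf(g)
    except DegenerateFitError:
        pass
    try:
        rec.assortativity_exponent, rec.assortativity_r = assortativity_fit(g)
    except DegenerateFitError:
        pass
    if null_summary is not None and not math.isnan(rec.path_length):
        rec.c_over_crand, rec.l_over_lrand, rec.l_over_llattice = (
            smallworld_ratios(g, null_summary)
        )
    return rec
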