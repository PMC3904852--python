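"""Degree-preserving null ensembles for small-world normalization.

Observed clustering and path length only become interpretable against
randomized networks with the same number of nodes and links and the same
degree distribution. We build these by double-edge swaps: pick two edges
(a,b) and (c,d), replace them by (a,d) and (c,b), rejecting any swap that
would create a self-loop or a duplicate edge. Swaps preserve every node's
degree exactly; connectedness is *not* enforced, because path length is in
any case computed on the giant component of each realization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .spatial_graph import as_nx

logger = logging.getLogger(__name__)

#: graph-attribute keys recording rewiring diagnostics
ACCEPTED_KEY = "rewire_accepted"
INCOMPLETE_KEY = "rewire_incomplete"

#: attempts allowed per requested swap before giving up (rigid graphs such
#: as a triangle admit no legal swap at all)
ATTEMPT_FACTOR = 100


@dataclass
class NullEnsembleSummary:
    """Mean/sd of the key observables across rewired realizations."""

    n_real: int
    clustering_mean: float
    clustering_std: float
    path_length_mean: float
    path_length_std: float
    global_efficiency_mean: float
    global_efficiency_std: float
    local_efficiency_mean: float
    local_efficiency_std: float
    rewire_warnings: int = 0


def degree_preserving_rewire(
    g,
    n_swaps: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Randomize a simple graph by accepted double-edge swaps.

    ``n_swaps`` counts *accepted* swaps (default 10×E); attempts are capped
    at 100×n_swaps so rigid graphs (e.g. a triangle, where every swap would
    duplicate an edge) terminate and come back unchanged, with the
    shortfall recorded in the graph attribute ``rewire_incomplete``. Node
    attributes are preserved; edge attributes are dropped (links are
    treated as identical).
    """
    G = as_nx(g)
    if G.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = nx.Graph()
    out.add_nodes_from(G.nodes(data=True))
    out.add_edges_from(G.edges())
    edges = list(out.edges())
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    accepted = 0
    attempts = 0
    max_attempts = ATTEMPT_FACTOR * n_swaps
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # random orientation of the second edge
        if rng.random() < 0.5:
            c, d = d, c
        if a == d or c == b:
            continue  # would create a self-loop
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue  # would create a duplicate edge
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    out.graph[ACCEPTED_KEY] = accepted
    out.graph[INCOMPLETE_KEY] = n_swaps - accepted
    if accepted < n_swaps:
        logger.warning(
            "rewiring stopped after %d/%d accepted swaps (%d attempts)",
            accepted, n_swaps, attempts,
        )
    return out


def null_ensemble_stats(
    g,
    n_real: int = 20,
    seed: int | None = None,
    n_swaps: int | None = None,
    include_efficiency: bool = True,
) -> NullEnsembleSummary:
    """Summarize clustering, GCC path length and efficiencies over a
    degree-matched rewired ensemble.

    Realizations use sub-seeds derived deterministically from ``seed``, so
    the summary is reproducible. Path length is computed on the giant
    component of each realization (realizations may disconnect). With
    ``include_efficiency=False`` the (comparatively expensive) efficiency
    summaries are skipped and reported as NaN — sufficient when only the
    C and L normalizations are needed.
    """
    from . import netstats  # local import: stats layer sits above this one

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_real)
    cs, ls, eg, el = [], [], [], []
    warn = 0
    for child in children:
        r = degree_preserving_rewire(
            g, n_swaps=n_swaps, rng=np.random.default_rng(child)
        )
        warn += int(r.graph.get(INCOMPLETE_KEY, 0) > 0)
        cs.append(netstats.clustering_coefficient(r))
        ls.append(netstats.path_length_gcc(r))
        if include_efficiency:
            eg.append(netstats.global_efficiency(r))
            el.append(netstats.local_efficiency(r))
    if not include_efficiency:
        eg = el = [float("nan")]

    def ms(x):
        a = np.asarray(x, dtype=float)
        return float(a.mean()), float(a.std(ddof=0))

    cm, csd = ms(cs)
    lm, lsd = ms(ls)
    gm, gsd = ms(eg)
    em, esd = ms(el)
    return NullEnsembleSummary(
        n_real=n_real,
        clustering_mean=cm, clustering_std=csd,
        path_length_mean=lm, path_length_std=lsd,
        global_efficiency_mean=gm, global_efficiency_std=gsd,
        local_efficiency_mean=em, local_efficiency_std=esd,
        rewire_warnings=warn,
    )
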