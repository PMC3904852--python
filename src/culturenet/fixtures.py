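"""Deterministic toy graphs and synthetic time series for tests and demos.

Every generator is a pure function of its parameters and seed, so fixture
data never needs to be shipped: tests and documentation examples rebuild
identical inputs on the fly. The ``geometric_random`` family is a static
stand-in for spatial culture graphs (points in a disk, links within a
radius); ``c_b_chain`` exercises the two-class reduction logic.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .netstats import NA, StatsRecord
from .spatial_graph import BRANCH, CLUSTER, CultureGraph, GraphInputError, build_graph

TOY_NAMES = (
    "triangle", "path", "star", "ring_lattice", "complete",
    "er_random", "geometric_random", "c_b_chain",
)


def _circle_positions(n: int, radius: float = 100.0) -> list[tuple[float, float]]:
    return [
        (radius * math.cos(2 * math.pi * i / n),
         radius * math.sin(2 * math.pi * i / n))
        for i in range(n)
    ]


def toy_graph(name: str, seed: int = 0, **params) -> CultureGraph:
    """Build a named deterministic toy culture graph.

    Supported names and their parameters:

    - ``triangle``: 3 C-nodes, 3 edges.
    - ``path`` (``n=4``): a simple chain of C-nodes.
    - ``star`` (``n=5``): hub C-node 0 with ``n`` leaves.
    - ``ring_lattice`` (``n=100``, ``k=4``): each node linked to its k
      nearest ring neighbours (k even).
    - ``complete`` (``n=5``).
    - ``er_random`` (``n=30``, ``p=0.2``): Erdős–Rényi, seeded.
    - ``geometric_random`` (``n=100``, ``radius=25.0``, ``disk=100.0``):
      nodes area-uniform in a disk, linked within ``radius``.
    - ``c_b_chain`` (``m=3``): m C-nodes around one central B-node, plus
      an isolated B–B chain; reducing to the C-subgraph yields the
      complete graph K_m (and drops the dangling B chain).
    """
    if name == "triangle":
        pos = _circle_positions(3)
        nodes = [(i, CLUSTER, pos[i]) for i in range(3)]
        return build_graph(nodes, [(0, 1), (1, 2), (2, 0)])

    if name == "path":
        n = params.get("n", 4)
        nodes = [(i, CLUSTER, (10.0 * i, 0.0)) for i in range(n)]
        return build_graph(nodes, [(i, i + 1) for i in range(n - 1)])

    if name == "star":
        n = params.get("n", 5)
        pos = _circle_positions(n)
        nodes = [(0, CLUSTER, (0.0, 0.0))] + [
            (i + 1, CLUSTER, pos[i]) for i in range(n)
        ]
        return build_graph(nodes, [(0, i + 1) for i in range(n)])

    if name == "ring_lattice":
        n = params.get("n", 100)
        k = params.get("k", 4)
        if k % 2 or k >= n:
            raise GraphInputError("ring_lattice needs even k < n")
        pos = _circle_positions(n)
        nodes = [(i, CLUSTER, pos[i]) for i in range(n)]
        edges = [
            (i, (i + d) % n) for i in range(n) for d in range(1, k // 2 + 1)
        ]
        return build_graph(nodes, edges)

    if name == "complete":
        n = params.get("n", 5)
        pos = _circle_positions(n)
        nodes = [(i, CLUSTER, pos[i]) for i in range(n)]
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        return build_graph(nodes, edges)

    if name == "er_random":
        n = params.get("n", 30)
        p = params.get("p", 0.2)
        rng = np.random.default_rng(seed)
        pos = _circle_positions(n)
        nodes = [(i, CLUSTER, pos[i]) for i in range(n)]
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        return build_graph(nodes, edges)

    if name == "geometric_random":
        n = params.get("n", 100)
        radius = params.get("radius", 25.0)
        disk = params.get("disk", 100.0)
        rng = np.random.default_rng(seed)
        r = disk * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
        nodes = [(i, CLUSTER, (xy[i, 0], xy[i, 1])) for i in range(n)]
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if d[i, j] <= radius
        ]
        return build_graph(nodes, edges)

    if name == "c_b_chain":
        m = params.get("m", 3)
        pos = _circle_positions(m)
        nodes = [(i, CLUSTER, pos[i]) for i in range(m)]
        nodes.append((m, BRANCH, (0.0, 0.0)))           # central junction
        nodes.append((m + 1, BRANCH, (300.0, 0.0)))     # dangling B chain
        nodes.append((m + 2, BRANCH, (310.0, 0.0)))
        edges = [(i, m) for i in range(m)] + [(m + 1, m + 2)]
        return build_graph(nodes, edges)

    raise GraphInputError(
        f"unknown fixture {name!r}; choose from {TOY_NAMES}"
    )


TS_SHAPES = ("rise_peak_decline", "monotone", "flat")


def synthetic_timeseries(
    shape: str,
    seed: int = 0,
    n_steps: int = 10,
    n_runs: int = 4,
    peak_step: int = 4,
    noise: float = 0.05,
) -> list[list[StatsRecord]]:
    """Synthesize per-run StatsRecord sequences with a named trend.

    ``rise_peak_decline`` ramps the edge count up to ``peak_step`` and back
    down (the GCC2 follows a rise-then-collapse analogue); ``monotone``
    increases linearly; ``flat`` stays constant. Multiplicative Gaussian
    noise of relative size ``noise`` is added per run (seeded); fit fields
    are left as NaN markers.
    """
    if shape not in TS_SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {TS_SHAPES}")
    rng = np.random.default_rng(seed)
    runs: list[list[StatsRecord]] = []
    steps = np.arange(n_steps, dtype=float)
    if shape == "rise_peak_decline":
        trend = 10.0 + 90.0 * np.minimum(
            steps / max(peak_step, 1),
            np.maximum(0.0, 1 - (steps - peak_step) / max(n_steps - peak_step, 1)),
        )
        g2 = 1.0 + 9.0 * np.minimum(
            steps / max(peak_step, 1),
            np.maximum(0.0, 1 - (steps - peak_step) / 2.0),
        )
    elif shape == "monotone":
        trend = 10.0 + 10.0 * steps
        g2 = 1.0 + steps
    else:  # flat
        trend = np.full(n_steps, 50.0)
        g2 = np.full(n_steps, 5.0)

    for _ in range(n_runs):
        eps = 1.0 + noise * rng.standard_normal(n_steps)
        eps2 = 1.0 + noise * rng.standard_normal(n_steps)
        run = []
        for s in range(n_steps):
            e = max(0.0, trend[s] * eps[s])
            n_conn = max(2.0, 2.0 * math.sqrt(e) + 5)
            run.append(
                StatsRecord(
                    n_connected=int(round(n_conn)),
                    n_edges=int(round(e)),
                    link_density=min(
                        1.0, 2 * e / (n_conn * max(n_conn - 1, 1))
                    ),
                    gcc_size=int(round(n_conn * 0.8)),
                    gcc2_size=int(round(max(0.0, g2[s] * eps2[s]))),
                    mean_degree=2 * e / n_conn,
                    clustering=min(1.0, 0.3 * eps[s] if e else 0.0),
                    path_length=NA,
                    global_efficiency=NA,
                    local_efficiency=NA,
                )
            )
        runs.append(run)
    return runs
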