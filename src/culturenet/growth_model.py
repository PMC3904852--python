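"""Agent-based spatial growth model of clustered neuronal cultures.

The model evolves N cells seeded at random on a circular 2-D substrate
through discrete time steps, one step per day in vitro (DIV). Three
coupled mechanisms drive the morphology:

**Neurite outgrowth and wiring.** Each cell *i* carries a growing disk of
radius ``R_i(t)`` abstracting the territory reached by its neurites
(initially the soma radius ρ). Per step the radius increases by

    Δr_i(t) = v · η_i(t) · max(0, 1 − k_i(t)/k_i⁰)

where ``v`` is the neurite growth velocity (common to all cells),
``η_i(t)`` a fresh uniform random number in [0, 1], ``k_i(t)`` the current
degree of the cell's unit and ``k_i⁰`` a randomly assigned integer
endowment: the growth rate decays with the fraction of connections already
acquired, and stalls once the endowment is saturated. Two units become
linked the first time their outer rings intersect (centroid distance ≤
sum of disk radii). Wiring and growth stop after step ``T_s``.

**Tension.** A new link starts at tension ``F0`` and is incremented by
``ΔF`` force units per subsequent step, pulling its endpoints together
along the line joining their centroids.

**Migration, clustering and merging.** Every cell adheres to the
substrate with force ``F_a`` (a cluster with the sum of its members'
adhesions; adhesion is cancelled outside the substrate disk). Whenever
the vector sum of tensions on a unit exceeds its adhesion, the unit is
displaced step-wise along the net force until an equilibrium position is
reached. Units closing within ``d_merge`` of each other merge into a
single cluster: internal links disappear and parallel links to a common
neighbour bundle into one link carrying the summed tension.

There is no neurite branching or retraction mechanism, and no electrical
activity; the model is purely morphological.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .spatial_graph import CLUSTER, CultureGraph, build_graph

logger = logging.getLogger(__name__)


class SimulationConfig(BaseModel):
    """All parameters of the spatial growth model.

    Lengths are in µm, forces in arbitrary force units, times in steps
    (1 step = 1 DIV). Defaults are the package's fitted example
    configuration, calibrated to reproduce the qualitative developmental
    scenario of dense locust-ganglion cultures (link peak at the wiring
    stop, percolation, small-world emergence) at n_cells = 300.
    """

    n_cells: int = Field(default=300, ge=1)
    substrate_radius: float = Field(default=450.0, gt=0)
    cell_radius: float = Field(default=7.5, gt=0)
    growth_velocity: float = Field(default=30.0, ge=0)
    wiring_stop: int = Field(default=6, ge=0)
    total_steps: int = Field(default=18, ge=1)
    initial_tension: float = Field(default=1.0, ge=0)
    tension_increment: float = Field(default=1.0, ge=0)
    adhesion_per_cell: float = Field(default=14.0, gt=0)
    merge_distance: float = Field(default=15.0, gt=0)
    k0_min: int = Field(default=1, ge=1)
    k0_max: int = Field(default=50, ge=1)
    k0_mean: float | None = Field(default=8.0, gt=1)
    relax_step: float = Field(default=3.75, gt=0)
    relax_max_iter: int = Field(default=1000, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimulationConfig":
        if self.wiring_stop > self.total_steps:
            raise ValueError("wiring_stop must be <= total_steps")
        if self.k0_max < self.k0_min:
            raise ValueError("k0_max must be >= k0_min")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.model_validate_json(Path(path).read_text())


@dataclass
class Unit:
    """A cell or cluster of cells moving as one rigid object."""

    members: list[int]          # cell ids
    pos: np.ndarray             # centroid, shape (2,)

    @property
    def n_cells(self) -> int:
        return len(self.members)


@dataclass
class EdgeState:
    tension: float
    birth: int


@dataclass
class SimulationState:
    """Mutable simulator state: units, per-cell arrays, tensioned edges."""

    units: dict[int, Unit]
    radii: np.ndarray           # per-cell neurite disk radius R_i(t)
    endowments: np.ndarray      # per-cell k_i0 (integers)
    edges: dict[tuple[int, int], EdgeState]  # key: sorted unit-id pair
    t: int
    rng: np.random.Generator
    unrelaxed: bool = False
    zero_distance_warnings: int = 0

    # -- helpers ----------------------------------------------------------
    def unit_radius(self, uid: int) -> float:
        """Disk radius of a unit = largest member disk radius."""
        return float(self.radii[self.units[uid].members].max())

    def unit_degrees(self) -> dict[int, int]:
        deg = {uid: 0 for uid in self.units}
        for (u, v) in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def total_cells(self) -> int:
        return sum(u.n_cells for u in self.units.values())


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def init_culture(cfg: SimulationConfig) -> SimulationState:
    """Seed the culture: area-uniform positions on the substrate disk.

    Each cell starts as a singleton unit with disk radius ρ and a random
    integer endowment k_i⁰: geometric with mean ``k0_mean`` clipped to
    [k0_min, k0_max] (the default, yielding the broad single-scale degree
    mix of real cultures), or uniform on [k0_min, k0_max] when ``k0_mean``
    is None. The RNG stream order is fixed (position radii, position
    angles, endowments) so that a configuration + seed reproduces the
    state exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    # area-uniform: P(r <= x) proportional to x^2, i.e. r = R * sqrt(u)
    r = cfg.substrate_radius * np.sqrt(rng.random(cfg.n_cells))
    theta = rng.random(cfg.n_cells) * 2.0 * np.pi
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if cfg.k0_mean is None:
        endow = rng.integers(cfg.k0_min, cfg.k0_max + 1, size=cfg.n_cells)
    else:
        # broad, monotone-decaying endowments reproduce the single-scale
        # exponential degree law of mature cultures
        endow = rng.geometric(1.0 / cfg.k0_mean, size=cfg.n_cells)
        endow = np.clip(endow, cfg.k0_min, cfg.k0_max)
    if cfg.n_cells * np.pi * cfg.cell_radius**2 > np.pi * cfg.substrate_radius**2:
        warnings.warn(
            "substrate cannot host all somata without overlap; "
            "overlapping cells will merge at the first step",
            stacklevel=2,
        )
    units = {
        i: Unit(members=[i], pos=xy[i].copy()) for i in range(cfg.n_cells)
    }
    return SimulationState(
        units=units,
        radii=np.full(cfg.n_cells, float(cfg.cell_radius)),
        endowments=endow,
        edges={},
        t=0,
        rng=rng,
    )


def grow_and_wire(state: SimulationState, cfg: SimulationConfig) -> SimulationState:
    """One step of neurite outgrowth and disk-intersection wiring.

    No-op after the wiring stop T_s: neither radii nor the edge set change.
    New links are created at tension F0 with the current step as birth time.
    """
    if state.t > cfg.wiring_stop:
        return state
    # fresh eta for every cell, drawn in ascending cell id (fixed stream)
    eta = state.rng.random(len(state.radii))
    deg = state.unit_degrees()
    for uid, unit in state.units.items():
        k = deg[uid]
        for cell in unit.members:
            frac = max(0.0, 1.0 - k / state.endowments[cell])
            state.radii[cell] += cfg.growth_velocity * eta[cell] * frac

    uids = sorted(state.units)
    pos = np.array([state.units[u].pos for u in uids])
    rad = np.array([state.unit_radius(u) for u in uids])
    if len(uids) > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        reach = rad[:, None] + rad[None, :]
        ii, jj = np.nonzero(dist <= reach)
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            key = _edge_key(uids[a], uids[b])
            if key not in state.edges:
                state.edges[key] = EdgeState(
                    tension=cfg.initial_tension, birth=state.t
                )
    return state


def update_tensions(state: SimulationState, cfg: SimulationConfig) -> SimulationState:
    """Increment every pre-existing edge's tension by ΔF.

    Edges born in the current step keep their initial tension, so an edge
    born at step t0 carries F0 + ΔF·(t − t0) at step t.
    """
    for e in state.edges.values():
        if e.birth < state.t:
            e.tension += cfg.tension_increment
    return state


def net_force(state: SimulationState, uid: int) -> np.ndarray:
    """Vector sum of tensions pulling a unit toward its neighbours.

    Edges internal to the unit contribute nothing (they no longer exist
    after merging); a tensioned edge between coincident centroids has an
    undefined direction and contributes zero (counted as a warning).
    """
    if uid not in state.units:
        raise KeyError(f"unknown unit {uid}")
    f = np.zeros(2)
    p = state.units[uid].pos
    for (u, v), e in state.edges.items():
        if uid == u:
            other = v
        elif uid == v:
            other = u
        else:
            continue
        d = state.units[other].pos - p
        norm = np.hypot(d[0], d[1])
        if norm == 0.0:
            state.zero_distance_warnings += 1
            logger.warning(
                "coincident centroids on tensioned edge (%s, %s)", u, v
            )
            continue
        f += e.tension * d / norm
    return f


def relax_and_migrate(state: SimulationState, cfg: SimulationConfig) -> SimulationState:
    """Move unbalanced units until net force ≤ adhesion everywhere.

    Adhesion of a unit is F_a times its member count, cancelled when its
    centroid lies outside the substrate disk (the boundary condition).
    Synchronous sweeps: every unit whose |net force| exceeds its adhesion
    moves by the relaxation step δ along the force direction; directions
    are recomputed after each sweep. With a fixed step a unit may end up
    hopping back and forth across its equilibrium point; an exact period-2
    position cycle is detected and treated as termination at the resolution
    δ. If the cycle check never fires and the iteration cap is hit, or a
    cycle is detected with units still formally unbalanced, the state is
    flagged ``unrelaxed`` rather than raising.
    """
    if not state.edges:
        return state
    uids = sorted(state.units)
    index = {u: i for i, u in enumerate(uids)}
    pos = np.array([state.units[u].pos for u in uids], dtype=float)
    n_members = np.array([state.units[u].n_cells for u in uids], dtype=float)
    ekeys = list(state.edges)
    ei = np.array([index[u] for u, _ in ekeys], dtype=int)
    ej = np.array([index[v] for _, v in ekeys], dtype=int)
    tension = np.array([state.edges[k].tension for k in ekeys])

    relaxed = False
    prev = pos.copy()      # positions two sweeps ago, for cycle detection
    for sweep in range(cfg.relax_max_iter):
        d = pos[ej] - pos[ei]
        dist = np.sqrt((d**2).sum(axis=1))
        ok = dist > 0
        if not ok.all():
            state.zero_distance_warnings += int((~ok).sum())
        unit_vec = np.zeros_like(d)
        unit_vec[ok] = d[ok] / dist[ok, None]
        f = np.zeros_like(pos)
        np.add.at(f, ei, tension[:, None] * unit_vec)
        np.add.at(f, ej, -tension[:, None] * unit_vec)
        adhesion = cfg.adhesion_per_cell * n_members
        outside = (pos**2).sum(axis=1) > cfg.substrate_radius**2
        adhesion[outside] = 0.0
        fmag = np.sqrt((f**2).sum(axis=1))
        movers = fmag > adhesion
        if not movers.any():
            relaxed = True
            break
        if sweep % 2 == 0:
            if sweep > 0 and np.array_equal(pos, prev):
                break  # exact period-2 hop around equilibrium
            prev = pos.copy()
        pos[movers] += cfg.relax_step * f[movers] / fmag[movers, None]
    if not relaxed:
        state.unrelaxed = True
        logger.debug("relaxation cap hit at step %d", state.t)
    for u in uids:
        state.units[u].pos = pos[index[u]]
    return state


def merge_units(state: SimulationState, cfg: SimulationConfig) -> SimulationState:
    """Merge units closer than d_merge into clusters (transitive closure).

    The merged unit keeps the smallest member unit id; its centroid is the
    member-count-weighted mean of the merged centroids. Edges internal to
    the new cluster are deleted; parallel edges toward a common neighbour
    bundle into one edge with the summed tension (earliest birth kept).
    The result is independent of unit enumeration order.
    """
    uids = sorted(state.units)
    if len(uids) < 2:
        return state
    pos = np.array([state.units[u].pos for u in uids])
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    parent = {u: u for u in uids}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # anchor on the smaller id for order independence
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    ii, jj = np.nonzero(dist < cfg.merge_distance)
    for a, b in zip(ii, jj):
        if a < b:
            union(uids[a], uids[b])

    groups: dict[int, list[int]] = {}
    for u in uids:
        groups.setdefault(find(u), []).append(u)
    if all(len(g) == 1 for g in groups.values()):
        return state

    new_units: dict[int, Unit] = {}
    remap: dict[int, int] = {}
    for root, group in groups.items():
        members: list[int] = []
        weights = []
        centroids = []
        for u in group:
            unit = state.units[u]
            members.extend(unit.members)
            weights.append(unit.n_cells)
            centroids.append(unit.pos)
            remap[u] = root
        w = np.asarray(weights, dtype=float)
        centroid = (np.asarray(centroids) * w[:, None]).sum(axis=0) / w.sum()
        new_units[root] = Unit(members=sorted(members), pos=centroid)

    new_edges: dict[tuple[int, int], EdgeState] = {}
    for (u, v), e in state.edges.items():
        nu, nv = remap[u], remap[v]
        if nu == nv:
            continue  # internal to a cluster: neurite absorbed
        key = _edge_key(nu, nv)
        if key in new_edges:
            new_edges[key].tension += e.tension
            new_edges[key].birth = min(new_edges[key].birth, e.birth)
        else:
            new_edges[key] = EdgeState(tension=e.tension, birth=e.birth)

    state.units = new_units
    state.edges = new_edges
    return state


def snapshot(state: SimulationState) -> CultureGraph:
    """Freeze the current units/edges as a C-node culture graph."""
    nodes = [
        (uid, CLUSTER, (unit.pos[0], unit.pos[1]))
        for uid, unit in sorted(state.units.items())
    ]
    edges = [(u, v, e.tension) for (u, v), e in sorted(state.edges.items())]
    return build_graph(nodes, edges)


def step(state: SimulationState, cfg: SimulationConfig) -> SimulationState:
    """Advance one DIV: grow/wire, accumulate tension, relax, merge."""
    state.t += 1
    grow_and_wire(state, cfg)
    update_tensions(state, cfg)
    relax_and_migrate(state, cfg)
    merge_units(state, cfg)
    return state


def simulate(
    cfg: SimulationConfig, seed: int | None = None
) -> list[CultureGraph]:
    """Run the full growth model; return one snapshot per step 0..T.

    ``seed`` overrides ``cfg.seed`` (convenient for ensembles). Snapshots
    are independent copies; the sequence is deterministic given the
    configuration and seed.
    """
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": int(seed)})
    state = init_culture(cfg)
    snaps = [snapshot(state)]
    for _ in range(cfg.total_steps):
        step(state, cfg)
        snaps.append(snapshot(state))
        logger.debug(
            "step %d: units=%d edges=%d unrelaxed=%s",
            state.t, len(state.units), len(state.edges), state.unrelaxed,
        )
    return snaps
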