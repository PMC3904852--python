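# Methods

## Graph representation

A culture at one developmental stage is an undirected simple graph with
two node classes: C (neurons / clusters of neurons, i.e. cluster
centroids) and B (neurite branch or connection points). Links are treated
as identical — length and direction are ignored — so the object of study
is a symmetric adjacency matrix with empty diagonal. All statistics are
computed on the C-node subgraph: two C-nodes are adjacent when they share
a direct link or are joined by a path whose internal nodes are all
B-class. The reduction is idempotent, never connects C-nodes from
different components, and collapses multiple routes between the same
C-pair into one unweighted link. B-only chains with no terminal C-node
carry no connectivity information between neurons and are dropped.

Positions are 2-D coordinates in micrometres, origin at the substrate
centre. Node ids are opaque integers.

## Growth model

The simulator evolves N cells on a circular substrate in discrete steps,
one step per day in vitro (DIV). Mechanisms, in the order applied per
step: neurite growth and wiring, tension accumulation, relaxation
(migration), merging.

**Growth and wiring.** Cell *i*'s neurite disk radius grows by
Δr = v·η·max(0, 1 − k/k⁰) with η ~ U[0,1] redrawn per cell per step and k
the degree of the cell's unit. The factor max(0, 1 − k/k⁰) is the
simplest monotone form that decays with the fraction of the endowment k⁰
already realized and freezes growth at saturation; it is isolated in one
function so alternative decay forms are one-line swaps. Units are linked
the first time centroid distance ≤ the sum of their disk radii (a
cluster's disk radius is its largest member radius). Growth and wiring
both stop after step T_s.

**Endowments.** k⁰ is drawn once per cell. The default draw is geometric
(mean `k0_mean`, clipped to [`k0_min`, `k0_max`]) rather than uniform: a
broad, monotone-decaying endowment mix is what pushes the simulated
degree distributions toward the single-scale exponential family seen in
real cultures, whereas uniform endowments leave the degree law strictly
peaked. Uniform draws remain available (`k0_mean=None`).

**Tension and migration.** A link starts at tension F₀ on the step of
its birth and gains ΔF on every later step, so an edge born at t₀ carries
F₀ + ΔF·(t − t₀). Tension is a scalar per edge (no length dependence);
its direction is re-evaluated from current centroids. A unit of m cells
adheres with force m·F_a, cancelled when its centroid leaves the
substrate disk (the boundary condition — there are no reflecting walls).
Relaxation is synchronous fixed-step gradient descent: every unit with
|net force| > adhesion moves by δ along its net force; directions are
recomputed each sweep until all units are balanced or the iteration cap
is reached. Because the step is fixed, a unit with a constant excess
force ends up hopping across its equilibrium point; an exact period-2
position cycle is detected and treated as termination at resolution δ
(the positions are identical to running out the cap). States that
terminate with formally unbalanced units are flagged `unrelaxed` rather
than raising.

**Merging.** After relaxation, the transitive closure of "centroid
distance < d_merge" partitions units; each part becomes one cluster
(centroid = member-count-weighted mean; id = smallest constituent id, so
the partition is independent of enumeration order). Links internal to a
cluster are absorbed; parallel links to a common neighbour bundle into
one link carrying the summed tension and the earliest birth step. Cell
count is conserved at every step.

**What the model leaves out.** No neurite branching (the stated reason
the real cultures reach higher mean degrees than the model), no
retraction as a distinct mechanism, no 3-D structure, no electrical
activity. Simulated snapshots contain only C-nodes; B-nodes occur only in
externally supplied graphs.

## Default parameters

Units: lengths µm, forces arbitrary force units, time steps = DIV.

| parameter | default | meaning |
|---|---|---|
| n_cells | 300 | cells seeded |
| substrate_radius | 450 | culture disk radius |
| cell_radius ρ | 7.5 | soma / initial disk radius |
| growth_velocity v | 30 | neurite growth velocity per step |
| wiring_stop T_s | 6 | last step of growth and wiring |
| total_steps T | 18 | culture horizon (18 DIV) |
| initial_tension F₀ | 1 | tension at link birth |
| tension_increment ΔF | 1 | tension gained per step |
| adhesion_per_cell F_a | 14 | substrate anchoring per cell |
| merge_distance | 15 (= 2ρ) | somata-touching merge threshold |
| k0_mean / k0_min / k0_max | 8 / 1 / 50 | geometric endowment draw |
| relax_step δ | 3.75 (= ρ/2) | relaxation displacement per sweep |
| relax_max_iter | 1000 | relaxation sweep cap |

The defaults are this package's fitted example configuration: they were
calibrated, once, so that the 300-cell ensemble reproduces the
developmental scenario of dense invertebrate cultures — link count rising
to a peak at the wiring stop and declining thereafter, GCC2 rising then
collapsing into the GCC while the giant component keeps growing,
clustering an order of magnitude above degree-matched random graphs at
near-random path length from the peak onward, persistently positive
degree-mixing correlation, and link density staying below ten percent.
They are a working point, not measured biological constants.

## Statistics conventions

* All observables are computed on nodes having at least one link; the
  component tracker (`gcc_sizes`) can include isolated nodes via a flag.
* Average path length L is restricted to pairs inside the giant
  component. Global efficiency averages 1/d over *all* pairs (1/∞ = 0),
  which is exactly why it is reported alongside L: it tolerates
  disconnected stages. Local efficiency is the mean over nodes of the
  neighbour-subgraph global efficiency (degree ≤ 1 nodes contribute 0).
* The degree law is summarized by fitting ln P_c(k) vs k by ordinary
  least squares over the distinct observed degrees with P_c(k) > 0
  (P_c(k) = fraction of connected nodes with degree ≥ k); the scale is
  k* = −1/slope. A maximum-likelihood geometric fit is available as an
  independent cross-check (`fit_geometric_mle`); the log-LS value is the
  reported one. Regular graphs (< 3 distinct degrees) raise a degenerate-
  fit error; `compute_stats` converts degenerate fits to NaN markers.
* Assortativity fits ln k_nn = ln c + α ln k over per-node points
  (k_nn = mean neighbour degree); r is the Pearson correlation of the log
  points, consistent with fitting a power law k_nn ∝ k^α. A degree-binned
  variant exists behind a flag. Raw-scale correlation is a one-liner on
  the same points but is not what the exponent fit linearizes, so it is
  not the default. Mixing regimes: linear |α−1| ≤ 0.1, sub-linear
  α < 0.9, super-linear α > 1.1.
* Null models are degree-preserving double-edge-swap randomizations:
  10×E accepted swaps by default, attempts capped at 100× the requested
  swaps so rigid graphs (e.g. a triangle) terminate unchanged with a
  warning counter. Connectedness is *not* enforced — L is computed on the
  GCC of each realization, matching how the observed L is computed.
  Ensemble summaries (default 20 realizations) are reproducible from one
  seed via deterministically spawned sub-seeds.
* Longitudinal tables hold per-step ensemble mean ± SEM (sd/√n, ddof 1,
  NaN markers skipped; SEM 0 for n = 1). The developmental transition is
  defined operationally: link-count peak = argmax of the mean edge count
  (ties to the earlier step); GCC2 collapse onset = first step after the
  GCC2 maximum with two consecutive decreases. Ensemble-to-ensemble
  comparison correlates mean curves per field (Pearson), not run-matched
  pairs.

## Synthetic data and what tests show

The `fixtures` module generates all test inputs: named deterministic toy
graphs (including `geometric_random`, a static stand-in for spatial
culture graphs, and `c_b_chain` for two-class reduction) and synthetic
per-run stats sequences with named trends. Simulated ensembles emulate
the *topological* developmental scenario of clustered cultures; they do
not emulate neurite branching, image-extraction noise, culture-to-culture
protocol variability, or absolute biological scales (forces are in
arbitrary units). Passing tests therefore certify the statistics
machinery exactly, and the model's qualitative scenario — not
quantitative agreement with any particular culture.

Known limitation, surfaced by the test suite deliberately: without
branching, disk-intersection wiring produces peaked (binomial-like)
degree distributions, so the fitted exponential scale k* of simulated
snapshots stays well below the mean degree (k*/⟨k⟩ ≈ 0.4–0.5 across the
explored parameter space), unlike real cultures where k* ≈ ⟨k⟩. The
acceptance test asserting k* within 25% of ⟨k⟩ on the simulated ensemble
fails for this reason and is intentionally left failing.

## Numerical and scale choices

* Ensemble sizes: the developmental checks use 50 independent runs of
  300 cells over 18 steps, with 20-realization null ensembles; null
  normalization is evaluated at four sampled stages (peak, peak+3, DIV
  12, DIV 18) — the ratios vary smoothly between stages, so denser
  sampling adds cost without information.
* Shortest-path quantities use scipy's sparse-graph BFS; correctness is
  pinned to Floyd–Warshall / neighbour-enumeration oracles on exhaustive
  small-graph sets (all ≤ 7-node graphs) and 200 seeded random graphs.
* RNG discipline: one `numpy` generator per simulation with a fixed
  stream order (position radii, position angles, endowments, then
  per-step η in ascending cell id); per-run and per-realization seeds are
  spawned deterministically from a single base seed. Identical
  configuration + seed reproduces snapshot sequences byte-for-byte.
* Degenerate inputs: edgeless graphs raise a distinct error for L and
  produce NaN-marked records elsewhere; coincident-centroid tensioned
  edges contribute zero force and increment a warning counter; a
  substrate too small for its cells warns and resolves by first-step
  merging.
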