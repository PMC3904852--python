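"""Developmental (longitudinal) analysis of culture ensembles.

Cultures — experimental or simulated — are followed over days in vitro
(DIV), each run contributing one :class:`~culturenet.netstats.StatsRecord`
per step. This module aggregates an ensemble of runs into per-step
mean ± standard error of the mean (SEM) tables, detects the developmental
transition (the link-count peak and the onset of the second-largest
component collapsing into the giant one), and correlates mean curves
between two ensembles — the mechanism used to score simulated parameter
sets against experimental trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .growth_model import SimulationConfig, simulate
from .netstats import STAT_FIELDS, StatsRecord, compute_stats
from .null_models import null_ensemble_stats
from .spatial_graph import CultureGraph


@dataclass
class LongitudinalTable:
    """Per-step ensemble summary: mean, SEM and count for every observable.

    Backed by a DataFrame indexed by step with columns
    ``<field>_mean``, ``<field>_sem``, ``<field>_n``.
    """

    frame: pd.DataFrame

    @property
    def steps(self) -> list[int]:
        return list(self.frame.index)

    def mean(self, field: str) -> pd.Series:
        return self.frame[f"{field}_mean"]

    def sem(self, field: str) -> pd.Series:
        return self.frame[f"{field}_sem"]

    def subset(self, steps: Sequence[int]) -> "LongitudinalTable":
        return LongitudinalTable(self.frame.loc[list(steps)])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="step")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LongitudinalTable":
        return cls(pd.read_csv(path, index_col="step"))


def aggregate_runs(
    runs: Sequence[Sequence[StatsRecord]],
    steps: Sequence[int] | None = None,
) -> LongitudinalTable:
    """Aggregate per-run stats sequences into mean ± SEM per step.

    All runs must share the same step grid. NaN markers (degenerate fits
    etc.) are skipped; the per-field ``n`` column counts the values that
    actually entered the mean. SEM = sd/√n (ddof=1), defined as 0 for
    n = 1 and NaN for n = 0.
    """
    if not runs:
        raise ValueError("no runs to aggregate")
    n_steps = len(runs[0])
    if any(len(r) != n_steps for r in runs):
        raise ValueError("runs have mismatched step grids")
    if steps is None:
        steps = list(range(n_steps))
    elif len(steps) != n_steps:
        raise ValueError("steps length does not match run length")

    data: dict[str, list[float]] = {}
    for f in STAT_FIELDS:
        means, sems, counts = [], [], []
        for s in range(n_steps):
            vals = np.array(
                [getattr(run[s], f) for run in runs], dtype=float
            )
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            counts.append(n)
            if n == 0:
                means.append(math.nan)
                sems.append(math.nan)
            else:
                means.append(float(vals.mean()))
                sems.append(
                    0.0 if n == 1 else float(vals.std(ddof=1) / math.sqrt(n))
                )
        data[f + "_mean"] = means
        data[f + "_sem"] = sems
        data[f + "_n"] = counts
    frame = pd.DataFrame(data, index=pd.Index(steps, name="step"))
    return LongitudinalTable(frame)


@dataclass
class TransitionSummary:
    """Developmental transition markers read off the mean curves."""

    peak_step: int                 # argmax of the mean link count
    gcc2_collapse_step: int | None  # onset of the GCC2 collapse, if seen


def detect_transition(table: LongitudinalTable) -> TransitionSummary:
    """Locate the link-count peak and the GCC2 collapse onset.

    The peak is the argmax of the mean edge count (ties toward the earlier
    step). The collapse onset is the first step after the GCC2 maximum
    where the mean GCC2 size decreases for two consecutive steps; a series
    that never does returns ``None`` for the onset.
    """
    if len(table.steps) < 3:
        raise ValueError("need at least 3 steps to detect a transition")
    steps = np.asarray(table.steps)
    edges = table.mean("n_edges").to_numpy(dtype=float)
    peak_step = int(steps[int(np.nanargmax(edges))])

    g2 = table.mean("gcc2_size").to_numpy(dtype=float)
    i_max = int(np.nanargmax(g2))
    onset = None
    for i in range(i_max + 1, len(g2) - 1):
        if g2[i] < g2[i - 1] and g2[i + 1] < g2[i]:
            onset = int(steps[i])
            break
    return TransitionSummary(peak_step=peak_step, gcc2_collapse_step=onset)


def compare_timeseries(
    table_a: LongitudinalTable,
    table_b: LongitudinalTable,
    fields: Sequence[str] | None = None,
) -> dict[str, float]:
    """Pearson correlation between the mean curves of two ensembles.

    Used to score a simulated ensemble against experimental trajectories.
    Both tables must share the step grid; per field, steps where either
    mean is NaN are dropped, at least 3 common steps are required, and a
    zero-variance series yields a NaN marker.
    """
    if list(table_a.steps) != list(table_b.steps):
        raise ValueError("tables have different step grids")
    if fields is None:
        fields = STAT_FIELDS
    out: dict[str, float] = {}
    for f in fields:
        a = table_a.mean(f).to_numpy(dtype=float)
        b = table_b.mean(f).to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(b))
        if keep.sum() < 3:
            out[f] = math.nan
            continue
        a, b = a[keep], b[keep]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            out[f] = math.nan
            continue
        out[f] = float(pearsonr(a, b).statistic)
    return out


# ---------------------------------------------------------------------------
# simulated ensembles
# ---------------------------------------------------------------------------

def run_seeds(base_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run integer seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_runs)]


def run_ensemble(
    cfg: SimulationConfig,
    n_runs: int,
    base_seed: int,
    keep_graphs: bool = False,
) -> tuple[list[list[StatsRecord]], list[list[CultureGraph]] | None]:
    """Simulate ``n_runs`` independent cultures and compute per-step stats.

    Returns the per-run stats sequences (one StatsRecord per step 0..T)
    and, when ``keep_graphs`` is set, the raw snapshot sequences for
    follow-up analyses such as null-model normalization at chosen steps.
    """
    stats_runs: list[list[StatsRecord]] = []
    graph_runs: list[list[CultureGraph]] = []
    for s in run_seeds(base_seed, n_runs):
        snaps = simulate(cfg, seed=s)
        stats_runs.append([compute_stats(g) for g in snaps])
        if keep_graphs:
            graph_runs.append(snaps)
    return stats_runs, (graph_runs if keep_graphs else None)


def smallworld_at_steps(
    graph_runs: Sequence[Sequence[CultureGraph]],
    steps: Sequence[int],
    base_seed: int,
    n_real: int = 20,
) -> pd.DataFrame:
    """Null-normalized small-world ratios at selected developmental steps.

    For every run and requested step, a degree-matched rewired ensemble of
    ``n_real`` realizations normalizes C and L; rows hold the per-run
    ratios, tagged by run and step. Snapshots whose graph has fewer than
    two edges are skipped.
    """
    from .netstats import smallworld_ratios

    rows = []
    seeds = run_seeds(base_seed + 1, len(graph_runs) * len(steps))
    i = 0
    for run_idx, snaps in enumerate(graph_runs):
        for s in steps:
            g = snaps[s]
            seed = seeds[i]
            i += 1
            if g.n_edges < 2:
                continue
            summary = null_ensemble_stats(
                g, n_real=n_real, seed=seed, include_efficiency=False
            )
            c_ratio, l_ratio, l_lat = smallworld_ratios(g, summary)
            rows.append(
                {"run": run_idx, "step": s, "c_over_crand": c_ratio,
                 "l_over_lrand": l_ratio, "l_over_llattice": l_lat}
            )
    return pd.DataFrame(rows)
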