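"""Generative models of dyadic affiliative/aggressive interaction streams.

Two models produce signed temporal networks for a small group (four nodes
by default, 20 three-minute periods per day over 80 days, 100 realizations).

*Memoryless ("simple") model.*  All links start neutral.  In each period
one dyad is drawn uniformly and its link set to +1 with the general
affiliation probability, to -1 with the general aggression probability,
and left neutral otherwise.

*Memory-based ("complex") model.*  Each period proceeds in order: (1) every
dyad that held a conflict in the previous period reconciles (+1) with the
reconciliation probability; (2) for each such conflict, one dyad containing
exactly one former opponent is drawn uniformly and set +1 with the
new-affiliation probability or -1 with the new-aggression probability;
(3) a spontaneous draw as in the memoryless model, with the spontaneous
probabilities.  A dyad already assigned in the current period is never
overwritten (first write wins).  Multiple previous-period conflicts are
processed in random order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .aggregation import AggregatedSnapshot, aggregate_day
from .motifs import MotifHistogram, canonicalize, census_snapshots, encode
from .events import ProbabilitySet
from .types import GroupRoster, Individual
from .temporal import SignedTemporalNetwork


def generic_roster(n_nodes: int, group: str = "sim") -> GroupRoster:
    """Anonymous roster for simulations (sexes alternate; models ignore them)."""
    members = [
        Individual(id=f"n{k}", sex="FM"[k % 2], node_index=k)
        for k in range(1, n_nodes + 1)
    ]
    return GroupRoster(group=group, members=members)


@dataclass
class SimulationConfig:
    """Run shape and probabilities for either model.

    Defaults mirror the study setup: 4 nodes, 20 periods of 3 min per day,
    80 days (1600 periods) per realization, 100 realizations.
    ``post_conflict_draw`` controls whether the new-contact step runs once
    per previous-period conflict (default) or once per period.
    """

    probs: ProbabilitySet
    n_nodes: int = 4
    periods_per_day: int = 20
    n_days: int = 80
    n_realizations: int = 100
    seed: int | None = None
    memory_mode: str = "simple"
    post_conflict_draw: str = "per_conflict"
    roster: GroupRoster | None = None

    def __post_init__(self) -> None:
        if self.memory_mode not in ("simple", "complex"):
            raise ValueError("memory_mode must be 'simple' or 'complex'")
        if self.post_conflict_draw not in ("per_conflict", "per_period"):
            raise ValueError(
                "post_conflict_draw must be 'per_conflict' or 'per_period'"
            )
        if min(self.n_nodes, self.periods_per_day, self.n_days, self.n_realizations) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.roster is None:
            self.roster = generic_roster(self.n_nodes)
        elif self.roster.n != self.n_nodes:
            raise ValueError("roster size does not match n_nodes")
        p = self.probs
        if self.memory_mode == "simple":
            if p.p_general_affiliation is None or p.p_general_aggression is None:
                raise ValueError("simple model needs the general probabilities")
        else:
            needed = (
                p.p_spontaneous_affiliation,
                p.p_spontaneous_aggression,
                p.p_reconciliation,
                p.p_new_affiliation,
                p.p_new_aggression,
            )
            if any(v is None for v in needed):
                raise ValueError("complex model needs all five memory probabilities")

    @property
    def dyads(self) -> list[tuple[int, int]]:
        return self.roster.dyads()


def _one_opponent_dyads(dyads, pair) -> list[tuple[int, int]]:
    return [d for d in dyads if len(set(d) & set(pair)) == 1]


def step_complex_period(
    rng: np.random.Generator,
    prev_conflicts: list[tuple[int, int]],
    probs: ProbabilitySet,
    dyads: list[tuple[int, int]],
    post_conflict_draw: str = "per_conflict",
) -> list[tuple[tuple[int, int], int, str]]:
    """One period of the memory-based model.

    Returns the period's assignments as (dyad, sign, category) in the order
    they were made; a dyad appears at most once (first write wins).  Exposed
    for testing and reused by the observation-log generator, whose ledger
    needs the latent categories.
    """
    assigned: dict[tuple[int, int], int] = {}
    out: list[tuple[tuple[int, int], int, str]] = []

    conflicts = list(prev_conflicts)
    if len(conflicts) > 1:
        order = rng.permutation(len(conflicts))
        conflicts = [conflicts[k] for k in order]

    for pair in conflicts:
        if rng.random() < probs.p_reconciliation and pair not in assigned:
            assigned[pair] = 1
            out.append((pair, 1, "reconciliation"))

    p_na = probs.p_new_affiliation
    p_ng = probs.p_new_aggression

    def new_contact_draw(candidates) -> None:
        if not candidates:
            return
        d = candidates[rng.integers(len(candidates))]
        u = rng.random()
        if u < p_na:
            sign, cat = 1, "new_affiliation"
        elif u < p_na + p_ng:
            sign, cat = -1, "new_aggression"
        else:
            return
        if d not in assigned:
            assigned[d] = sign
            out.append((d, sign, cat))

    if post_conflict_draw == "per_conflict":
        for pair in conflicts:
            new_contact_draw(_one_opponent_dyads(dyads, pair))
    elif conflicts:
        union = sorted(
            {d for pair in conflicts for d in _one_opponent_dyads(dyads, pair)}
        )
        new_contact_draw(union)

    f = dyads[rng.integers(len(dyads))]
    u = rng.random()
    if u < probs.p_spontaneous_affiliation:
        sign, cat = 1, "spontaneous_affiliation"
    elif u < probs.p_spontaneous_affiliation + probs.p_spontaneous_aggression:
        sign, cat = -1, "spontaneous_aggression"
    else:
        sign = 0
    if sign and f not in assigned:
        assigned[f] = sign
        out.append((f, sign, cat))
    return out


def _assignments_to_matrix(assignments, n) -> np.ndarray:
    m = np.zeros((n, n), dtype=np.int8)
    for (i, j), sign, _ in assignments:
        m[i, j] = m[j, i] = sign
    return m


def simulate_simple(config: SimulationConfig) -> list[list[SignedTemporalNetwork]]:
    """Memoryless model: one list of daily networks per realization."""
    if config.memory_mode != "simple":
        raise ValueError("config.memory_mode must be 'simple'")
    rng = np.random.default_rng(config.seed)
    p_aff = config.probs.p_general_affiliation
    p_agg = config.probs.p_general_aggression
    n = config.n_nodes
    dyads = config.dyads
    P = config.periods_per_day
    realizations = []
    for _ in range(config.n_realizations):
        days = []
        for day in range(1, config.n_days + 1):
            picks = rng.integers(len(dyads), size=P)
            u = rng.random(P)
            arr = np.zeros((P, n, n), dtype=np.int8)
            signs = np.where(u < p_aff, 1, np.where(u < p_aff + p_agg, -1, 0))
            for t in range(P):
                s = int(signs[t])
                if s:
                    i, j = dyads[int(picks[t])]
                    arr[t, i, j] = arr[t, j, i] = s
            days.append(
                SignedTemporalNetwork(roster=config.roster, day=day, periods=arr)
            )
        realizations.append(days)
    return realizations


def simulate_complex(config: SimulationConfig) -> list[list[SignedTemporalNetwork]]:
    """Memory-based model: one list of daily networks per realization.

    Conflict memory does not cross day boundaries (each day starts with all
    links neutral and no previous-period conflicts).
    """
    if config.memory_mode != "complex":
        raise ValueError("config.memory_mode must be 'complex'")
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    dyads = config.dyads
    P = config.periods_per_day
    realizations = []
    for _ in range(config.n_realizations):
        days = []
        for day in range(1, config.n_days + 1):
            arr = np.zeros((P, n, n), dtype=np.int8)
            prev_conflicts: list[tuple[int, int]] = []
            for t in range(P):
                assignments = step_complex_period(
                    rng, prev_conflicts, config.probs, dyads,
                    config.post_conflict_draw,
                )
                arr[t] = _assignments_to_matrix(assignments, n)
                prev_conflicts = [d for d in dyads if arr[t][d] == -1]
            days.append(
                SignedTemporalNetwork(roster=config.roster, day=day, periods=arr)
            )
        realizations.append(days)
    return realizations


def simulate(config: SimulationConfig) -> list[list[SignedTemporalNetwork]]:
    """Dispatch on ``config.memory_mode``."""
    if config.memory_mode == "simple":
        return simulate_simple(config)
    return simulate_complex(config)


@dataclass
class ExperimentResult:
    """Aggregated-motif summary of a batch of simulated realizations."""

    config: SimulationConfig
    pooled_histogram: MotifHistogram
    realization_histograms: list[MotifHistogram]
    n_period_networks_per_realization: int
    n_snapshots: int
    snapshots: list[list[AggregatedSnapshot]] | None = None


def run_experiment(
    config: SimulationConfig, keep_snapshots: bool = False
) -> ExperimentResult:
    """Simulate, aggregate each day, and census the snapshot sign patterns.

    Returns the pooled motif histogram over all realizations plus one
    histogram per realization.  Snapshots are dropped by default to bound
    memory; pass ``keep_snapshots=True`` to retain them.
    """
    realizations = simulate(config)
    pooled = MotifHistogram(n_nodes=config.n_nodes, source="simulated")
    per_real: list[MotifHistogram] = []
    kept: list[list[AggregatedSnapshot]] = []
    n_snapshots = 0
    for days in realizations:
        hist = MotifHistogram(n_nodes=config.n_nodes, source="simulated")
        snaps_r: list[AggregatedSnapshot] = []
        for net in days:
            for snap in aggregate_day(net):
                code = canonicalize(encode(snap.sign_pattern()))
                hist.add(code)
                pooled.add(code)
                n_snapshots += 1
                if keep_snapshots:
                    snaps_r.append(snap)
        per_real.append(hist)
        if keep_snapshots:
            kept.append(snaps_r)
    return ExperimentResult(
        config=config,
        pooled_histogram=pooled,
        realization_histograms=per_real,
        n_period_networks_per_realization=config.periods_per_day * config.n_days,
        n_snapshots=n_snapshots,
        snapshots=kept if keep_snapshots else None,
    )
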