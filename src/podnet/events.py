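"""Post-conflict event classification and probability/rate estimation.

Interactions are treated as *episodes*: a conflict or an affiliation on one
dyad spans consecutive periods of the same sign (neutral gaps do not end
it) and finishes when the link's valence flips or the day ends.  Each
conflict opens a same-day memory on its opponent pair; while that memory is
open,

* the first affiliative episode between the two former opponents is a
  **reconciliation**,
* an affiliative episode between one opponent and a bystander is a
  **new (third-party) affiliation**,
* an aggressive episode involving a former opponent is a
  **new (redirected) aggression**,

and a reconciliation or new affiliation closes the memory — affiliations
and aggressions after that are again spontaneous.  The memory horizon is
configurable: ``None`` keeps it open for the rest of the day (the
convention of the empirical analysis); an integer ``h`` keeps it open for
``h`` periods after each conflict period (``h = 1`` matches the
memory-based simulator).

Probabilities per 3-min period convert to per-minute rates through
``p = 1 - exp(-r * dt)``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .temporal import SignedTemporalNetwork

CATEGORIES = (
    "reconciliation",
    "new_affiliation",
    "spontaneous_affiliation",
    "new_aggression",
    "spontaneous_aggression",
)

AFFILIATIVE_CATEGORIES = (
    "reconciliation",
    "new_affiliation",
    "spontaneous_affiliation",
)
AGGRESSIVE_CATEGORIES = ("new_aggression", "spontaneous_aggression")


@dataclass(frozen=True)
class Episode:
    """A maximal same-sign run of one dyad's link within a day.

    ``start``/``end`` are 1-based periods of the first and last non-zero
    entry; ``n_active`` counts the non-zero periods in between (neutral
    gaps are allowed inside an episode).
    """

    day: Hashable
    dyad: tuple[int, int]
    sign: int
    start: int
    end: int
    n_active: int


@dataclass(frozen=True)
class ClassifiedEpisode:
    episode: Episode
    category: str
    trigger: Episode | None = None


@dataclass
class Classification:
    """Classified episodes for one or more days, with count helpers."""

    episodes: list[ClassifiedEpisode] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for ce in self.episodes:
            out[ce.category] += 1
        return out

    def daily_counts(self) -> pd.DataFrame:
        """Per-day episode counts, one column per category."""
        rows: dict[Hashable, dict[str, int]] = {}
        for ce in self.episodes:
            day = ce.episode.day
            rows.setdefault(day, {c: 0 for c in CATEGORIES})
            rows[day][ce.category] += 1
        frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        frame.index.name = "day"
        return frame.sort_index()

    def to_frame(self, roster) -> pd.DataFrame:
        rows = []
        for k, ce in enumerate(self.episodes):
            ep = ce.episode
            trig = ce.trigger
            rows.append(
                (
                    ep.day,
                    ep.start,
                    ep.end,
                    roster.id_of(ep.dyad[0]),
                    roster.id_of(ep.dyad[1]),
                    ep.sign,
                    ce.category,
                    "" if trig is None else f"{trig.dyad}@{trig.start}",
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "day",
                "start",
                "end",
                "id1",
                "id2",
                "valence",
                "category",
                "linked_conflict",
            ],
        )


def extract_episodes(net: SignedTemporalNetwork) -> list[Episode]:
    """Per-link episodes of one day, sorted by (start period, dyad)."""
    episodes: list[Episode] = []
    P = net.periods
    for (i, j) in net.roster.dyads():
        series = P[:, i, j]
        sign = 0
        start = end = 0
        active = 0
        for t in range(len(series)):
            s = int(series[t])
            if s == 0:
                continue
            if sign != 0 and s != sign:
                episodes.append(
                    Episode(net.day, (i, j), sign, start, end, active)
                )
                sign = 0
            if sign == 0:
                sign, start, active = s, t + 1, 0
            end = t + 1
            active += 1
        if sign != 0:
            episodes.append(Episode(net.day, (i, j), sign, start, end, active))
    episodes.sort(key=lambda e: (e.start, e.dyad))
    return episodes


@dataclass
class _Memory:
    pair: tuple[int, int]
    conflict: Episode
    open_from: int
    open_until: int
    opened_order: int
    open: bool = True


def classify_events(
    networks: Iterable[SignedTemporalNetwork],
    memory_horizon: int | None = None,
    include_renewed: bool = True,
) -> Classification:
    """Classify every episode of every day into the five categories.

    ``memory_horizon=None`` keeps a conflict memory open until the end of
    the day; ``memory_horizon=h`` closes it ``h`` periods after the
    conflict's last period.  With ``include_renewed`` (default), a renewed
    aggression between the same two opponents while their memory is open
    counts as new aggression; otherwise it is spontaneous.  When several
    memories are compatible with an event, the most recently opened wins.
    """
    result = Classification()
    for net in networks:
        episodes = extract_episodes(net)
        memories: list[_Memory] = []
        for ep in episodes:
            if ep.sign < 0:
                mem = _match_memory(memories, ep, include_renewed)
                category = "new_aggression" if mem else "spontaneous_aggression"
                result.episodes.append(
                    ClassifiedEpisode(ep, category, mem.conflict if mem else None)
                )
                # every conflict opens its own memory; the window opens the
                # period after the conflict begins (post-conflict contacts
                # can occur while a long conflict is still running)
                until = (
                    net.n_periods
                    if memory_horizon is None
                    else min(net.n_periods, ep.end + memory_horizon)
                )
                memories.append(
                    _Memory(
                        pair=ep.dyad,
                        conflict=ep,
                        open_from=ep.start + 1,
                        open_until=until,
                        opened_order=len(memories),
                    )
                )
            else:
                mem = _match_memory(memories, ep, True)
                if mem is None:
                    category = "spontaneous_affiliation"
                elif set(mem.pair) == set(ep.dyad):
                    category = "reconciliation"
                    mem.open = False
                else:
                    category = "new_affiliation"
                    mem.open = False
                result.episodes.append(
                    ClassifiedEpisode(ep, category, mem.conflict if mem else None)
                )
    return result


def _match_memory(
    memories: list[_Memory], ep: Episode, allow_same_pair: bool
) -> _Memory | None:
    best = None
    for mem in memories:
        if not mem.open:
            continue
        if not (mem.open_from <= ep.start <= mem.open_until):
            continue
        shared = len(set(mem.pair) & set(ep.dyad))
        if shared == 0:
            continue
        if shared == 2 and not allow_same_pair:
            continue
        if best is None or mem.opened_order > best.opened_order:
            best = mem
    return best


def spontaneous_counts(
    total_aff: int,
    total_agg: int,
    n_reconciliation: int,
    n_new_affiliation: int,
    n_new_aggression: int,
) -> tuple[int, int]:
    """Spontaneous counts by subtraction from daily totals.

    spontaneous affiliations = total affiliations - reconciliations - new
    affiliations; spontaneous aggressions = total aggressions - new
    aggressions.  Negative results mean inconsistent inputs and raise.
    """
    counts = (total_aff, total_agg, n_reconciliation, n_new_affiliation, n_new_aggression)
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    n_spont_aff = total_aff - n_reconciliation - n_new_affiliation
    n_spont_agg = total_agg - n_new_aggression
    if n_spont_aff < 0 or n_spont_agg < 0:
        raise ValueError(
            f"inconsistent counts: spontaneous totals would be "
            f"({n_spont_aff}, {n_spont_agg})"
        )
    return n_spont_aff, n_spont_agg


def daily_probability(category_periods: int, periods_in_day: int) -> float:
    """Fraction of a day's periods in which a category's contact occurred."""
    if periods_in_day <= 0:
        raise ValueError("periods_in_day must be positive")
    if not 0 <= category_periods <= periods_in_day:
        raise ValueError(
            f"count {category_periods} outside [0, {periods_in_day}]"
        )
    return category_periods / periods_in_day


def prob_to_rate(p: float, dt_minutes: float) -> float:
    """Per-minute rate r with p = 1 - exp(-r dt).  Requires 0 <= p < 1."""
    if dt_minutes <= 0:
        raise ValueError("dt must be positive")
    if not 0 <= p < 1:
        raise ValueError(f"p must be in [0, 1), got {p} (p=1 implies infinite rate)")
    return -math.log1p(-p) / dt_minutes


def rate_to_prob(r: float, dt_minutes: float) -> float:
    """Per-period probability p = 1 - exp(-r dt).  Requires r >= 0."""
    if dt_minutes <= 0:
        raise ValueError("dt must be positive")
    if r < 0:
        raise ValueError(f"rate must be non-negative, got {r}")
    return -math.expm1(-r * dt_minutes)


@dataclass
class ProbabilitySet:
    """Per-period interaction probabilities and their per-minute rates.

    The memoryless model uses the general probabilities
    (``p_general_affiliation``, ``p_general_aggression``); the memory-based
    model uses the spontaneous/reconciliation/new probabilities.  Unused
    entries may stay None.  Rates follow p = 1 - exp(-r dt).
    """

    period_minutes: float = 3.0
    p_general_affiliation: float | None = None
    p_general_aggression: float | None = None
    p_spontaneous_affiliation: float | None = None
    p_spontaneous_aggression: float | None = None
    p_reconciliation: float | None = None
    p_new_affiliation: float | None = None
    p_new_aggression: float | None = None

    _FIELDS = (
        "p_general_affiliation",
        "p_general_aggression",
        "p_spontaneous_affiliation",
        "p_spontaneous_aggression",
        "p_reconciliation",
        "p_new_affiliation",
        "p_new_aggression",
    )

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        g = (self.p_general_affiliation, self.p_general_aggression)
        if None not in g and g[0] + g[1] > 1 + 1e-12:
            raise ValueError("p_general_affiliation + p_general_aggression > 1")
        s = (self.p_spontaneous_affiliation, self.p_spontaneous_aggression)
        if None not in s and s[0] + s[1] > 1 + 1e-12:
            raise ValueError("spontaneous probabilities sum to > 1")
        nn = (self.p_new_affiliation, self.p_new_aggression)
        if None not in nn and nn[0] + nn[1] > 1 + 1e-12:
            raise ValueError("new-contact probabilities sum to > 1")

    def rates(self) -> dict[str, float]:
        """Per-minute rates for every defined probability."""
        out = {}
        for name in self._FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isnan(v):
                out[name.replace("p_", "r_")] = prob_to_rate(v, self.period_minutes)
        return out

    def to_dict(self) -> dict:
        d = {"period_minutes": self.period_minutes}
        d.update({n: getattr(self, n) for n in self._FIELDS})
        d.update(self.rates())
        return d


def empirical_probabilities(
    networks: Sequence[SignedTemporalNetwork],
    classification: Classification | None = None,
    period_minutes: float | None = None,
    **classify_kwargs,
) -> ProbabilitySet:
    """Descriptive per-period probabilities, the observational way.

    For each day, the number of periods containing an affiliative
    (aggressive) contact is divided by that day's period count; the mean of
    these daily fractions is the general per-period probability.  Category
    probabilities use episode counts per day divided by the day's periods,
    again averaged over days (days weigh equally regardless of length).
    """
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one day of networks")
    if classification is None:
        classification = classify_events(networks, **classify_kwargs)
    if period_minutes is None:
        period_minutes = networks[0].roster.period_minutes

    day_periods = {net.day: net.n_periods for net in networks}
    gen_aff, gen_agg = [], []
    for net in networks:
        has_aff = (net.periods == 1).any(axis=(1, 2))
        has_agg = (net.periods == -1).any(axis=(1, 2))
        gen_aff.append(daily_probability(int(has_aff.sum()), net.n_periods))
        gen_agg.append(daily_probability(int(has_agg.sum()), net.n_periods))

    cat_daily: dict[str, dict[Hashable, int]] = {c: {} for c in CATEGORIES}
    for ce in classification.episodes:
        day = ce.episode.day
        cat_daily[ce.category][day] = cat_daily[ce.category].get(day, 0) + 1
    cat_mean = {}
    for cat in CATEGORIES:
        fractions = [
            min(cat_daily[cat].get(day, 0), nper) / nper
            for day, nper in day_periods.items()
        ]
        cat_mean[cat] = float(np.mean(fractions))

    return ProbabilitySet(
        period_minutes=period_minutes,
        p_general_affiliation=float(np.mean(gen_aff)),
        p_general_aggression=float(np.mean(gen_agg)),
        p_spontaneous_affiliation=cat_mean["spontaneous_affiliation"],
        p_spontaneous_aggression=cat_mean["spontaneous_aggression"],
        p_reconciliation=cat_mean["reconciliation"],
        p_new_affiliation=cat_mean["new_affiliation"],
        p_new_aggression=cat_mean["new_aggression"],
    )


def estimate_probabilities(
    networks: Sequence[SignedTemporalNetwork],
    period_minutes: float | None = None,
    return_counts: bool = False,
):
    """Method-of-moments recovery of the memory-model probabilities.

    Assumes the one-period-memory generative process: in each period one
    dyad is drawn for a spontaneous contact, and every dyad that held a
    conflict in the previous period triggers a reconciliation draw on
    itself plus one new-contact draw on a dyad containing exactly one
    former opponent.

    The spontaneous probabilities are estimated from periods with no
    conflict in the previous period, where they are the only event source.
    Conditional probabilities are estimated from opportunity periods with
    the expected spontaneous contamination removed: a spontaneous
    affiliation has probability p_sa/D of landing on the conflict dyad
    (mimicking reconciliation) and p_sa*u/D of landing on a one-opponent
    dyad (mimicking a new affiliation), with D the number of dyads and u
    the number of eligible one-opponent dyads that period.  Unlike naive
    category counting, this estimator is consistent: the latent category of
    a single contact is not identifiable, but its expected rate is.
    """
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one day of networks")
    if period_minutes is None:
        period_minutes = networks[0].roster.period_minutes
    n = networks[0].roster.n
    dyads = networks[0].roster.dyads()
    n_dyads = len(dyads)

    n_no_opp = 0
    pos_no_opp = 0
    neg_no_opp = 0
    n_opp = 0
    rec_succ = 0
    new_pos = 0
    new_neg = 0
    contam_units = 0.0  # sum over opportunity periods of u / n_dyads

    for net in networks:
        P = net.periods
        for t in range(net.n_periods):
            prev = P[t - 1] if t > 0 else None
            cur = P[t]
            conflicts = (
                [d for d in dyads if prev[d] == -1] if prev is not None else []
            )
            if not conflicts:
                n_no_opp += 1
                iu = np.triu_indices(n, k=1)
                pos_no_opp += int((cur[iu] == 1).sum())
                neg_no_opp += int((cur[iu] == -1).sum())
                continue
            n_opp += len(conflicts)
            conflict_set = set(conflicts)
            eligible = set()
            for (a, b) in conflicts:
                rec_succ += int(cur[a, b] == 1)
                for d in dyads:
                    if d in conflict_set:
                        continue
                    if len({a, b} & set(d)) == 1:
                        eligible.add(d)
            for d in eligible:
                if cur[d] == 1:
                    new_pos += 1
                elif cur[d] == -1:
                    new_neg += 1
            contam_units += len(eligible) / n_dyads

    if n_no_opp == 0:
        raise ValueError("no conflict-free periods: cannot anchor spontaneous rates")
    p_sa = pos_no_opp / n_no_opp
    p_sg = neg_no_opp / n_no_opp

    if n_opp == 0:
        warnings.warn("no post-conflict opportunities observed; memory "
                      "probabilities are undefined and reported as NaN")
        p_rec = p_na = p_ng = math.nan
    else:
        denom = 1.0 - p_sa / n_dyads
        p_rec = (rec_succ / n_opp - p_sa / n_dyads) / denom
        p_na = (new_pos - p_sa * contam_units) / n_opp
        p_ng = (new_neg - p_sg * contam_units) / n_opp

    clip = lambda x: x if math.isnan(x) else min(1.0, max(0.0, x))
    probs = ProbabilitySet(
        period_minutes=period_minutes,
        p_spontaneous_affiliation=clip(p_sa),
        p_spontaneous_aggression=clip(p_sg),
        p_reconciliation=clip(p_rec),
        p_new_affiliation=clip(p_na),
        p_new_aggression=clip(p_ng),
    )
    if not return_counts:
        return probs
    counts = {
        "n_no_opportunity_periods": n_no_opp,
        "spontaneous_affiliations": pos_no_opp,
        "spontaneous_aggressions": neg_no_opp,
        "n_opportunities": n_opp,
        "reconciliation_successes": rec_succ,
        "new_positive_contacts": new_pos,
        "new_negative_contacts": new_neg,
        "contamination_units": contam_units,
    }
    return probs, counts
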