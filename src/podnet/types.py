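"""Core record types for dyadic interaction data in small animal groups.

A study group is a roster of individually identified animals.  Observations
come in two streams: all-occurrence logs of dyadic affiliative/aggressive
contacts binned into fixed-length periods (3 minutes by default), and 0-1
group-sampling records of synchronous swimming used for the affiliation
index.  Everything downstream consumes these types; no other module parses
text.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

#: Link value for an affiliative (positive) contact.
AFFILIATIVE = 1
#: Link value for an aggressive (agonistic, negative) contact.
AGGRESSIVE = -1

SEXES = ("F", "M")


@dataclass(frozen=True)
class Individual:
    """One animal: short id label, sex, and 1-based node index in its group."""

    id: str
    sex: str
    node_index: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.node_index < 1:
            raise ValueError(f"node_index must be >= 1, got {self.node_index}")


@dataclass
class GroupRoster:
    """A study group: its members and the observation period length.

    Node indices must form 1..N; internally all matrix work is 0-based
    (node_index - 1).
    """

    group: str
    members: list[Individual]
    period_minutes: float = 3.0

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                f"group {self.group!r} needs at least 2 members, "
                f"got {len(self.members)}"
            )
        if self.period_minutes <= 0:
            raise ValueError("period_minutes must be positive")
        idx = sorted(m.node_index for m in self.members)
        if idx != list(range(1, len(self.members) + 1)):
            raise ValueError(
                f"node_index values must form 1..{len(self.members)}, got {idx}"
            )
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate individual ids in group {self.group!r}")
        self._by_id = {m.id: m for m in self.members}
        self._by_index = {m.node_index: m for m in self.members}

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return [self._by_index[i].id for i in range(1, self.n + 1)]

    def member(self, id: str) -> Individual:
        try:
            return self._by_id[id]
        except KeyError:
            raise KeyError(
                f"unknown individual id {id!r} in group {self.group!r}"
            ) from None

    def index_of(self, id: str) -> int:
        """0-based matrix index of an individual id."""
        return self.member(id).node_index - 1

    def id_of(self, index: int) -> str:
        """Individual id for a 0-based matrix index."""
        return self._by_index[index + 1].id

    def dyads(self) -> list[tuple[int, int]]:
        """All unordered pairs as 0-based (i, j), i < j, lexicographic."""
        return [(i, j) for i in range(self.n) for j in range(i + 1, self.n)]

    def sex_class(self, i: int, j: int) -> str:
        """Dyad sex class 'F-F', 'F-M' or 'M-M' for 0-based node indices."""
        a = self._by_index[i + 1].sex
        b = self._by_index[j + 1].sex
        return "-".join(sorted((a, b)))


@dataclass(frozen=True)
class InteractionEvent:
    """One observed dyadic contact.

    ``order_in_period`` records observation order inside the 3-min bin so
    that "the last observed interaction" of a dyad-period is well defined.
    Actor/receiver are kept for provenance; the networks built from events
    are undirected.
    """

    day: Hashable
    period: int
    actor: str
    receiver: str
    valence: int
    order_in_period: int = 1

    def __post_init__(self) -> None:
        if self.actor == self.receiver:
            raise ValueError(
                f"actor and receiver must differ (got {self.actor!r} on "
                f"day {self.day!r}, period {self.period})"
            )
        if self.valence not in (AFFILIATIVE, AGGRESSIVE):
            raise ValueError(f"valence must be +1 or -1, got {self.valence!r}")
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")
        if self.order_in_period < 1:
            raise ValueError(f"order_in_period must be >= 1, got {self.order_in_period}")

    @property
    def dyad(self) -> tuple[str, str]:
        """Unordered dyad as a sorted id pair."""
        a, b = sorted((self.actor, self.receiver))
        return (a, b)

    @property
    def sort_key(self) -> tuple:
        # integer day indices sort numerically, labels lexicographically
        day_key = (
            (0, self.day, "") if isinstance(self.day, int) else (1, 0, str(self.day))
        )
        return (day_key, self.period, self.order_in_period)


@dataclass(frozen=True)
class SamplingRecord:
    """One 0-1 group-sampling observation of a dyad in one period.

    ``observed`` marks whether both animals were in view; ``synchronous``
    whether they were swimming synchronously (which entails being observed).
    """

    day: Hashable
    period: int
    id1: str
    id2: str
    observed: int
    synchronous: int

    def __post_init__(self) -> None:
        if self.observed not in (0, 1) or self.synchronous not in (0, 1):
            raise ValueError("observed and synchronous must be 0 or 1")
        if self.synchronous == 1 and self.observed == 0:
            raise ValueError(
                f"synchronous=1 requires observed=1 (dyad {self.id1}-{self.id2}, "
                f"day {self.day!r}, period {self.period})"
            )
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")

    @property
    def dyad(self) -> tuple[str, str]:
        a, b = sorted((self.id1, self.id2))
        return (a, b)
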