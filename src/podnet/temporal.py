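"""Signed temporal networks: one symmetric {-1, 0, +1} matrix per 3-min period.

Within a period a dyad's link is the valence of its *last* observed
interaction (by observation order); dyads with no interaction are neutral.
A "contact", as counted here, is one non-zero dyad-period after that
last-wins collapsing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import GroupRoster, InteractionEvent


@dataclass
class SignedTemporalNetwork:
    """One day's sequence of per-period signed adjacency matrices.

    ``periods`` has shape (n_periods, N, N), entries in {-1, 0, +1},
    symmetric with zero diagonal.
    """

    roster: GroupRoster
    day: Hashable
    periods: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.periods, dtype=np.int8)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError("periods must have shape (n_periods, N, N)")
        if arr.shape[0] < 1:
            raise ValueError("a day must contain at least one period")
        if arr.shape[1] != self.roster.n:
            raise ValueError(
                f"matrix size {arr.shape[1]} != roster size {self.roster.n}"
            )
        if not np.isin(arr, (-1, 0, 1)).all():
            raise ValueError("entries must be in {-1, 0, +1}")
        if (np.diagonal(arr, axis1=1, axis2=2) != 0).any():
            raise ValueError("diagonal entries must be zero")
        if (arr != np.transpose(arr, (0, 2, 1))).any():
            raise ValueError("per-period matrices must be symmetric")
        self.periods = arr

    @property
    def n_periods(self) -> int:
        return self.periods.shape[0]

    def entry(self, period: int, a: str, b: str) -> int:
        """Signed link of dyad (a, b) in a 1-based period."""
        i, j = self.roster.index_of(a), self.roster.index_of(b)
        return int(self.periods[period - 1, i, j])


def build_temporal_network(
    events: Iterable[InteractionEvent], roster: GroupRoster, n_periods: int
) -> SignedTemporalNetwork:
    """Build one day's signed temporal network from that day's events.

    The link of dyad (i, j) in period t is the valence of the last event (by
    ``order_in_period``) on that dyad in t, or 0 if there was none.
    """
    events = sorted(events, key=lambda e: e.sort_key)
    days = {e.day for e in events}
    if len(days) > 1:
        raise ValueError(f"events span multiple days: {sorted(map(str, days))}")
    day = days.pop() if days else None
    n = roster.n
    arr = np.zeros((n_periods, n, n), dtype=np.int8)
    for e in events:
        if e.period > n_periods:
            raise ValueError(
                f"event at period {e.period} exceeds n_periods={n_periods}"
            )
        i, j = roster.index_of(e.actor), roster.index_of(e.receiver)
        # events arrive sorted by order_in_period, so plain assignment
        # implements the last-wins rule
        arr[e.period - 1, i, j] = e.valence
        arr[e.period - 1, j, i] = e.valence
    return SignedTemporalNetwork(roster=roster, day=day, periods=arr)


def contact_counts(networks: Sequence[SignedTemporalNetwork]) -> pd.DataFrame:
    """Count non-zero dyad-periods ("contacts") by valence and dyad sex class.

    Returns a frame indexed by sex class ('F-F', 'F-M', 'M-M') plus a
    'total' row, with columns 'affiliative' and 'aggressive'.
    """
    classes = ["F-F", "F-M", "M-M"]
    counts = {c: {"affiliative": 0, "aggressive": 0} for c in classes}
    for net in networks:
        for (i, j) in net.roster.dyads():
            col = net.periods[:, i, j]
            sc = net.roster.sex_class(i, j)
            counts[sc]["affiliative"] += int((col == 1).sum())
            counts[sc]["aggressive"] += int((col == -1).sum())
    frame = pd.DataFrame(counts).T.loc[classes]
    frame.loc["total"] = frame.sum()
    frame.index.name = "sex_class"
    return frame


def to_long_frame(net: SignedTemporalNetwork) -> pd.DataFrame:
    """Long-format serialization: one row per non-zero dyad-period."""
    rows = []
    for t in range(net.n_periods):
        for (i, j) in net.roster.dyads():
            s = int(net.periods[t, i, j])
            if s != 0:
                rows.append(
                    (net.day, t + 1, net.roster.id_of(i), net.roster.id_of(j), s)
                )
    return pd.DataFrame(rows, columns=["day", "period", "id1", "id2", "sign"])


def networks_to_csv(networks: Sequence[SignedTemporalNetwork], path) -> None:
    frames = [to_long_frame(n) for n in networks]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["day", "period", "id1", "id2", "sign"])
    )
    out.to_csv(path, index=False)
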