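"""Qualitative-change time aggregation of signed temporal networks.

Each day's per-period networks are collapsed into a sequence of weighted
signed snapshots.  A link's *state* is the valence of its last non-zero
entry so far that day: going quiet (returning to neutral) does not change
the state, and an interaction only finishes when the link's valence flips.
A window stays open while every link keeps its state; it closes just
before the first period in which any link changes *qualitatively* —
reverses sign relative to its state, or activates for the first time that
day.  Because the state is tracked over the whole day, a link resuming its
established sign after the window break is a continuation, not a new
activation, so several links can be simultaneously active within one
window.  Within a window a link's weight is the signed sum of its
per-period entries: sign encodes valence, magnitude encodes duration.
Example: a link running (+1, +1, 0, -1) yields a first snapshot of weight
+2 (periods 1-3) and a second of weight -1 (period 4).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .temporal import SignedTemporalNetwork


@dataclass
class AggregatedSnapshot:
    """Weighted signed network for one aggregation window.

    ``window_start``/``window_end`` are inclusive 1-based period indices;
    ``weights`` is the N x N symmetric integer matrix of signed sums.
    """

    day: Hashable
    window_start: int
    window_end: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if (w != w.T).any() or (np.diag(w) != 0).any():
            raise ValueError("weights must be symmetric with zero diagonal")
        if self.window_end < self.window_start:
            raise ValueError("window_end must be >= window_start")
        self.weights = w

    @property
    def length(self) -> int:
        return self.window_end - self.window_start + 1

    def sign_pattern(self) -> np.ndarray:
        """The snapshot reduced to its {-1, 0, +1} sign matrix."""
        return np.sign(self.weights).astype(np.int8)


def _qualitative_change(current: np.ndarray, state: np.ndarray) -> np.ndarray:
    # Change at a link: entry non-zero AND (never active today, or opposite
    # to the last non-zero entry today). Both reduce to
    # current != 0 and state != current.
    return (current != 0) & (state != current)


def aggregate_day(
    net: SignedTemporalNetwork, mode: str = "global"
) -> list[AggregatedSnapshot]:
    """Collapse one day into qualitative-change windows.

    ``mode='global'`` (default): a change on any single link closes the
    snapshot for the whole network; the triggering period opens the next
    window and its own entries do not re-trigger.  ``mode='per-link'`` is a
    sensitivity variant in which each link is windowed independently; each
    returned snapshot then carries a single link's weight and windows of
    different links may overlap in time.
    """
    if net.n_periods < 1:
        raise ValueError("cannot aggregate an empty period list")
    if mode == "global":
        return _aggregate_global(net)
    if mode == "per-link":
        return _aggregate_per_link(net)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def _aggregate_global(net: SignedTemporalNetwork) -> list[AggregatedSnapshot]:
    P = net.periods
    n_periods, n, _ = P.shape
    snapshots: list[AggregatedSnapshot] = []
    start = 0
    # day-scoped link state: last non-zero valence seen so far today
    state = np.zeros((n, n), dtype=np.int8)
    for t in range(n_periods):
        cur = P[t]
        if t > start and _qualitative_change(cur, state).any():
            snapshots.append(
                AggregatedSnapshot(
                    day=net.day,
                    window_start=start + 1,
                    window_end=t,
                    weights=P[start:t].sum(axis=0, dtype=np.int64),
                )
            )
            start = t
        state = np.where(cur != 0, cur, state).astype(np.int8)
    snapshots.append(
        AggregatedSnapshot(
            day=net.day,
            window_start=start + 1,
            window_end=n_periods,
            weights=P[start:n_periods].sum(axis=0, dtype=np.int64),
        )
    )
    return snapshots


def _aggregate_per_link(net: SignedTemporalNetwork) -> list[AggregatedSnapshot]:
    P = net.periods
    n_periods, n, _ = P.shape
    snapshots: list[AggregatedSnapshot] = []
    for (i, j) in net.roster.dyads():
        series = P[:, i, j]
        start = 0
        state = 0  # day-scoped: last non-zero valence of this link
        for t in range(n_periods):
            s = int(series[t])
            if t > start and s != 0 and s != state:
                snapshots.append(_single_link_snapshot(net, i, j, start, t - 1))
                start = t
            if s != 0:
                state = s
        snapshots.append(_single_link_snapshot(net, i, j, start, n_periods - 1))
    snapshots.sort(key=lambda s: (s.window_start, s.window_end))
    return snapshots


def _single_link_snapshot(net, i, j, start, end) -> AggregatedSnapshot:
    w = np.zeros((net.roster.n, net.roster.n), dtype=np.int64)
    total = int(net.periods[start : end + 1, i, j].sum())
    w[i, j] = w[j, i] = total
    return AggregatedSnapshot(
        day=net.day, window_start=start + 1, window_end=end + 1, weights=w
    )


def aggregate_days(
    networks: Iterable[SignedTemporalNetwork], mode: str = "global"
) -> list[AggregatedSnapshot]:
    """Aggregate each day independently and concatenate the snapshots."""
    out: list[AggregatedSnapshot] = []
    for net in networks:
        out.extend(aggregate_day(net, mode=mode))
    return out


def mean_link_weight(
    snapshots: Sequence[AggregatedSnapshot], sign: int
) -> tuple[float, float]:
    """Mean and population SD of |weight| over non-zero links of one sign.

    Each (snapshot, link) pair with the requested sign contributes one
    observation.  Raises ``ValueError`` when no link of that sign exists,
    since the mean is then undefined (not zero).
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    values: list[int] = []
    for snap in snapshots:
        w = snap.weights
        n = w.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if np.sign(w[i, j]) == sign:
                    values.append(abs(int(w[i, j])))
    if not values:
        raise ValueError(f"no links of sign {sign:+d} in the given snapshots")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def snapshots_to_frame(
    snapshots: Sequence[AggregatedSnapshot], roster
) -> pd.DataFrame:
    """Snapshot export: one row per non-zero link per window."""
    rows = []
    for w_idx, snap in enumerate(snapshots, start=1):
        for (i, j) in roster.dyads():
            weight = int(snap.weights[i, j])
            if weight != 0:
                rows.append(
                    (
                        snap.day,
                        w_idx,
                        snap.window_start,
                        snap.window_end,
                        roster.id_of(i),
                        roster.id_of(j),
                        weight,
                    )
                )
    return pd.DataFrame(
        rows, columns=["day", "window", "start", "end", "id1", "id2", "weight"]
    )
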