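"""Reading and writing event logs, sampling logs and group rosters.

Event and sampling logs are delimited text (comma or tab, sniffed on read);
rosters are YAML (JSON is valid YAML and also accepted).  These are the only
functions in the package that touch raw observation files.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .types import GroupRoster, Individual, InteractionEvent, SamplingRecord

EVENT_COLUMNS = ["day", "period", "actor", "receiver", "valence", "order"]
SAMPLING_COLUMNS = ["day", "period", "id1", "id2", "observed", "synchronous"]

_VALENCE = {"aff": 1, "agg": -1, "+1": 1, "-1": -1, "1": 1}


def _parse_valence(raw) -> int:
    key = str(raw).strip().lower()
    if key not in _VALENCE:
        raise ValueError(
            f"malformed valence {raw!r}: expected one of aff, agg, +1, -1"
        )
    return _VALENCE[key]


def _parse_day(raw):
    # Integer day indices stay integers; anything else is an opaque label.
    try:
        return int(raw)
    except (TypeError, ValueError):
        return str(raw)


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; python engine required for sniffing.
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def read_event_log(path, roster: GroupRoster) -> list[InteractionEvent]:
    """Read a dyadic interaction log, returning events sorted by
    (day, period, order_in_period).

    Raises ``ValueError`` on ids absent from the roster, actor == receiver,
    or malformed valence.
    """
    frame = _read_table(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event log {path} lacks columns {missing}")
    events = []
    for row in frame.itertuples(index=False):
        for who in (row.actor, row.receiver):
            if who not in roster.ids:
                raise ValueError(
                    f"event log {path} mentions unknown individual id {who!r} "
                    f"(group {roster.group!r})"
                )
        events.append(
            InteractionEvent(
                day=_parse_day(row.day),
                period=int(row.period),
                actor=str(row.actor),
                receiver=str(row.receiver),
                valence=_parse_valence(row.valence),
                order_in_period=int(row.order),
            )
        )
    events.sort(key=lambda e: e.sort_key)
    return events


def write_event_log(events: Iterable[InteractionEvent], path) -> None:
    """Write events as CSV, sorted by (day, period, order_in_period).

    ``read_event_log(write_event_log(events))`` is the identity on valid
    event lists.
    """
    rows = sorted(events, key=lambda e: e.sort_key)
    frame = pd.DataFrame(
        [
            (e.day, e.period, e.actor, e.receiver, e.valence, e.order_in_period)
            for e in rows
        ],
        columns=EVENT_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_sampling_log(path, roster: GroupRoster) -> list[SamplingRecord]:
    """Read 0-1 group-sampling records of synchronous swimming."""
    frame = _read_table(path)
    missing = [c for c in SAMPLING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"sampling log {path} lacks columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        for who in (row.id1, row.id2):
            if who not in roster.ids:
                raise ValueError(
                    f"sampling log {path} mentions unknown individual id {who!r}"
                )
        records.append(
            SamplingRecord(
                day=_parse_day(row.day),
                period=int(row.period),
                id1=str(row.id1),
                id2=str(row.id2),
                observed=int(row.observed),
                synchronous=int(row.synchronous),
            )
        )
    return records


def write_sampling_log(records: Iterable[SamplingRecord], path) -> None:
    frame = pd.DataFrame(
        [
            (r.day, r.period, r.id1, r.id2, r.observed, r.synchronous)
            for r in records
        ],
        columns=SAMPLING_COLUMNS,
    )
    frame.to_csv(path, index=False)


def load_roster(path) -> GroupRoster:
    """Load a group roster from a YAML/JSON config.

    Expected shape::

        group: G1
        period_minutes: 3
        members:
          - {id: Estel, sex: F, node_index: 1}
          - ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "members" not in raw:
        raise ValueError(f"roster file {path} must define a 'members' list")
    members = [
        Individual(
            id=str(m["id"]), sex=str(m["sex"]), node_index=int(m["node_index"])
        )
        for m in raw["members"]
    ]
    return GroupRoster(
        group=str(raw.get("group", Path(str(path)).stem)),
        members=members,
        period_minutes=float(raw.get("period_minutes", 3)),
    )


def save_roster(roster: GroupRoster, path) -> None:
    data = {
        "group": roster.group,
        "period_minutes": roster.period_minutes,
        "members": [
            {"id": m.id, "sex": m.sex, "node_index": m.node_index}
            for m in roster.members
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def bin_period(seconds_from_start: float, period_minutes: float = 3.0) -> int:
    """Bin a within-session time offset (seconds) into a 1-based period index.

    Floor division: the first ``period_minutes`` minutes are period 1.  The
    field convention of recording clock times is thereby reduced to the
    integer period index the rest of the package uses.
    """
    if seconds_from_start < 0:
        raise ValueError("time offset must be non-negative")
    return int(math.floor(seconds_from_start / (60.0 * period_minutes))) + 1
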