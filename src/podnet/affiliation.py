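"""Index of affiliative relationships (IA) from 0-1 sampling records.

For a dyad (A, B), IA = X_AB / Y_AB where X_AB counts sampling periods with
synchronous swimming and Y_AB counts sampling periods in which both animals
were observed.  IA lies in [0, 1] and is undefined (NaN, not 0) when a dyad
was never observed together.

Summaries by dyad sex class use the population standard deviation
(divide by n); classes containing a single dyad report a mean only.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .types import GroupRoster, SamplingRecord

IA_COLUMNS = ["group", "id1", "id2", "sex_class", "X", "Y", "IA"]


def compute_ia(
    records: Iterable[SamplingRecord], roster: GroupRoster
) -> pd.DataFrame:
    """Per-dyad X, Y and IA = X/Y over all roster dyads.

    Dyads never observed together get Y = 0 and IA = NaN.  A record with
    synchronous=1 but observed=0 breaches the sampling invariant and raises.
    """
    X: dict[tuple[str, str], int] = {}
    Y: dict[tuple[str, str], int] = {}
    for r in records:
        if r.synchronous == 1 and r.observed == 0:
            raise ValueError(
                f"sampling record {r.id1}-{r.id2} day {r.day!r} period "
                f"{r.period}: synchronous=1 requires observed=1"
            )
        for who in (r.id1, r.id2):
            roster.member(who)  # raises on unknown id
        key = r.dyad
        Y[key] = Y.get(key, 0) + r.observed
        X[key] = X.get(key, 0) + r.synchronous
    rows = []
    for (i, j) in roster.dyads():
        a, b = sorted((roster.id_of(i), roster.id_of(j)))
        x, y = X.get((a, b), 0), Y.get((a, b), 0)
        rows.append(
            (
                roster.group,
                a,
                b,
                roster.sex_class(i, j),
                x,
                y,
                x / y if y > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=IA_COLUMNS)


def sex_class_summary(ia_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and population SD of IA per sex class, per group and pooled.

    ``ia_table`` needs columns ``group, sex_class, IA`` (the output of
    :func:`compute_ia`; concatenate frames from several groups to obtain
    pooled rows).  Dyads with undefined IA are dropped.  Classes with a
    single dyad report the mean with SD = NaN; empty classes are omitted.
    Rows are indexed by (group, sex_class) with group 'total' for the pool.
    """
    table = ia_table.dropna(subset=["IA"])
    if table.empty:
        raise ValueError("no defined IA values to summarize")
    pooled = table.assign(group="total")
    both = pd.concat([table, pooled], ignore_index=True)
    rows = []
    for (group, sc), sub in both.groupby(["group", "sex_class"]):
        vals = sub["IA"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=0)) if len(vals) > 1 else np.nan
        rows.append((group, sc, len(vals), float(vals.mean()), sd))
    out = pd.DataFrame(rows, columns=["group", "sex_class", "n", "mean", "sd"])
    return out.set_index(["group", "sex_class"]).sort_index()


def ia_edge_list(ia_table: pd.DataFrame) -> pd.DataFrame:
    """Weighted affiliative-network edge list (IA as weight), non-zero links."""
    sub = ia_table.dropna(subset=["IA"])
    sub = sub[sub["IA"] > 0]
    return sub[["group", "id1", "id2", "IA"]].rename(columns={"IA": "weight"})
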