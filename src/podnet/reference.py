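"""Published summary data for the two captive bottlenose dolphin groups.

These are the printed observational summaries the package's worked
examples and calibration targets use: the group rosters (G1, four animals;
G2, five animals, three shared), the per-dyad affiliation indices from
synchronous-swimming 0-1 sampling, the post-conflict event-count
breakdowns, and the per-period interaction probabilities that parameterize
the two generative models.  The raw interaction logs were not deposited;
everything downstream of these summaries is either re-derived arithmetic
or simulation.
"""
from __future__ import annotations

import pandas as pd

from .events import ProbabilitySet
from .types import GroupRoster, Individual

_SEX = {
    "Estel": "F",
    "Mateo": "M",
    "Blava": "F",
    "Blue": "M",
    "Stella": "F",
    "Aitamy": "M",
}


def roster_g1() -> GroupRoster:
    """G1: Estel, Mateo, Blava, Blue (network indices 1-4)."""
    order = ["Estel", "Mateo", "Blava", "Blue"]
    return GroupRoster(
        group="G1",
        members=[
            Individual(id=name, sex=_SEX[name], node_index=k)
            for k, name in enumerate(order, start=1)
        ],
    )


def roster_g2() -> GroupRoster:
    """G2: Blava, Mateo, Stella, Blue, Aitamy (network indices 1-5)."""
    order = ["Blava", "Mateo", "Stella", "Blue", "Aitamy"]
    return GroupRoster(
        group="G2",
        members=[
            Individual(id=name, sex=_SEX[name], node_index=k)
            for k, name in enumerate(order, start=1)
        ],
    )


# Per-dyad index of affiliative relationships (X/Y from 0-1 sampling).
_IA_ROWS = [
    ("G1", "Estel", "Mateo", 0.116),
    ("G1", "Estel", "Blava", 0.434),
    ("G1", "Estel", "Blue", 0.079),
    ("G1", "Mateo", "Blava", 0.050),
    ("G1", "Mateo", "Blue", 0.474),
    ("G1", "Blava", "Blue", 0.001),
    ("G2", "Mateo", "Blava", 0.000),
    ("G2", "Mateo", "Blue", 0.525),
    ("G2", "Blava", "Blue", 0.000),
    ("G2", "Blava", "Stella", 0.533),
    ("G2", "Blava", "Aitamy", 0.095),
    ("G2", "Mateo", "Stella", 0.214),
    ("G2", "Mateo", "Aitamy", 0.468),
    ("G2", "Stella", "Blue", 0.152),
    ("G2", "Stella", "Aitamy", 0.069),
    ("G2", "Blue", "Aitamy", 0.461),
]


def observed_ia_table() -> pd.DataFrame:
    """Observed IA per dyad for both groups, with dyad sex classes.

    Columns match the output of :func:`podnet.affiliation.compute_ia`
    closely enough (``group, id1, id2, sex_class, IA``) to feed
    :func:`podnet.affiliation.sex_class_summary` directly.
    """
    rows = []
    for group, a, b, ia in _IA_ROWS:
        a2, b2 = sorted((a, b))
        rows.append(
            (group, a2, b2, "-".join(sorted((_SEX[a], _SEX[b]))), ia)
        )
    return pd.DataFrame(rows, columns=["group", "id1", "id2", "sex_class", "IA"])


#: Observed event totals and post-conflict breakdowns per group:
#: affiliations/aggressions registered, and the reconciliation / new
#: affiliation / new aggression counts over the whole observation span
#: (80 recording days for G1, 23 for G2).
OBSERVED_EVENT_COUNTS = {
    "G1": {
        "total_affiliations": 217,
        "total_aggressions": 133,
        "reconciliations": 41,
        "new_affiliations": 35,
        "new_aggressions": 41,
    },
    "G2": {
        "total_affiliations": 91,
        "total_aggressions": 44,
        "reconciliations": 16,
        "new_affiliations": 17,
        "new_aggressions": 14,
    },
}


def simple_model_probs() -> ProbabilitySet:
    """Per-period probabilities of the memoryless model fitted to G1."""
    return ProbabilitySet(
        period_minutes=3.0,
        p_general_affiliation=0.17,
        p_general_aggression=0.07,
    )


def complex_model_probs() -> ProbabilitySet:
    """Per-period probabilities of the memory-based model fitted to G1."""
    return ProbabilitySet(
        period_minutes=3.0,
        p_spontaneous_affiliation=0.05,
        p_spontaneous_aggression=0.02,
        p_reconciliation=0.04,
        p_new_affiliation=0.01,
        p_new_aggression=0.01,
    )
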