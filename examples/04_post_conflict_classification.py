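"""Classify post-conflict events and convert probabilities to rates.

Every conflict opens a same-day memory on its opponent pair: the first
affiliation between the opponents is a reconciliation, an affiliation
between one opponent and a bystander is a new (third-party) affiliation,
an aggression involving an opponent is a new (redirected) aggression, and
a reconciliation or new affiliation closes the memory.
"""
import numpy as np

from podnet import (
    SignedTemporalNetwork,
    classify_events,
    prob_to_rate,
    spontaneous_counts,
)
from podnet.reference import OBSERVED_EVENT_COUNTS, roster_g1

roster = roster_g1()

# conflict(Estel,Mateo)@1; affiliation(Estel,Blava)@2 -> third-party
# affiliation that closes the memory; affiliation(Estel,Mateo)@4 is then
# spontaneous again
arr = np.zeros((4, 4, 4), dtype=np.int8)
arr[0, 0, 1] = arr[0, 1, 0] = -1
arr[1, 0, 2] = arr[1, 2, 0] = 1
arr[3, 0, 1] = arr[3, 1, 0] = 1
net = SignedTemporalNetwork(roster=roster, day=1, periods=arr)

print("episode classification:")
print(classify_events([net]).to_frame(roster).to_string(index=False))

# Count bookkeeping over the published daily totals: subtracting
# reconciliations and new affiliations from total affiliations (and new
# aggressions from total aggressions) yields the spontaneous counts.
for group, c in OBSERVED_EVENT_COUNTS.items():
    n_sa, n_sg = spontaneous_counts(
        c["total_affiliations"],
        c["total_aggressions"],
        c["reconciliations"],
        c["new_affiliations"],
        c["new_aggressions"],
    )
    print(f"\n{group}: spontaneous affiliations = {n_sa}, spontaneous aggressions = {n_sg}")

# Per-period probabilities convert to per-minute rates via p = 1 - e^(-r dt)
p = 0.04
print(f"\np = {p} per 3-min period  ->  r = {prob_to_rate(p, 3.0):.6f} per minute")
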