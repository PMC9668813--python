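"""Time-aggregate a day at qualitative changes and census its motifs.

A window stays open while every link keeps its valence; it closes just
before any link reverses sign or activates from a silent start.  Link
weights are signed sums: sign = valence, magnitude = duration in periods.
The sign patterns of per-period networks or snapshots are then reduced to
canonical motif classes (node labels are immaterial).
"""
import numpy as np

from podnet import (
    SignedTemporalNetwork,
    aggregate_day,
    canonicalize,
    census_snapshots,
    count_classes,
    encode,
    rank,
)
from podnet.reference import roster_g1

roster = roster_g1()

# one link running (+1, +1, 0, -1): affiliation for two periods, a pause,
# then a conflict -- the textbook aggregation case
arr = np.zeros((4, 4, 4), dtype=np.int8)
for t, s in enumerate([1, 1, 0, -1]):
    arr[t, 0, 1] = arr[t, 1, 0] = s
net = SignedTemporalNetwork(roster=roster, day=1, periods=arr)

for snap in aggregate_day(net):
    print(
        f"window periods {snap.window_start}-{snap.window_end}: "
        f"weight(Estel,Mateo) = {snap.weights[0, 1]:+d}"
    )
# -> +2 over periods 1-3 (the neutral gap is a continuation), then -1.

print("\nsigned tetrad classes under node permutation:", count_classes(4))
print("code of a single +1 link on dyad (1,2):", encode(np.sign(arr[0])))
print("its canonical class:", canonicalize(encode(np.sign(arr[0]))))

hist = census_snapshots(aggregate_day(net))
print("\nsnapshot motif census:")
print(rank(hist).to_string(index=False))
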