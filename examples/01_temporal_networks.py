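"""Build signed temporal networks from a dyadic interaction log.

Constructs one day of per-period signed networks for a four-animal group,
applying the last-observed-interaction rule within each 3-min period, and
counts contacts (non-zero dyad-periods) by dyad sex class.
"""
from podnet import InteractionEvent, build_temporal_network, contact_counts
from podnet.reference import roster_g1

roster = roster_g1()

# A short observed day: Estel and Mateo clash in period 1, the same dyad
# shows both valences in period 2 (the later observation wins), and the
# two males affiliate in period 3.
events = [
    InteractionEvent(day=1, period=1, actor="Estel", receiver="Mateo", valence=-1),
    InteractionEvent(day=1, period=2, actor="Estel", receiver="Mateo", valence=-1, order_in_period=1),
    InteractionEvent(day=1, period=2, actor="Mateo", receiver="Estel", valence=1, order_in_period=2),
    InteractionEvent(day=1, period=3, actor="Mateo", receiver="Blue", valence=1),
]

net = build_temporal_network(events, roster, n_periods=4)
print("link Estel-Mateo per period:", [net.entry(t, "Estel", "Mateo") for t in range(1, 5)])
print("link Mateo-Blue   per period:", [net.entry(t, "Mateo", "Blue") for t in range(1, 5)])

print("\ncontact counts by dyad sex class (one contact = one non-zero dyad-period):")
print(contact_counts([net]))

# The Estel-Mateo link reads (-1, +1, 0, 0): the period-2 entry is +1
# because the affiliative observation came after the aggressive one.
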