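"""Run the two generative interaction models and check their calibration.

The memoryless model assigns one uniformly drawn dyad per period an
affiliation (p = 0.17) or aggression (p = 0.07).  The memory-based model
adds one-period post-conflict effects: reconciliation (0.04), third-party
affiliation (0.01) and redirected aggression (0.01) on top of spontaneous
contacts (0.05 / 0.02).  Both are run at the study shape: 20 periods x 80
days per realization.
"""
import numpy as np

from podnet import SimulationConfig, estimate_probabilities, simulate_complex, simulate_simple
from podnet.reference import complex_model_probs, simple_model_probs

config = SimulationConfig(
    probs=simple_model_probs(), memory_mode="simple", n_realizations=20, seed=0
)
realizations = simulate_simple(config)
flags_aff = np.concatenate(
    [(net.periods == 1).any(axis=(1, 2)) for days in realizations for net in days]
)
flags_agg = np.concatenate(
    [(net.periods == -1).any(axis=(1, 2)) for days in realizations for net in days]
)
print("memoryless model, 20 realizations x 1600 periods:")
print(f"  fraction of periods with an affiliation: {flags_aff.mean():.4f} (generating p = 0.17)")
print(f"  fraction of periods with an aggression:  {flags_agg.mean():.4f} (generating p = 0.07)")

config = SimulationConfig(
    probs=complex_model_probs(), memory_mode="complex", n_realizations=20, seed=0
)
nets = [net for days in simulate_complex(config) for net in days]
est = estimate_probabilities(nets)
print("\nmemory model, probabilities re-estimated from its own output:")
for name in (
    "p_spontaneous_affiliation",
    "p_spontaneous_aggression",
    "p_reconciliation",
    "p_new_affiliation",
    "p_new_aggression",
):
    true = getattr(complex_model_probs(), name)
    print(f"  {name:28s} {getattr(est, name):.4f} (generating {true})")
# Each estimate should sit within Monte-Carlo error of its generating value.
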