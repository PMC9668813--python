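import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from podnet import GroupRoster, Individual, SignedTemporalNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def roster4() -> GroupRoster:
    """Four-animal group shaped like G1 (two females, two males)."""
    return GroupRoster(
        group="G1",
        members=[
            Individual("Estel", "F", 1),
            Individual("Mateo", "M", 2),
            Individual("Blava", "F", 3),
            Individual("Blue", "M", 4),
        ],
    )


@pytest.fixture
def roster2() -> GroupRoster:
    return GroupRoster(
        group="pair",
        members=[Individual("A", "F", 1), Individual("B", "M", 2)],
    )


def make_network(roster, day, link_series: dict) -> SignedTemporalNetwork:
    """Build a network from {(i, j): [sign per period]} (0-based dyads)."""
    n_periods = max(len(v) for v in link_series.values())
    arr = np.zeros((n_periods, roster.n, roster.n), dtype=np.int8)
    for (i, j), series in link_series.items():
        for t, s in enumerate(series):
            arr[t, i, j] = arr[t, j, i] = s
    return SignedTemporalNetwork(roster=roster, day=day, periods=arr)
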