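import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from herdnet import (
    ACTIVITIES,
    Animal,
    GeneratorConfig,
    ObservationRecord,
    ProximityNetwork,
)


@pytest.fixture
def toy_roster():
    return [
        Animal("A", 9.0, 1),
        Animal("B", 3.0, 2),
        Animal("C", 5.5, 1),
        Animal("D", 12.0, 1),
    ]


@pytest.fixture
def toy_records():
    """Period 1: A-B graze together, C grazes alone, D stands."""
    return [
        ObservationRecord(1, "A", "grazing", frozenset({"B"})),
        ObservationRecord(1, "B", "grazing", frozenset({"A"})),
        ObservationRecord(1, "C", "grazing", frozenset()),
        ObservationRecord(1, "D", "standing", frozenset()),
    ]


def network_from_edges(n, edges, activity="grazing", period_id=1, ids=None):
    """Build a ProximityNetwork on n vertices from an edge list of indices."""
    if ids is None:
        ids = tuple(f"v{i}" for i in range(n))
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return ProximityNetwork(
        activity=activity, period_id=period_id, vertex_ids=tuple(ids), adjacency=adj
    )


def random_network(rng, n, p=0.4):
    adj = (rng.random((n, n)) < p).astype(np.int8)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    return ProximityNetwork(
        activity="grazing",
        period_id=1,
        vertex_ids=tuple(f"v{i}" for i in range(n)),
        adjacency=adj,
    )


@pytest.fixture
def small_config():
    """Scaled-down campaign: full herd, 12 periods."""
    return GeneratorConfig(seed=7, n_periods=12)
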