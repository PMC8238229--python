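import numpy as np
import pytest

from deerlaterate.fixtures import FixtureSpec, make_network
from deerlaterate.multilateration import TraceNetwork, run_replicas

#: the fully connected pair is held out of the training network so tests can
#: probe prediction of an unseen restraint
HELDOUT_TRACE_ID = "A:4-A:12"


@pytest.fixture(scope="session")
def small_fixture():
    """A compact planted network: 4 sites, all 6 pairs, short traces.

    Session-scoped so the jit-compiled annealing engine is exercised (and
    compiled) once for the whole suite.
    """
    spec = FixtureSpec(
        n_residues=32,
        label_sites=[4, 12, 20, 28],
        pairs=[(u, v, 1.2, 16.0) for u, v in
               [(4, 20), (4, 28), (12, 28), (12, 20), (20, 28), (4, 12)]],
        noise_sigma=0.01,
        n_candidates=8,
        seed=11,
        planted_distance_window=(15.5, 70.0),
    )
    return make_network(spec)


@pytest.fixture(scope="session")
def small_network(small_fixture):
    """Training network: every trace except the held-out pair."""
    full = small_fixture.to_trace_network()
    train = [t for t in full.traces if t.trace_id != HELDOUT_TRACE_ID]
    return TraceNetwork(traces=train, clouds=small_fixture.clouds)


@pytest.fixture(scope="session")
def small_models(small_network):
    """A few refined replicas on the small network, ranked by AICc."""
    return run_replicas(small_network, 6, base_seed=40)


@pytest.fixture(scope="session")
def small_model(small_models):
    return small_models[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
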