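import numpy as np
import pytest

from behavepi import network, seir


@pytest.fixture(scope="session")
def small_graph() -> network.HyperbolicGraph:
    """A 500-node hyperbolic graph shared by fast SEIR tests."""
    return network.generate_graph(
        n_nodes=500, zeta=1.0, alpha=0.75, target_mean_degree=6.0, seed=42
    )


@pytest.fixture(scope="session")
def fast_params() -> seir.SEIRParams:
    return seir.SEIRParams(horizon=150, n_realizations=8, seed=7)


def two_node_graph() -> network.HyperbolicGraph:
    """A minimal graph with a single edge, for exact transition checks."""
    return network.HyperbolicGraph(
        n_nodes=2,
        zeta=1.0,
        radii=np.zeros(2),
        angles=np.zeros(2),
        edges=np.array([[0, 1]]),
        disk_radius=1.0,
    )
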