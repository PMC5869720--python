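import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sigflow as sf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy():
    """Six-node worked-example network with its two conditions and alpha."""
    net, conds, alpha = sf.make_toy_network()
    return net, conds, alpha


@pytest.fixture
def toy_weights(toy):
    net, _, _ = toy
    return sf.normalize_weights(sf.build_adjacency(net))


def random_weighted_instance(seed, n_nodes=30, density=0.1):
    """A seeded random normalized network with a ternary basal vector."""
    rng = np.random.default_rng(seed)
    net = sf.make_random_network(n_nodes, density=density, seed=rng)
    w = sf.normalize_weights(sf.build_adjacency(net))
    b = sf.BasalActivity(
        rng.choice([-1.0, 0.0, 1.0], size=n_nodes), w.node_order
    )
    return net, w, b
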