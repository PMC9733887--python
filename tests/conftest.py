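import numpy as np
import pytest

from avasamp import (
    GeometryConfig,
    build_connectivity,
    connection_radius,
    place_neurons,
)


@pytest.fixture(scope="session")
def small_topology():
    """400 neurons at the canonical density; K ~ 40 so tests stay fast."""
    cfg = GeometryConfig(n_neurons=400, seed=11)
    pos = place_neurons(cfg)
    d_max = connection_radius(40, cfg.density)
    return build_connectivity(pos, d_max, 300.0, cfg.system_size)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
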