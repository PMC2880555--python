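import numpy as np
import pytest
from dataclasses import replace

import columnet as cn
from columnet.network import ConnectivityParams, NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """A desk-scale structural spec: 2 hypercolumns x 3 minicolumns x 5 pyr."""
    return NetworkSpec(
        n_hypercolumns=2,
        n_minicolumns_per_hc=3,
        n_pyr_per_mc=5,
        connectivity=ConnectivityParams(
            lr_pyr_in_degree=3, rsnp_lr_in_degree=2, n_closest_baskets=2
        ),
    )


@pytest.fixture(scope="session")
def tiny_network(tiny_spec):
    return cn.build_network(tiny_spec)


def passive_cell(cell_type="basket", E_leak=-65.0):
    """A cell of the given morphology with all active channels removed."""
    base = cn.baseline_neuron(cell_type)
    comps = tuple(replace(c, E_leak=E_leak) for c in base.compartments)
    channels = replace(
        base.channels, g_na={}, g_k={}, g_ca={}, g_kca={}, ca_alpha=0.0
    )
    return replace(base, compartments=comps, channels=channels)


@pytest.fixture(scope="session")
def passive_basket():
    return passive_cell("basket")


@pytest.fixture(scope="session")
def passive_pyramidal():
    return passive_cell("pyramidal")
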