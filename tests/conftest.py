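"""Shared fixtures: small networks and deterministic inputs."""

import numpy as np
import pytest

from dexat.neurons import ALIFParams, DEXATParams, LIFParams
from dexat.network import LSNNConfig, init_weights


@pytest.fixture
def lif():
    return LIFParams(delta_t=1.0, tau_m=20.0, v_th_base=1.0, t_refractory=2.0)


@pytest.fixture
def dexat_params(lif):
    return DEXATParams(lif=lif, tau_a1=30.0, tau_a2=300.0, beta1=3.0, beta2=120.0)


@pytest.fixture
def alif_params(lif):
    return ALIFParams(lif=lif, tau_a=300.0, beta=40.0)


@pytest.fixture
def small_config(lif, dexat_params):
    """A 3 LIF + 2 DEXAT network small enough for scalar-loop oracles."""
    return LSNNConfig(
        n_input=4, n_lif=3, n_adaptive=2, n_output=2,
        lif=lif, adaptive=dexat_params, tau_out=20.0, seed=7,
    )


@pytest.fixture
def small_weights(small_config):
    return init_weights(small_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
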