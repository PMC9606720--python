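import numpy as np
import pytest

from neuroforward.adex_spiking import (
    AdExNeuronParams,
    NetworkSpec,
    SynapseParams,
    build_network,
)
from neuroforward.ulfp_kernel import UlfpKernel


@pytest.fixture(scope="session")
def small_network():
    """500-neuron network reused across simulator tests."""
    return build_network(NetworkSpec(n_total=500, p_connect=0.05, seed=42))


@pytest.fixture
def neuron_e():
    return AdExNeuronParams(b_pA=60.0)


@pytest.fixture
def neuron_i():
    return AdExNeuronParams(b_pA=0.0, Delta_T_mV=0.5)


@pytest.fixture
def syn():
    return SynapseParams()


@pytest.fixture
def kernel_e():
    return UlfpKernel(
        depths_um=[-400.0, 0.0, 400.0, 800.0],
        A0_uV=[-0.35, -1.1, 0.4, 1.0],
        lambda_um=200.0,
        sigma_ms=3.15,
        d_ms=10.4,
    )


@pytest.fixture
def kernel_i():
    return UlfpKernel(
        depths_um=[-400.0, 0.0, 400.0, 800.0],
        A0_uV=[0.5, 3.0, 0.2, -0.3],
        lambda_um=200.0,
        sigma_ms=2.1,
        d_ms=10.4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
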