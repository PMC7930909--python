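import numpy as np
import pytest

from eqprop.data import ToyDatasetSpec, make_fixture_net, make_toy_images
from eqprop.model import relax, zeros_state


def steady_state(x, params, arch, steps=400):
    """Free phase from zeros, long enough for double-precision convergence."""
    return relax(x, zeros_state(arch, x.shape[0]), params, arch, steps=steps)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_dataset():
    return make_toy_images(ToyDatasetSpec(seed=0))


@pytest.fixture()
def scalar_net():
    return make_fixture_net("scalar")


@pytest.fixture()
def fc_mse_net():
    return make_fixture_net("fc_small", loss_mode="mse_output_layer", seed=3, n_classes=2)


@pytest.fixture()
def fc_ce_net():
    return make_fixture_net("fc_small", loss_mode="ce_readout", seed=1, n_classes=4)


@pytest.fixture()
def conv_ce_net():
    return make_fixture_net("conv_small", loss_mode="ce_readout", seed=5, n_classes=4)


@pytest.fixture()
def conv_uni_net():
    return make_fixture_net(
        "conv_small", coupling="unidirectional", loss_mode="ce_readout", seed=7, n_classes=4
    )
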