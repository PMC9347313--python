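import numpy as np
import pytest

from semnet.params import ModelParams, reduced_params
from semnet.network import build_network


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def tiny_net():
    """2-HC-per-network model: fast to build and simulate in unit tests."""
    return build_network(reduced_params(n_hc=2), seed=7)


@pytest.fixture(scope="session")
def desk_net():
    """6-HC-per-network model used by the experiment-level tests."""
    return build_network(reduced_params(n_hc=6), seed=1)


N_SEEDS = 10
BASE_SEED = 101


@pytest.fixture(scope="session")
def bcpnn_trials(desk_net):
    """Ten independently seeded item-cued trials under BCPNN (shared)."""
    from semnet.protocol import ExperimentConfig, run_trial

    cfg = ExperimentConfig(variant="item-cued", rule="bcpnn")
    return cfg, [
        run_trial(desk_net, cfg, seed=BASE_SEED + 997 * k, keep_raster=False)
        for k in range(N_SEEDS)
    ]


@pytest.fixture(scope="session")
def stdp_trials(desk_net):
    """Twenty independently seeded item-cued trials under STDP (shared)."""
    from semnet.protocol import ExperimentConfig, run_trial

    cfg = ExperimentConfig(variant="item-cued", rule="stdp")
    return cfg, [
        run_trial(desk_net, cfg, seed=BASE_SEED + 997 * k, keep_raster=False)
        for k in range(2 * N_SEEDS)
    ]
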