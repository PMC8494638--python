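import numpy as np
import pytest

from patchpipe.morph_features import LayerContext
from patchpipe.synthetic import (
    EphysGroundTruth,
    default_protocol,
    simulate_sweep_set,
)


@pytest.fixture(scope="session")
def basic_truth():
    return EphysGroundTruth(
        rmp=-70.0, r_input=100.0, tau=20.0, sag_fraction=0.0, v_threshold=-50.0, seed=0
    )


@pytest.fixture(scope="session")
def sag_truth():
    return EphysGroundTruth(
        rmp=-70.0, r_input=100.0, tau=20.0, sag_fraction=0.2, v_threshold=-50.0, seed=0
    )


@pytest.fixture(scope="session")
def noiseless_sweeps(basic_truth):
    return simulate_sweep_set(
        basic_truth, default_protocol(basic_truth), sampling_rate=25_000.0
    )


@pytest.fixture(scope="session")
def sag_sweeps(sag_truth):
    return simulate_sweep_set(
        sag_truth, default_protocol(sag_truth), sampling_rate=25_000.0
    )


@pytest.fixture(scope="session")
def layer_ctx():
    return LayerContext(
        pia_y=0.0, boundaries={"L1/2": 280.0, "L3/4": 1450.0, "wm": 2400.0}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
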