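import numpy as np
import pytest

from snnpart.emulator import LIFParams
from snnpart.encoders import EncoderConfig
from snnpart.substrate import ChipSpec
from snnpart.synth import SyntheticTaskSpec, make_spike_dataset
from snnpart.training import TrainConfig


@pytest.fixture(scope="session")
def spec() -> ChipSpec:
    return ChipSpec()


@pytest.fixture(scope="session")
def toy_dataset():
    """Separable 3-class blob task, linearly TTFS-encoded."""
    task = SyntheticTaskSpec(n_classes=3, seed=7)
    enc = EncoderConfig(scheme="linear", T=30.0, dt=0.5)
    return make_spike_dataset(task, enc, n_train=96, n_val=48, n_test=48)


@pytest.fixture(scope="session")
def toy_train_setup():
    cfg = TrainConfig(
        hidden_sizes=(24,), lr=5e-3, epochs=50, batch_size=32, beta=5.0,
        init_scale=2.0, seeds=(0,), rate_w=1e-4, sat_w=1e-3, weight_w=1e-3,
        sat_bound=2.0, weight_bound=2.0,
    )
    return cfg, LIFParams(v_th=0.5)
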