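import numpy as np
import pytest

from eegshapes import TrialSet
from eegshapes.model import BlockSpec, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_ts(rng):
    """12 balanced two-class trials, T=8, C=2."""
    trials = rng.standard_normal((12, 8, 2)).astype(np.float32)
    labels = np.tile([0, 1], 6)
    return TrialSet(
        trials=trials,
        labels=labels,
        class_names=("left", "right"),
        sampling_rate_hz=250.0,
        subject_id="T1",
        channel_names=("C3", "C4"),
    )


def small_model_config(shape, T=32, C=3, n_classes=2):
    """A shrunken block schedule for fast functional tests."""
    return ModelConfig(
        n_classes=n_classes,
        input_shape=shape,
        T=T,
        C=C,
        blocks=(
            BlockSpec((5, 1), 4, (3, 1), 4),
            BlockSpec((3, 1), 4, (3, 1), 4),
            BlockSpec((3, 1), 2, (3, 1), 2),
        ),
    )


@pytest.fixture
def small_cfg_factory():
    return small_model_config
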