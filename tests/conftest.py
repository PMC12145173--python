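import numpy as np
import pytest

from moafuse.synthetic import PRESETS, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def smoke_dataset():
    """Tiny 3-class dataset (60 samples, 32x32 images) for structural tests."""
    ds, report = generate_dataset(SynthConfig(seed=11, **PRESETS["smoke"]))
    return ds


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 10 classes x 20 compounds x 4 images."""
    ds, report = generate_dataset(SynthConfig(seed=0))
    return ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
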