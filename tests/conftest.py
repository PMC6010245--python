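import numpy as np
import pytest

from shgfib import synthdata


@pytest.fixture(scope="session")
def stage3_tile():
    """One mid-fibrosis tile with ground truth, shared across tests."""
    return synthdata.generate_tile(synthdata.TileSpec(stage=3, seed=42))


@pytest.fixture(scope="session")
def tiles_by_stage():
    """One tile + truth per stage, fixed seeds."""
    return {
        stage: synthdata.generate_tile(synthdata.TileSpec(stage=stage, seed=11))
        for stage in range(5)
    }


@pytest.fixture(scope="session")
def feature_table():
    """An 83-subject synthetic feature table with a small-noise stage signal."""
    spec = synthdata.SyntheticFeatureSpec(noise_sd=0.02, seed=5)
    return synthdata.generate_feature_table(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
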