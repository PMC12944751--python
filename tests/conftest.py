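import numpy as np
import pytest

from vernstab.synthetic import SyntheticConfig, gen_met_trials


@pytest.fixture(scope="session")
def study_trials():
    """One balanced 12 x 6 x 4 trial at the default variance components."""
    df, truth = gen_met_trials(SyntheticConfig(seed=42))
    return df, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
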