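import numpy as np
import pytest

from genophen import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scenario():
    """Default study conditions with a fixed seed."""
    return synthdata.ScenarioConfig(seed=11)


@pytest.fixture
def tiny_scenario():
    """A three-locus scenario that keeps simulation-heavy tests fast."""
    return synthdata.ScenarioConfig(
        locus_specs=(("locA", 400, 1.0), ("locB", 400, 1.5), ("locC", 400, 0.5)),
        planted_signals=(),
        feature_source_locus="locA",
        n_metabolites=30,
        seed=5,
    )
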