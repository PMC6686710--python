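import pytest

import herdsense as hs


@pytest.fixture(scope="session")
def default_config() -> hs.HerdConfig:
    return hs.HerdConfig(seed=11)


@pytest.fixture(scope="session")
def roster(default_config):
    return hs.generate_herd(default_config)


@pytest.fixture(scope="session")
def sim14(default_config, roster):
    """147 cows, 14 simulated days with default planted events."""
    activity, truths = hs.simulate_activity(roster, 14, default_config)
    return activity, truths


@pytest.fixture(scope="session")
def profiles14(sim14):
    return hs.compute_deviation_table(sim14[0])
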