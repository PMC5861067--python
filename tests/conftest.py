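import pytest

import mozpump as mp


@pytest.fixture(scope="session")
def config():
    return mp.default_config()


@pytest.fixture(scope="session")
def timing():
    return mp.default_timing()


@pytest.fixture(scope="session")
def continuous_result(config, timing):
    return mp.simulate_mode("continuous", config, timing, n_steps=2000)


@pytest.fixture(scope="session")
def burst_result(config, timing):
    return mp.simulate_mode("burst", config, timing, n_steps=2000)


@pytest.fixture(scope="session")
def continuous_summary(continuous_result):
    return mp.summarize(continuous_result)


@pytest.fixture(scope="session")
def burst_summary(burst_result):
    return mp.summarize(burst_result)
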