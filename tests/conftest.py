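import pytest

from quizscreen import default_config, default_personas


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def personas(config):
    return default_personas(config)
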