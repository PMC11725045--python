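import pytest

from respdx.synth import SynthConfig, build_default_profiles, generate_corpus


@pytest.fixture(scope="session")
def default_profiles():
    return build_default_profiles(0.1)


@pytest.fixture(scope="session")
def small_corpus(default_profiles):
    """400-record default corpus shared across tests."""
    config = SynthConfig(n_records=400, seed=20190401)
    train, test = generate_corpus(config, default_profiles)
    return config, train, test
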