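import pytest

from quailscore import default_protocol_config, generate_farm, preset_profile


@pytest.fixture(scope="session")
def config():
    return default_protocol_config()


@pytest.fixture(scope="session")
def enhanced_farm():
    return generate_farm(preset_profile("enhanced"), seed=11)


@pytest.fixture(scope="session")
def study_farm():
    return generate_farm(preset_profile("study_like"), seed=7)
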