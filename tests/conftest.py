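import pytest
from hypothesis import settings

from mirspec.synthetic import SyntheticConfig, generate_fixture_set

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    """Synthetic bundle with planted avoidance + Λ preference, two older
    age classes carrying a stronger signal."""
    out = tmp_path_factory.mktemp("planted")
    config = SyntheticConfig(bias_profile="avoidance_lambda", strength=0.7, seed=3)
    paths = generate_fixture_set(config, out)
    return config, paths


@pytest.fixture(scope="session")
def independence_bundle(tmp_path_factory):
    """Synthetic bundle with targeting independent of expression."""
    out = tmp_path_factory.mktemp("independent")
    config = SyntheticConfig(bias_profile="independence", seed=11)
    paths = generate_fixture_set(config, out)
    return config, paths
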