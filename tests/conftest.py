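import pytest

from somaticmz import load_discovery_frame, load_discovery_snvs, pair_with_clean_normal


@pytest.fixture(scope="session")
def discovery_frame():
    return load_discovery_frame()


@pytest.fixture(scope="session")
def discovery_snvs():
    return load_discovery_snvs()


@pytest.fixture()
def discovery_pairs(discovery_snvs):
    return [pair_with_clean_normal(obs) for obs in discovery_snvs]
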