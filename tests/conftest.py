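import pytest

from genefamkit.domain_scan import load_bundled_profile
from genefamkit.family_classify import load_reference_domains
from genefamkit.synthetic_data import SimulationConfig, generate_family_genome


@pytest.fixture(scope="session")
def ap2_profile():
    return load_bundled_profile("AP2")


@pytest.fixture(scope="session")
def b3_profile():
    return load_bundled_profile("B3")


@pytest.fixture(scope="session")
def references():
    return load_reference_domains()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        counts={"ERF": 8, "DREB": 4, "DRF": 2, "AP2": 3, "RAV": 3, "SOLOIST": 3,
                "NONE": 4},
        n_duplicate_pairs=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_family_genome(small_config)
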