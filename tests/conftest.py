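import pytest

from spudlca.energy import ScenarioConfig
from spudlca.synthetic import (
    GeneratorConfig,
    gen_characterization_model,
    gen_pedigree_scores,
    load_paper_fixtures,
)


@pytest.fixture(scope="session")
def bundle():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def rw_us(bundle):
    return bundle.profile("RW-US", 0)


@pytest.fixture(scope="session")
def model():
    return gen_characterization_model(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def pedigree():
    return gen_pedigree_scores(GeneratorConfig(seed=7))


@pytest.fixture()
def scenario():
    return ScenarioConfig()
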