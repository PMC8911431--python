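import pytest

from degmeta import datasets, pair_homologs


@pytest.fixture(scope="session")
def seed_degs():
    return datasets.load_seed_degs()


@pytest.fixture(scope="session")
def partner_degs():
    return datasets.load_hypertension_family_degs()


@pytest.fixture(scope="session")
def homolog_map():
    return datasets.load_homolog_map()


@pytest.fixture(scope="session")
def family_pairs(seed_degs, partner_degs, homolog_map):
    """The curated hemoglobin + beta-protocadherin homolog pairs."""
    return pair_homologs(seed_degs, partner_degs, homolog_map)


@pytest.fixture(scope="session")
def published_sign_counts():
    return datasets.load_published_sign_counts()


@pytest.fixture(scope="session")
def qpcr_measurements():
    return datasets.load_qpcr_measurements()
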