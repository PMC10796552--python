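import pytest

from drugnorm import bundled_opioid_lexicon, bundled_approved_list
from drugnorm.fixtures import variant_frequency_table
from drugnorm.normalize import Matcher


@pytest.fixture(scope="session")
def opioid_lexicon():
    return bundled_opioid_lexicon()


@pytest.fixture(scope="session")
def opioid_matcher(opioid_lexicon):
    return Matcher(opioid_lexicon)


@pytest.fixture(scope="session")
def approved_list():
    return bundled_approved_list()


@pytest.fixture(scope="session")
def aspirin_oxycodone_freqs():
    """Ranked verbatim name frequencies for concept 214256 (total 110)."""
    return variant_frequency_table(214256)


@pytest.fixture(scope="session")
def methadone_hcl_freqs():
    """Ranked verbatim name frequencies for concept 218337 (total 14,717)."""
    return variant_frequency_table(218337)
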