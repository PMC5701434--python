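import pytest

from exptrait import (
    InstrumentSpec,
    ItemSpec,
    fixture_prevalence_table,
    generate_prevalence_table,
    make_cisr_like_instrument,
)


@pytest.fixture(scope="session")
def cisr():
    return make_cisr_like_instrument()


@pytest.fixture(scope="session")
def fixture_table(cisr):
    return fixture_prevalence_table(cisr)


@pytest.fixture(scope="session")
def toy_instrument():
    """Small 10-question instrument for oracle-vs-simulator comparisons."""
    return InstrumentSpec((ItemSpec("item A", 5), ItemSpec("item B", 5)))


@pytest.fixture(scope="session")
def toy_table(toy_instrument):
    return generate_prevalence_table(toy_instrument, seed=11)
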