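import pytest

from splicedx.synthetic_data import (
    CohortConfig,
    fixture_worked_examples,
    generate_cohort,
    make_transcript,
)


@pytest.fixture(scope="session")
def toy_plus():
    """3-exon plus-strand transcript: exons 100/60/90, introns 50/40."""
    return make_transcript("TOY+", "chrT", "+", [100, 60, 90], [50, 40])


@pytest.fixture(scope="session")
def toy_minus():
    """Same exon/intron lengths on the minus strand."""
    return make_transcript("TOY-", "chrT", "-", [100, 60, 90], [50, 40])


@pytest.fixture(scope="session", params=["+", "-"], ids=["plus", "minus"])
def toy_both(request, toy_plus, toy_minus):
    return toy_plus if request.param == "+" else toy_minus


@pytest.fixture(scope="session")
def worked_cases():
    return {fx.name: fx for fx in fixture_worked_examples()}


@pytest.fixture(scope="session")
def small_bundle():
    """One default-size synthetic cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))
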