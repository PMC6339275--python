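import pytest

from oncotier import (
    classify_cohort,
    cohort_level_census,
    cross_tabulate,
    fixture_records,
    load_knowledgebase,
    off_label_uptake,
    pair_records,
)


@pytest.fixture(scope="session")
def kb():
    return load_knowledgebase()


@pytest.fixture(scope="session")
def fixture_cohort():
    return fixture_records()


@pytest.fixture(scope="session")
def classified(kb, fixture_cohort):
    return classify_cohort(fixture_cohort, kb)


@pytest.fixture(scope="session")
def census(classified):
    return cohort_level_census(classified)


@pytest.fixture(scope="session")
def pairs(classified, fixture_cohort):
    return pair_records(classified, fixture_cohort)


@pytest.fixture(scope="session")
def agreement_table(pairs):
    return cross_tabulate(pairs)


@pytest.fixture(scope="session")
def off_label(pairs):
    return off_label_uptake(pairs)
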