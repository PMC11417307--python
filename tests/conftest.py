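import datetime as dt

import pytest

from pvtls import (
    DrugEntry,
    DrugRole,
    ReactionEntry,
    RegimenQuery,
    Report,
    ReporterType,
    Sex,
    TermSet,
    builtin_term_set,
    make_case_series_fixture,
)


def mk_report(
    i,
    drugs=(),
    reactions=(),
    case_id=None,
    version=1,
    year=2020,
    quarter=1,
    sex=Sex.UNKNOWN,
    age=None,
    reporter=ReporterType.UNKNOWN,
    outcomes=(),
    preexisting=(),
):
    """Small hand-built report; drugs/reactions are names or entries."""
    return Report(
        report_id=f"r{i}",
        case_id=case_id or f"c{i}",
        case_version=version,
        report_year=year,
        report_quarter=quarter,
        reporter_type=reporter,
        age_years=age,
        sex=sex,
        outcomes=frozenset(outcomes),
        drugs=[d if isinstance(d, DrugEntry) else DrugEntry(d) for d in drugs],
        reactions=[
            r if isinstance(r, ReactionEntry) else ReactionEntry(r) for r in reactions
        ],
        preexisting_terms=frozenset(preexisting),
    )


@pytest.fixture(scope="session")
def tls_terms():
    return builtin_term_set("tls_pt_narrow")


@pytest.fixture(scope="session")
def smq_terms():
    return builtin_term_set("tls_smq_broad_synthetic")


@pytest.fixture(scope="session")
def enc_bin_query():
    return RegimenQuery(
        name="encorafenib+binimetinib",
        required_drugs=frozenset({"encorafenib", "binimetinib"}),
    )


@pytest.fixture(scope="session")
def case_series():
    return make_case_series_fixture()
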