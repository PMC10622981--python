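import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from pvror.casedef import load_default_case_query, resolve_query
from pvror.reports import Report, ReportSet
from pvror.vocab import (
    load_default_drug_dictionary,
    load_default_term_dictionary,
)

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def term_dict():
    return load_default_term_dictionary()


@pytest.fixture(scope="session")
def drug_dict():
    return load_default_drug_dictionary()


@pytest.fixture(scope="session")
def case_set(term_dict):
    return resolve_query(load_default_case_query(), term_dict)


@pytest.fixture(scope="session")
def domain_map(term_dict):
    return term_dict.domain_map


def _mk_report(
    report_id,
    date="2015-06-01",
    sex="female",
    age=60,
    events=("PT0030",),
    drugs=(("D01", "suspect"),),
    region="Europe",
    reporter="healthcare_professional",
    serious=False,
    **kw,
):
    return Report(
        report_id=str(report_id),
        date=dt.date.fromisoformat(date),
        sex=sex,
        age_years=age,
        region=region,
        reporter=reporter,
        serious=serious,
        drugs=tuple(drugs),
        events=tuple(events),
        **kw,
    )


@pytest.fixture(scope="session")
def mk_report():
    """Factory for hand-built reports with sensible defaults."""
    return _mk_report


@pytest.fixture(scope="session")
def mk_report_set():
    def build(reports, date_range=None):
        return ReportSet.from_reports(reports, date_range=date_range)

    return build
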