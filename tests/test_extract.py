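"""Cohort filtering, flow accounting, and 2x2 table construction."""

import datetime as dt

import numpy as np
import pytest

from pvror.casedef import label_reports
from pvror.extract import (
    ALL_ROLES,
    CohortFilter,
    apply_filters,
    align_labels,
    build_table,
    first_report_date,
)

WINDOW = (dt.date(2014, 1, 1), dt.date(2022, 3, 16))


def _labels(rs, term_dict, case_set, domain_map):
    return label_reports(rs, case_set, domain_map)


def test_window_boundaries_inclusive(mk_report, mk_report_set):
    rs = mk_report_set(
        [
            mk_report(1, date="2013-12-31"),
            mk_report(2, date="2014-01-01"),
            mk_report(3, date="2022-03-16"),
            mk_report(4, date="2022-03-17"),
        ]
    )
    cohort, flow = apply_filters(rs, CohortFilter(window=WINDOW))
    kept = set(cohort.reports["report_id"])
    assert kept == {"2", "3"}
    assert dict(flow.removed)["outside_window"] == 2
    flow.check()


def test_hand_counted_flow(mk_report, mk_report_set):
    """10 reports, 3 male, 2 missing-age: cohort of 5, flow 10-3-2."""
    reports = (
        [mk_report(i, sex="male") for i in range(3)]
        + [mk_report(i + 3, age=None) for i in range(2)]
        + [mk_report(i + 5) for i in range(5)]
    )
    rs = mk_report_set(reports)
    cohort, flow = apply_filters(rs, CohortFilter(window=WINDOW, require_age=True))
    assert flow.total_in == 10
    assert cohort.n_reports == 5
    assert dict(flow.removed)["sex!=female"] == 3
    assert dict(flow.removed)["missing_age"] == 2
    flow.check()


def test_no_restriction_is_identity(mk_report, mk_report_set):
    rs = mk_report_set([mk_report(i) for i in range(6)])
    cohort, flow = apply_filters(rs, CohortFilter(window=WINDOW))
    assert cohort.n_reports == 6
    assert all(n == 0 for _, n in flow.removed)


def test_filter_composition_order_independent(mk_report, mk_report_set):
    reports = [
        mk_report(1, sex="male", age=None),
        mk_report(2, age=None),
        mk_report(3, date="2010-05-01"),
        mk_report(4),
        mk_report(5, reporter="non_hcp"),
    ]
    rs = mk_report_set(reports)
    full = CohortFilter(
        window=WINDOW, require_age=True, reporter_restrict="healthcare_professional"
    )
    one_pass, _ = apply_filters(rs, full)
    step1, _ = apply_filters(rs, CohortFilter(window=WINDOW, require_age=True))
    two_pass, _ = apply_filters(
        step1,
        CohortFilter(window=WINDOW, reporter_restrict="healthcare_professional"),
    )
    assert list(one_pass.reports["report_id"]) == list(two_pass.reports["report_id"])


EIGHT = [
    # 4 exposed to D01, 3 of them cases; 4 unexposed, 1 case
    ("1", ("D01", "suspect"), ("PT0001",)),
    ("2", ("D01", "suspect"), ("PT0017",)),
    ("3", ("D01", "concomitant"), ("PT0006",)),
    ("4", ("D01", "suspect"), ("PT0030",)),
    ("5", ("D15", "concomitant"), ("PT0001",)),
    ("6", ("D15", "concomitant"), ("PT0030",)),
    ("7", ("D15", "concomitant"), ("PT0035",)),
    ("8", ("D15", "concomitant"), ("PT0038",)),
]


@pytest.fixture()
def eight_report_set(mk_report, mk_report_set):
    return mk_report_set(
        [mk_report(rid, drugs=(drug,), events=ev) for rid, drug, ev in EIGHT]
    )


def test_hand_counted_table(eight_report_set, term_dict, case_set, domain_map):
    labels = _labels(eight_report_set, term_dict, case_set, domain_map)
    t = build_table(eight_report_set, "D01", labels)
    assert (t.a, t.b, t.c, t.d) == (3, 1, 1, 3)
    assert t.n_observed == 3 and t.n_drug_total == 4
    assert t.total == 8


def test_all_roles_accepted_by_default(eight_report_set, term_dict, case_set, domain_map):
    """Concomitant-only exposure counts when all roles are accepted, and
    drops when attribution is narrowed to suspect reports."""
    labels = _labels(eight_report_set, term_dict, case_set, domain_map)
    t_all = build_table(eight_report_set, "D01", labels, roles=ALL_ROLES)
    t_suspect = build_table(
        eight_report_set, "D01", labels, roles=frozenset({"suspect"})
    )
    assert (t_all.a, t_all.b) == (3, 1)
    assert (t_suspect.a, t_suspect.b) == (2, 1)  # report 3 no longer exposed


def test_absent_drug_table(eight_report_set, term_dict, case_set, domain_map):
    labels = _labels(eight_report_set, term_dict, case_set, domain_map)
    t = build_table(eight_report_set, "D09", labels)
    assert t.a == 0 and t.b == 0
    assert t.c + t.d == 8


def test_cells_partition_cohort(term_dict, drug_dict, case_set, domain_map):
    from pvror.synth import default_config, generate_reports

    rs = generate_reports(default_config(n_reports=5000, seed=4), term_dict, drug_dict)
    cohort, _ = apply_filters(rs, CohortFilter(window=WINDOW, require_age=True))
    labels = align_labels(label_reports(rs, case_set, domain_map), cohort)
    for drug_id in ("D01", "D07"):
        t = build_table(cohort, drug_id, labels)
        assert t.total == cohort.n_reports
        pooled = np.array([t.a, t.b, t.c, t.d])
        by_strata = np.array([v for v in t.strata.values()]).sum(axis=0)
        assert (pooled == by_strata).all()


def test_first_report_date(mk_report, mk_report_set, drug_dict):
    rs = mk_report_set(
        [
            mk_report(1, date="2015-03-01", drugs=(("D01", "suspect"),)),
            mk_report(2, date="2014-06-15", drugs=(("D01", "concomitant"),)),
            mk_report(3, date="2016-01-10", drugs=(("D07", "suspect"),)),
            mk_report(4, date="2015-08-01", drugs=(("D08", "suspect"),)),
        ]
    )
    assert first_report_date(rs, "D01") == dt.date(2014, 6, 15)
    assert first_report_date(rs, "iCDK46", drug_dict) == dt.date(2015, 8, 1)
    assert first_report_date(rs, "D02") is None


def test_oncology_noncase_restriction(mk_report, mk_report_set, term_dict, drug_dict,
                                      case_set, domain_map):
    """Cases are kept regardless; non-cases survive only with an oncology
    drug on board."""
    reports = [
        mk_report(1, events=("PT0001",), drugs=(("D01", "suspect"),)),       # case, ET
        mk_report(2, events=("PT0001",), drugs=(("D15", "concomitant"),)),   # case, no onco
        mk_report(3, events=("PT0030",), drugs=(("D10", "suspect"),)),       # non-case, onco
        mk_report(4, events=("PT0030",), drugs=(("D15", "concomitant"),)),   # non-case, no onco
    ]
    rs = mk_report_set(reports)
    labels = label_reports(rs, case_set, domain_map)
    cohort, flow = apply_filters(
        rs,
        CohortFilter(window=WINDOW, noncase_restrict_oncology=True),
        labels=labels,
        drug_dict=drug_dict,
    )
    assert set(cohort.reports["report_id"]) == {"1", "2", "3"}
    assert dict(flow.removed)["noncase_without_oncology_drug"] == 1


def test_oncology_restriction_requires_labels(mk_report, mk_report_set):
    rs = mk_report_set([mk_report(1)])
    with pytest.raises(ValueError, match="labels"):
        apply_filters(rs, CohortFilter(noncase_restrict_oncology=True))
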