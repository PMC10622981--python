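"""Primary analysis, DSM-5 subgroups, and the four sensitivity variants."""

import datetime as dt

import pytest

from pvror.analyses import (
    StudyPlan,
    VariantSkipped,
    prepare_cohort,
    run_domain_subgroups,
    run_primary,
    run_sensitivity,
)
from pvror.disprop import results_frame
from pvror.synth import default_config, generate_reports


@pytest.fixture(scope="module")
def plan(drug_dict):
    return StudyPlan.default(drug_dict)


@pytest.fixture(scope="module")
def demo_db(term_dict, drug_dict):
    return generate_reports(
        default_config(n_reports=40_000, seed=5), term_dict, drug_dict
    )


def test_primary_keeps_suppressed_rows(demo_db, plan, term_dict, drug_dict):
    """Every study drug yields a row; rare drugs come back not-computed
    (never dropped)."""
    res = run_primary(demo_db, plan, term_dict, drug_dict)
    assert len(res) == len(plan.drug_ids)
    by_name = {drug_dict[r.drug_id].name: r for r in res}
    tore = by_name["toremifene"]
    assert not tore.computed and "fewer than" in tore.reason
    # diagnostics carry crude and MH companions
    for r in res:
        assert "crude" in r.diagnostics and "mantel_haenszel" in r.diagnostics


def test_domain_subgroup_counts_partition(mk_report, mk_report_set, plan,
                                          term_dict, drug_dict):
    """With single-domain case reports the per-domain observed counts
    partition the composite count; a multi-domain report breaks the
    partition (sums exceed the composite)."""
    base = [
        mk_report(1, events=("PT0001",), drugs=(("D01", "suspect"),)),  # memory
        mk_report(2, events=("PT0006",), drugs=(("D01", "suspect"),)),  # language
        mk_report(3, events=("PT0030",), drugs=(("D01", "suspect"),)),
        mk_report(4, events=("PT0030",), drugs=(("D15", "concomitant"),)),
    ]
    rs = mk_report_set(base)
    cohort, labels, _ = prepare_cohort(rs, plan, term_dict, drug_dict)
    from pvror.casedef import DOMAIN_COLUMNS
    from pvror.extract import build_table

    nci = build_table(cohort, "D01", labels)
    per_domain = [
        build_table(cohort, "D01", labels, outcome_col=col, outcome=dom)
        for dom, col in DOMAIN_COLUMNS.items()
    ]
    assert nci.n_observed == 2
    assert sum(t.n_observed for t in per_domain) == nci.n_observed

    multi = base + [
        mk_report(5, events=("PT0001", "PT0006"), drugs=(("D01", "suspect"),))
    ]
    rs2 = mk_report_set(multi)
    cohort2, labels2, _ = prepare_cohort(rs2, plan, term_dict, drug_dict)
    nci2 = build_table(cohort2, "D01", labels2)
    per_domain2 = [
        build_table(cohort2, "D01", labels2, outcome_col=col, outcome=dom)
        for dom, col in DOMAIN_COLUMNS.items()
    ]
    assert nci2.n_observed == 3
    assert sum(t.n_observed for t in per_domain2) == 4  # one report counted twice


def test_report_level_dedup_invariance(mk_report, mk_report_set, plan,
                                       term_dict, drug_dict):
    """Adding a second NCI PT to an already-case report changes no
    downstream 2x2 cell."""
    from pvror.extract import build_table

    base = [
        mk_report(1, events=("PT0001",), drugs=(("D01", "suspect"),)),
        mk_report(2, events=("PT0030",), drugs=(("D01", "suspect"),)),
        mk_report(3, events=("PT0001",), drugs=(("D15", "concomitant"),)),
        mk_report(4, events=("PT0030",), drugs=(("D15", "concomitant"),)),
    ]
    dup = [
        mk_report(1, events=("PT0001", "PT0002"), drugs=(("D01", "suspect"),)),
    ] + base[1:]
    t1 = [None, None]
    for i, reports in enumerate((base, dup)):
        rs = mk_report_set(reports)
        cohort, labels, _ = prepare_cohort(rs, plan, term_dict, drug_dict)
        t1[i] = build_table(cohort, "D01", labels)
    assert t1[0].strata == t1[1].strata


def test_subgroups_shape_and_single_domain_drug(demo_db, plan, term_dict, drug_dict):
    res = run_domain_subgroups(demo_db, plan, term_dict, drug_dict)
    assert len(res) == len(plan.drug_ids) * 6
    # social cognition is rare by construction: mostly not calculable
    sc = [r for r in res if r.outcome == "social cognition"]
    assert any(not r.computed for r in sc)


def test_s1_only_shrinks_noncase_cells(demo_db, plan, term_dict, drug_dict):
    """Restricting non-cases to oncology reports leaves a and b untouched
    for every drug of interest and shrinks c + d."""
    prim = run_primary(demo_db, plan, term_dict, drug_dict)
    s1 = run_sensitivity(demo_db, plan, "S1", term_dict, drug_dict)
    for p, s in zip(prim, s1):
        tp = p.diagnostics["table"]
        ts = s.diagnostics["table"]
        assert ts.a == tp.a
        # b may only change for non-oncology drugs; study drugs are all
        # oncology classes, so exposed non-cases are retained too
        assert ts.b == tp.b
        assert ts.c <= tp.c and ts.d < tp.d


def test_s2_restricts_to_hcp(demo_db, plan, term_dict, drug_dict):
    from dataclasses import replace

    filt = replace(plan.primary_filter, reporter_restrict="healthcare_professional")
    cohort, _, flow = prepare_cohort(demo_db, plan, term_dict, drug_dict, filt=filt)
    assert (cohort.reports["reporter"] == "healthcare_professional").all()
    assert dict(flow.removed)["reporter!=healthcare_professional"] > 0


def test_s4_identity_when_nothing_flagged(plan, term_dict, drug_dict):
    """With zero flagged reports the confounder-exclusion variant equals
    the primary analysis row for row."""
    cfg = default_config(
        n_reports=20_000, seed=8, comorbidity_prob=0.0, cotreatment_prob=0.0
    )
    rs = generate_reports(cfg, term_dict, drug_dict)
    prim = results_frame(run_primary(rs, plan, term_dict, drug_dict))
    s4 = results_frame(run_sensitivity(rs, plan, "S4", term_dict, drug_dict))
    assert prim.equals(s4)


def test_s3_pre_icdk_window(mk_report, mk_report_set, plan, term_dict, drug_dict):
    """The per-ET window is closed at the ET's first report and open at
    the first CDK4/6-inhibitor report."""
    reports = [
        mk_report(1, date="2014-03-01", events=("PT0001",), drugs=(("D01", "suspect"),)),
        mk_report(2, date="2015-12-31", events=("PT0030",), drugs=(("D01", "suspect"),)),
        mk_report(3, date="2016-01-01", events=("PT0030",), drugs=(("D01", "suspect"),)),
        mk_report(4, date="2016-01-01", events=("PT0039",), drugs=(("D07", "suspect"),)),
        mk_report(5, date="2015-06-15", events=("PT0030",), drugs=(("D15", "concomitant"),)),
    ]
    rs = mk_report_set(reports)
    res = run_sensitivity(rs, plan, "S3", term_dict, drug_dict)
    by_drug = {r.drug_id: r for r in res}
    # only ET drugs are analysed in this variant
    assert set(by_drug) == {"D01", "D02", "D03", "D04", "D05", "D06"}
    d01 = by_drug["D01"]
    t = d01.diagnostics.get("table")
    # reports 1, 2 and 5 fall in [2014-03-01, 2016-01-01); 3 and 4 do not
    assert t.total == 3
    assert t.n_drug_total == 2  # reports 1 and 2
    # ETs never reported in the window come back as explicit no-window rows
    assert not by_drug["D02"].computed


def test_s3_skipped_without_icdk(mk_report, mk_report_set, plan, term_dict, drug_dict):
    rs = mk_report_set([mk_report(1, drugs=(("D01", "suspect"),))])
    with pytest.raises(VariantSkipped, match="CDK4/6"):
        run_sensitivity(rs, plan, "S3", term_dict, drug_dict)


def test_sensitivity_flows_reconcile(demo_db, plan, term_dict, drug_dict):
    """Filter-type variants remove reports from the primary cohort:
    primary remaining = variant remaining + extra removals."""
    from dataclasses import replace

    _, _, flow_p = prepare_cohort(demo_db, plan, term_dict, drug_dict)
    for mod in (
        {"reporter_restrict": "healthcare_professional"},
        {"exclude_confounded": True},
        {"noncase_restrict_oncology": True},
    ):
        filt = replace(plan.primary_filter, **mod)
        _, _, flow_v = prepare_cohort(demo_db, plan, term_dict, drug_dict, filt=filt)
        flow_v.check()
        extra = sum(n for _, n in flow_v.removed) - sum(n for _, n in flow_p.removed)
        assert flow_v.remaining == flow_p.remaining - extra
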