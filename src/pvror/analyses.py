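"""Study orchestration: primary analysis, DSM-5 subgroups, sensitivities.

The primary analysis computes, for each study drug, the logistic
age-adjusted ROR for the composite outcome on the female, study-window,
known-age cohort, with the crude and Mantel-Haenszel estimates attached as
diagnostics and the >=5-report / lower-bound rules applied.

Subgroup analyses repeat this per DSM-5 neurocognitive domain (cases =
reports with at least one PT mapped to that domain; non-cases = all other
cohort reports, including cases of other domains).

Four sensitivity variants each derive from the primary filter by a single
declared modification:

* S1 - non-cases restricted to oncology reports (cases untouched);
* S2 - reports from healthcare professionals only;
* S3 - per endocrine-therapy drug, the window runs from that drug's first
  report to (exclusive) the first CDK4/6-inhibitor report;
* S4 - reports flagged with known NCI co-illness/co-treatment excluded.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .casedef import (
    CaseQuery,
    DOMAIN_COLUMNS,
    label_reports,
    load_default_case_query,
    resolve_query,
)
from .disprop import (
    MIN_REPORTS_DEFAULT,
    RorResult,
    apply_signal_rules,
    crude_ror,
    lr_from_table,
    mh_adjusted_ror,
)
from .extract import (
    ALL_ROLES,
    CohortFilter,
    FlowCounts,
    align_labels,
    apply_filters,
    build_table,
    first_report_date,
)
from .reports import ReportSet
from .vocab import (
    DSM5_DOMAINS,
    ET_CLASSES,
    DrugDictionary,
    TermDictionary,
    iter_study_drug_ids,
)

SENSITIVITY_VARIANTS = ("S1", "S2", "S3", "S4")


class VariantSkipped(RuntimeError):
    """A sensitivity variant cannot run on this database (with reason)."""


@dataclass
class StudyPlan:
    """Declarative description of the whole study."""

    drug_ids: list[str]
    query: CaseQuery
    primary_filter: CohortFilter
    domains: tuple[str, ...] = DSM5_DOMAINS
    min_count: int = MIN_REPORTS_DEFAULT

    @classmethod
    def default(cls, drug_dict: DrugDictionary) -> "StudyPlan":
        return cls(
            drug_ids=iter_study_drug_ids(drug_dict),
            query=load_default_case_query(),
            primary_filter=CohortFilter(require_age=True),
        )

    @classmethod
    def from_yaml(cls, path, drug_dict: DrugDictionary) -> "StudyPlan":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        plan = cls.default(drug_dict)
        if "drug_ids" in obj:
            plan.drug_ids = list(obj["drug_ids"])
        if "min_count" in obj:
            plan.min_count = int(obj["min_count"])
        filt = {}
        if "window" in obj:
            filt["window"] = tuple(dt.date.fromisoformat(d) for d in obj["window"])
        if "sex" in obj:
            filt["sex"] = obj["sex"]
        if "roles" in obj:
            filt["roles"] = frozenset(obj["roles"])
        if filt:
            plan.primary_filter = replace(plan.primary_filter, **filt)
        return plan


def prepare_cohort(
    report_set: ReportSet,
    plan: StudyPlan,
    term_dict: TermDictionary,
    drug_dict: DrugDictionary,
    filt: CohortFilter | None = None,
) -> tuple[ReportSet, pd.DataFrame, FlowCounts]:
    """Label the full database, apply cohort filters, align labels.

    Returns (cohort, aligned labels, flow counts).  Labelling precedes
    filtering so that case status is available to case-aware filters.
    """
    filt = filt or plan.primary_filter
    case_set = resolve_query(plan.query, term_dict)
    labels = label_reports(report_set, case_set, term_dict.domain_map)
    cohort, flow = apply_filters(report_set, filt, labels=labels, drug_dict=drug_dict)
    return cohort, align_labels(labels, cohort), flow


def _analyze_drug(
    cohort: ReportSet,
    labels: pd.DataFrame,
    drug_id: str,
    roles,
    min_count: int,
    outcome_col: str = "is_case",
    outcome: str = "NCI",
) -> RorResult:
    table = build_table(
        cohort, drug_id, labels, roles=roles, outcome_col=outcome_col, outcome=outcome
    )
    adjusted = apply_signal_rules(lr_from_table(table), min_count=min_count)
    adjusted.diagnostics["crude"] = apply_signal_rules(
        crude_ror(table), min_count=min_count
    )
    adjusted.diagnostics["mantel_haenszel"] = apply_signal_rules(
        mh_adjusted_ror(table), min_count=min_count
    )
    adjusted.diagnostics["table"] = table
    return adjusted


def run_primary(
    report_set: ReportSet,
    plan: StudyPlan,
    term_dict: TermDictionary,
    drug_dict: DrugDictionary,
) -> list[RorResult]:
    """One age-adjusted result per study drug, signal rules applied.

    Drugs below the minimum report count are returned as not-computed
    rows, never dropped.
    """
    cohort, labels, _ = prepare_cohort(report_set, plan, term_dict, drug_dict)
    roles = plan.primary_filter.roles
    return [
        _analyze_drug(cohort, labels, d, roles, plan.min_count)
        for d in plan.drug_ids
    ]


def run_domain_subgroups(
    report_set: ReportSet,
    plan: StudyPlan,
    term_dict: TermDictionary,
    drug_dict: DrugDictionary,
) -> list[RorResult]:
    """Adjusted results for every (drug, DSM-5 domain) pair.

    For domain D, cases are cohort reports with >=1 PT mapped to D and
    non-cases are all other cohort reports (cases of other domains
    included).  Pairs under the minimum count come back not-calculable.
    """
    cohort, labels, _ = prepare_cohort(report_set, plan, term_dict, drug_dict)
    roles = plan.primary_filter.roles
    out: list[RorResult] = []
    for domain in plan.domains:
        col = DOMAIN_COLUMNS[domain]
        for d in plan.drug_ids:
            out.append(
                _analyze_drug(
                    cohort, labels, d, roles, plan.min_count,
                    outcome_col=col, outcome=domain,
                )
            )
    return out


def run_sensitivity(
    report_set: ReportSet,
    plan: StudyPlan,
    variant: str,
    term_dict: TermDictionary,
    drug_dict: DrugDictionary,
) -> list[RorResult]:
    """Run one sensitivity variant (S1-S4); see module docstring."""
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    roles = plan.primary_filter.roles

    if variant in ("S1", "S2", "S4"):
        mod = {
            "S1": {"noncase_restrict_oncology": True},
            "S2": {"reporter_restrict": "healthcare_professional"},
            "S4": {"exclude_confounded": True},
        }[variant]
        filt = replace(plan.primary_filter, **mod)
        cohort, labels, _ = prepare_cohort(
            report_set, plan, term_dict, drug_dict, filt=filt
        )
        return [
            _analyze_drug(cohort, labels, d, roles, plan.min_count)
            for d in plan.drug_ids
        ]

    # S3: per-ET window ending (exclusive) at the first iCDK4/6 report
    icdk_first = first_report_date(report_set, "iCDK46", drug_dict)
    if icdk_first is None:
        raise VariantSkipped("no CDK4/6-inhibitor reports; pre-iCDK4/6 window undefined")
    et_ids = [
        d for d in plan.drug_ids
        if drug_dict[d].drug_class in ET_CLASSES
    ]
    out: list[RorResult] = []
    for d in et_ids:
        et_first = first_report_date(report_set, d)
        if et_first is None or et_first >= icdk_first:
            out.append(
                RorResult(
                    drug_id=d,
                    outcome="NCI",
                    method="logistic_adjusted",
                    n_observed=0,
                    n_drug_b=0,
                    n_drug_total=0,
                    computed=False,
                    signal=False,
                    reason="no pre-iCDK4/6 reporting window for this drug",
                )
            )
            continue
        filt = replace(
            plan.primary_filter,
            window=(et_first, icdk_first),
            window_right_open=True,
        )
        cohort, labels, _ = prepare_cohort(
            report_set, plan, term_dict, drug_dict, filt=filt
        )
        out.append(_analyze_drug(cohort, labels, d, roles, plan.min_count))
    return out


def combined_results_frame(
    named_results: dict[str, list[RorResult]],
    drug_dict: DrugDictionary | None = None,
) -> pd.DataFrame:
    """Long-format results across analyses, with crude/MH diagnostic rows."""
    rows = []
    for analysis, results in named_results.items():
        for r in results:
            for res in (r, *[
                r.diagnostics[k]
                for k in ("crude", "mantel_haenszel")
                if k in r.diagnostics
            ]):
                row = res.to_dict()
                row["analysis"] = analysis
                if drug_dict is not None and res.drug_id in drug_dict:
                    row["drug"] = drug_dict[res.drug_id].name
                rows.append(row)
    df = pd.DataFrame(rows)
    front = ["analysis"] + (["drug"] if "drug" in df.columns else [])
    return df[front + [c for c in df.columns if c not in front]]
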