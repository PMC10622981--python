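"""Case definition: resolve the outcome term query and label reports.

The outcome of interest (neurocognitive impairment) is defined by a query
over the term dictionary: a union of group terms (SMQ/HLGT names) plus
explicit PT additions, minus explicit PT exclusions and minus every PT
flagged as a neurological/psychiatric *disease* (the study counts
symptoms, not diseases).  Exclusions always win over inclusions.

Case status is report-level: a report with three matching PTs is one
case.  Domain sub-labels record which DSM-5 neurocognitive domains the
matched PTs map to; a report may carry PTs from several domains and then
contributes to each of those subgroup analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .reports import Report, ReportSet
from .vocab import DSM5_DOMAINS, TermDictionary, VocabError, packaged_path


class QueryResolutionError(ValueError):
    """A query names a group or PT absent from the dictionary."""


@dataclass(frozen=True)
class CaseQuery:
    """Outcome definition over the term dictionary."""

    included_groups: frozenset[str] = frozenset()
    included_pts: frozenset[str] = frozenset()
    excluded_pts: frozenset[str] = frozenset()

    @classmethod
    def from_yaml(cls, path) -> "CaseQuery":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        return cls(
            included_groups=frozenset(obj.get("included_groups") or ()),
            included_pts=frozenset(obj.get("included_pts") or ()),
            excluded_pts=frozenset(obj.get("excluded_pts") or ()),
        )


def load_default_case_query() -> CaseQuery:
    """The packaged study query (six NCI group terms, no explicit PTs)."""
    return CaseQuery.from_yaml(packaged_path("case_query.yaml"))


def resolve_query(query: CaseQuery, dictionary: TermDictionary) -> set[str]:
    """Resolve a :class:`CaseQuery` to the set of case-defining PT codes.

    Returns (union of group members and explicit inclusions) minus explicit
    exclusions minus disease-flagged PTs.  Unknown group or PT names raise
    :class:`QueryResolutionError` naming the offender.
    """
    resolved: set[str] = set()
    for g in sorted(query.included_groups):
        try:
            resolved |= dictionary.group_members(g)
        except VocabError:
            raise QueryResolutionError(f"unknown group {g!r}") from None
    for p in sorted(query.included_pts | query.excluded_pts):
        if p not in dictionary:
            raise QueryResolutionError(f"unknown PT {p!r}")
    resolved |= set(query.included_pts)
    resolved -= set(query.excluded_pts)
    resolved -= dictionary.disease_pts
    return resolved


@dataclass(frozen=True)
class CaseLabel:
    """Report-level case label with DSM-5 domain sub-labels."""

    is_case: bool
    matched_pts: frozenset[str]
    domains: frozenset[str]


def label_report(
    report: Report, case_set: set[str], domain_map: dict[str, str]
) -> CaseLabel:
    """Label one report: case iff any event PT is in ``case_set``."""
    matched = frozenset(p for p in report.events if p in case_set)
    domains = frozenset(domain_map[p] for p in matched if p in domain_map)
    return CaseLabel(is_case=bool(matched), matched_pts=matched, domains=domains)


#: Column name used for the domain sub-label of ``domain`` in label frames.
def domain_column(domain: str) -> str:
    return "is_" + domain.replace(" ", "_")


DOMAIN_COLUMNS = {d: domain_column(d) for d in DSM5_DOMAINS}


def label_reports(
    report_set: ReportSet,
    case_set: set[str],
    domain_map: dict[str, str],
) -> pd.DataFrame:
    """Vectorised labelling of a whole :class:`ReportSet`.

    Returns a DataFrame aligned row-for-row with ``report_set.reports``:
    ``report_id``, boolean ``is_case``, and one boolean column per DSM-5
    domain (``is_learning_and_memory`` etc.).
    """
    rep_ids = pd.Index(report_set.reports["report_id"])
    n = len(rep_ids)
    ev = report_set.events
    pos = rep_ids.get_indexer(ev["report_id"])
    if (pos < 0).any():
        raise ValueError("events reference unknown report_id")

    out = pd.DataFrame({"report_id": rep_ids.to_numpy()})
    pt = ev["pt_code"].astype(str).to_numpy()
    in_case = np.isin(pt, sorted(case_set))
    is_case = np.zeros(n, dtype=bool)
    is_case[pos[in_case]] = True
    out["is_case"] = is_case

    for domain in DSM5_DOMAINS:
        dom_pts = sorted(p for p, d in domain_map.items() if d == domain and p in case_set)
        col = np.zeros(n, dtype=bool)
        if dom_pts:
            hit = np.isin(pt, dom_pts)
            col[pos[hit]] = True
        out[DOMAIN_COLUMNS[domain]] = col
    return out


def labels_to_csv(labels: pd.DataFrame, path) -> None:
    """Export labels as CSV (report_id, is_case, semicolon-joined domains)."""
    dom_cols = [DOMAIN_COLUMNS[d] for d in DSM5_DOMAINS]
    domains = labels[dom_cols].apply(
        lambda row: ";".join(d for d, v in zip(DSM5_DOMAINS, row) if v), axis=1
    )
    pd.DataFrame(
        {
            "report_id": labels["report_id"],
            "is_case": labels["is_case"],
            "domains": domains,
        }
    ).to_csv(path, index=False)
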