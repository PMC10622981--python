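"""Cohort restriction and stratified 2x2 table construction.

The case/non-case design compares, within a filtered cohort of reports,
exposure to a drug of interest between reports that carry the outcome
(cases) and all other reports (non-cases).  For each drug this yields a
2x2 table per age stratum:

    a = cases exposed      b = non-cases exposed
    c = cases unexposed    d = non-cases unexposed

``n_observed`` is the pooled ``a`` and ``n_drug_total`` the pooled
``a + b``.  Published tables in this field often print ``b`` under the
name "N_drug"; outputs here carry ``a``, ``b`` and ``a + b`` explicitly
to avoid the ambiguity.

Every filter's removals are accounted for in :class:`FlowCounts` so the
study flow chart can be reconstructed; the recorded removal counts depend
on the declared filter order (the final cohort does not).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reports import ReportSet
from .vocab import (
    ADULT_AGE_CLASSES,
    AGE_CLASS_ORDER,
    DRUG_CLASSES,
    ET_CLASSES,
    ROLES,
    AgeClass,
    DrugDictionary,
)

ALL_ROLES = frozenset(ROLES)

#: Drug classes whose presence marks a report as oncology-related (used
#: when restricting non-cases to oncology reports).  CDK4/6 inhibitors
#: are antineoplastic agents and count as oncology drugs here, so the
#: restriction never removes a report exposed to a drug of interest.
ONCOLOGY_CLASSES = ("antineoplastic", "immunotherapy", "iCDK46") + ET_CLASSES


@dataclass(frozen=True)
class CohortFilter:
    """Cohort restrictions applied before table construction."""

    sex: str = "female"
    window: tuple[dt.date, dt.date] = (dt.date(2014, 1, 1), dt.date(2022, 3, 16))
    roles: frozenset[str] = ALL_ROLES  # accepted for drug attribution
    require_age: bool = False
    reporter_restrict: str | None = None
    noncase_restrict_oncology: bool = False
    exclude_confounded: bool = False
    window_right_open: bool = False  # pre-iCDK4/6 sensitivity windows

    def __post_init__(self):
        if self.window[0] > self.window[1]:
            raise ValueError("filter window start after end")
        if not self.roles:
            raise ValueError("roles must be nonempty")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {bad}")


@dataclass
class FlowCounts:
    """Record-level accounting of filter removals (the study flow chart)."""

    total_in: int
    removed: list[tuple[str, int]] = field(default_factory=list)
    remaining: int = 0
    note: str = (
        "removal counts are sequential in the declared filter order; "
        "the final cohort is order-independent"
    )

    def check(self) -> None:
        if self.total_in - sum(n for _, n in self.removed) != self.remaining:
            raise AssertionError("flow counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "total_in": self.total_in,
            "removed": [{"filter": f, "n_removed": n} for f, n in self.removed],
            "remaining": self.remaining,
            "note": self.note,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_filters(
    report_set: ReportSet,
    filt: CohortFilter,
    labels: pd.DataFrame | None = None,
    drug_dict: DrugDictionary | None = None,
) -> tuple[ReportSet, FlowCounts]:
    """Apply cohort restrictions, recording each removal.

    ``labels`` and ``drug_dict`` are required only when
    ``noncase_restrict_oncology`` is set (cases are kept; non-cases must
    carry a drug of an oncology class).  An empty final cohort is legal;
    downstream tables are then all-zero.
    """
    rep = report_set.reports
    flow = FlowCounts(total_in=len(rep))
    keep = np.ones(len(rep), dtype=bool)

    def step(name: str, ok: np.ndarray) -> None:
        removed = int((keep & ~ok).sum())
        flow.removed.append((name, removed))
        np.logical_and(keep, ok, out=keep)

    step(f"sex!={filt.sex}", rep["sex"].to_numpy() == filt.sex)

    dates = pd.to_datetime(rep["date"]).to_numpy()
    lo = np.datetime64(filt.window[0], "D")
    hi = np.datetime64(filt.window[1], "D")
    in_window = (dates >= lo) & ((dates < hi) if filt.window_right_open else (dates <= hi))
    step("outside_window", in_window)

    if filt.reporter_restrict is not None:
        step(
            f"reporter!={filt.reporter_restrict}",
            rep["reporter"].to_numpy() == filt.reporter_restrict,
        )

    if filt.require_age:
        step("missing_age", ~np.isnan(rep["age_years"].to_numpy(dtype=float)))

    if filt.exclude_confounded:
        flagged = (
            rep["nci_comorbidity"].to_numpy() | rep["nci_cotreatment"].to_numpy()
        )
        step("nci_comorbidity_or_cotreatment", ~flagged)

    if filt.noncase_restrict_oncology:
        if labels is None or drug_dict is None:
            raise ValueError(
                "noncase_restrict_oncology needs labels and a drug dictionary"
            )
        onco_ids = drug_dict.drugs_in_class(*ONCOLOGY_CLASSES)
        dm = report_set.drug_mentions
        onco_reports = pd.Index(
            dm.loc[dm["drug_id"].isin(sorted(onco_ids)), "report_id"].unique()
        )
        is_onco = rep["report_id"].isin(onco_reports).to_numpy()
        is_case = _aligned_column(labels, rep, "is_case")
        step("noncase_without_oncology_drug", is_case | is_onco)

    flow.remaining = int(keep.sum())
    flow.check()
    return report_set.subset(keep), flow


def _aligned_column(labels: pd.DataFrame, reports: pd.DataFrame, col: str) -> np.ndarray:
    """Label column aligned to ``reports`` rows via report_id."""
    idx = pd.Index(labels["report_id"])
    pos = idx.get_indexer(reports["report_id"])
    if (pos < 0).any():
        raise ValueError("labels missing for some reports")
    return labels[col].to_numpy()[pos]


def align_labels(labels: pd.DataFrame, report_set: ReportSet) -> pd.DataFrame:
    """Subset/reorder a label frame to match ``report_set.reports`` rows."""
    idx = pd.Index(labels["report_id"])
    pos = idx.get_indexer(report_set.reports["report_id"])
    if (pos < 0).any():
        raise ValueError("labels missing for some cohort reports")
    return labels.iloc[pos].reset_index(drop=True)


@dataclass
class StratifiedTable:
    """Per-age-stratum 2x2 counts for one drug-outcome pair."""

    drug_id: str
    strata: dict[AgeClass, tuple[int, int, int, int]]
    outcome: str = "NCI"

    def _pooled(self, i: int) -> int:
        return int(sum(cells[i] for cells in self.strata.values()))

    @property
    def a(self) -> int:
        return self._pooled(0)

    @property
    def b(self) -> int:
        return self._pooled(1)

    @property
    def c(self) -> int:
        return self._pooled(2)

    @property
    def d(self) -> int:
        return self._pooled(3)

    @property
    def n_observed(self) -> int:
        return self.a

    @property
    def n_drug_total(self) -> int:
        return self.a + self.b

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def adult_strata(self) -> dict[AgeClass, tuple[int, int, int, int]]:
        """Strata usable for age adjustment (missing-age stratum excluded)."""
        return {k: v for k, v in self.strata.items() if k != AgeClass.MISSING}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"drug_id": self.drug_id, "outcome": self.outcome,
             "age_class": k.value, "a": v[0], "b": v[1], "c": v[2], "d": v[3]}
            for k, v in self.strata.items()
        ]
        rows.append(
            {"drug_id": self.drug_id, "outcome": self.outcome, "age_class": "pooled",
             "a": self.a, "b": self.b, "c": self.c, "d": self.d}
        )
        return pd.DataFrame(rows)


def build_table(
    cohort: ReportSet,
    drug_id: str,
    labels: pd.DataFrame,
    roles: frozenset[str] = ALL_ROLES,
    outcome_col: str = "is_case",
    outcome: str = "NCI",
    drug_dict: DrugDictionary | None = None,
) -> StratifiedTable:
    """Build the stratified 2x2 table for one drug against one outcome.

    A report is exposed iff it mentions ``drug_id`` with a role in
    ``roles``.  Cells partition the cohort; the missing-age stratum is
    carried separately and never feeds adjustment.
    """
    if drug_dict is not None and drug_id not in drug_dict:
        raise KeyError(f"unknown drug_id {drug_id!r}")
    rep = cohort.reports
    n = len(rep)
    dm = cohort.drug_mentions
    sel = (dm["drug_id"] == drug_id).to_numpy() & dm["role"].isin(sorted(roles)).to_numpy()
    rep_idx = pd.Index(rep["report_id"])
    pos = rep_idx.get_indexer(dm.loc[sel, "report_id"])
    exposed = np.zeros(n, dtype=bool)
    exposed[pos[pos >= 0]] = True

    is_case = _aligned_column(labels, rep, outcome_col)
    age_codes = pd.Categorical(
        rep["age_class"], categories=[k.value for k in AGE_CLASS_ORDER]
    ).codes
    # cell index: age * 4 + exposed * 2 + case
    counts = np.bincount(
        age_codes * 4 + exposed.astype(int) * 2 + is_case.astype(int),
        minlength=len(AGE_CLASS_ORDER) * 4,
    )
    strata: dict[AgeClass, tuple[int, int, int, int]] = {}
    for i, k in enumerate(AGE_CLASS_ORDER):
        base = i * 4
        a = counts[base + 3]  # exposed & case
        b = counts[base + 2]  # exposed & non-case
        c = counts[base + 1]  # unexposed & case
        d = counts[base + 0]
        strata[k] = (int(a), int(b), int(c), int(d))
    return StratifiedTable(drug_id=drug_id, strata=strata, outcome=outcome)


def first_report_date(
    report_set: ReportSet,
    drug_or_class: str,
    drug_dict: DrugDictionary | None = None,
) -> dt.date | None:
    """Earliest report date mentioning a drug (any role) or any drug of a
    class.  Returns None when there are no mentions."""
    if drug_or_class in DRUG_CLASSES:
        if drug_dict is None:
            raise ValueError("resolving a drug class needs a drug dictionary")
        ids = sorted(drug_dict.drugs_in_class(drug_or_class))
    else:
        ids = [drug_or_class]
    dm = report_set.drug_mentions
    hit = dm.loc[dm["drug_id"].isin(ids), "report_id"]
    if hit.empty:
        return None
    rep = report_set.reports
    mask = rep["report_id"].isin(pd.Index(hit.unique()))
    return pd.to_datetime(rep.loc[mask, "date"]).min().date()
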