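"""Individual case safety reports (ICSRs) and their in-memory container.

A single report is a :class:`Report`; a database of them is a
:class:`ReportSet`, three normalised pandas DataFrames (one row per report,
one row per drug mention, one row per event term).  The frame form scales
to millions of reports; the object form is for record-level work and the
JSONL external format (one report object per line).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .vocab import (
    ROLES,
    SEXES,
    REGIONS,
    REPORTERS,
    AgeClass,
    age_class_series,
    VocabError,
)


class ReportValidationError(ValueError):
    """A report or report database violates a structural invariant."""


@dataclass(frozen=True)
class Report:
    """One spontaneous adverse-event report."""

    report_id: str
    date: dt.date
    sex: str
    age_years: int | None
    region: str
    reporter: str
    serious: bool
    drugs: tuple[tuple[str, str], ...]  # (drug_id, role)
    events: tuple[str, ...]  # pt_codes, nonempty
    action_interrupted: bool = False
    nci_comorbidity: bool = False
    nci_cotreatment: bool = False

    def __post_init__(self):
        if not self.events:
            raise ReportValidationError(f"report {self.report_id}: no events")
        if len(set(self.drugs)) != len(self.drugs):
            raise ReportValidationError(
                f"report {self.report_id}: duplicate (drug, role) pairs"
            )
        if self.sex not in SEXES:
            raise ReportValidationError(f"report {self.report_id}: sex {self.sex!r}")
        if self.region not in REGIONS:
            raise ReportValidationError(
                f"report {self.report_id}: region {self.region!r}"
            )
        if self.reporter not in REPORTERS:
            raise ReportValidationError(
                f"report {self.report_id}: reporter {self.reporter!r}"
            )
        for _, role in self.drugs:
            if role not in ROLES:
                raise ReportValidationError(
                    f"report {self.report_id}: role {role!r}"
                )
        if self.age_years is not None and self.age_years < 18:
            raise ReportValidationError(
                f"report {self.report_id}: age {self.age_years} under 18"
            )

    @property
    def age_class(self) -> AgeClass:
        from .vocab import assign_age_class

        return assign_age_class(self.age_years)

    def to_json_obj(self) -> dict:
        return {
            "report_id": self.report_id,
            "date": self.date.isoformat(),
            "sex": self.sex,
            "age_years": self.age_years,
            "region": self.region,
            "reporter": self.reporter,
            "serious": self.serious,
            "action_interrupted": self.action_interrupted,
            "nci_comorbidity": self.nci_comorbidity,
            "nci_cotreatment": self.nci_cotreatment,
            "drugs": [{"drug_id": d, "role": r} for d, r in self.drugs],
            "events": list(self.events),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "Report":
        return cls(
            report_id=str(obj["report_id"]),
            date=dt.date.fromisoformat(obj["date"]),
            sex=obj["sex"],
            age_years=obj["age_years"],
            region=obj["region"],
            reporter=obj["reporter"],
            serious=bool(obj["serious"]),
            action_interrupted=bool(obj.get("action_interrupted", False)),
            nci_comorbidity=bool(obj.get("nci_comorbidity", False)),
            nci_cotreatment=bool(obj.get("nci_cotreatment", False)),
            drugs=tuple((d["drug_id"], d["role"]) for d in obj["drugs"]),
            events=tuple(obj["events"]),
        )


REPORT_COLUMNS = [
    "report_id",
    "date",
    "sex",
    "age_years",
    "region",
    "reporter",
    "serious",
    "action_interrupted",
    "nci_comorbidity",
    "nci_cotreatment",
]


@dataclass
class ReportSet:
    """A report database as three aligned DataFrames.

    ``reports`` has one row per report (columns :data:`REPORT_COLUMNS` plus
    a derived ``age_class`` categorical); ``drug_mentions`` has columns
    (report_id, drug_id, role); ``events`` has columns (report_id, pt_code).
    ``date_range`` is the declared calendar range of the database.
    """

    reports: pd.DataFrame
    drug_mentions: pd.DataFrame
    events: pd.DataFrame
    date_range: tuple[dt.date, dt.date] | None = None

    def __post_init__(self):
        if "age_class" not in self.reports.columns:
            self.reports = self.reports.copy()
            self.reports["age_class"] = age_class_series(self.reports["age_years"])

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def report_index(self) -> pd.Index:
        return pd.Index(self.reports["report_id"])

    def validate(self) -> None:
        """Check structural invariants; raise ReportValidationError."""
        rep = self.reports
        if rep["report_id"].duplicated().any():
            dup = rep.loc[rep["report_id"].duplicated(), "report_id"].iloc[0]
            raise ReportValidationError(f"duplicate report_id {dup!r}")
        ages = rep["age_years"].to_numpy(dtype=float)
        if np.any(ages[~np.isnan(ages)] < 18):
            raise ReportValidationError("reports with age under 18 present")
        for col, allowed in [
            ("sex", SEXES),
            ("region", REGIONS),
            ("reporter", REPORTERS),
        ]:
            bad = ~rep[col].isin(allowed)
            if bad.any():
                raise ReportValidationError(
                    f"invalid {col} value {rep.loc[bad, col].iloc[0]!r}"
                )
        if not self.drug_mentions["role"].isin(ROLES).all():
            raise ReportValidationError("invalid drug role present")
        if self.drug_mentions.duplicated(["report_id", "drug_id", "role"]).any():
            raise ReportValidationError("duplicate (report, drug, role) mention")
        # every report must carry at least one event
        with_events = pd.Index(self.events["report_id"].unique())
        missing = ~rep["report_id"].isin(with_events)
        if missing.any():
            raise ReportValidationError(
                f"report {rep.loc[missing, 'report_id'].iloc[0]!r} has no events"
            )
        if self.date_range is not None:
            lo = pd.Timestamp(self.date_range[0])
            hi = pd.Timestamp(self.date_range[1])
            dates = pd.to_datetime(rep["date"])
            if ((dates < lo) | (dates > hi)).any():
                raise ReportValidationError("report dated outside declared range")

    def subset(self, keep: np.ndarray | pd.Series) -> "ReportSet":
        """New ReportSet restricted to reports where ``keep`` is True
        (boolean mask aligned with ``self.reports`` rows)."""
        keep = np.asarray(keep, dtype=bool)
        rep = self.reports.loc[keep]
        ids = pd.Index(rep["report_id"])
        dm = self.drug_mentions[self.drug_mentions["report_id"].isin(ids)]
        ev = self.events[self.events["report_id"].isin(ids)]
        return ReportSet(
            reports=rep.reset_index(drop=True),
            drug_mentions=dm.reset_index(drop=True),
            events=ev.reset_index(drop=True),
            date_range=self.date_range,
        )

    # ---- conversions -------------------------------------------------

    @classmethod
    def from_reports(
        cls,
        reports: Iterable[Report],
        date_range: tuple[dt.date, dt.date] | None = None,
    ) -> "ReportSet":
        rows, drugs, events = [], [], []
        for r in reports:
            rows.append(
                {
                    "report_id": r.report_id,
                    "date": pd.Timestamp(r.date),
                    "sex": r.sex,
                    "age_years": np.nan if r.age_years is None else float(r.age_years),
                    "region": r.region,
                    "reporter": r.reporter,
                    "serious": r.serious,
                    "action_interrupted": r.action_interrupted,
                    "nci_comorbidity": r.nci_comorbidity,
                    "nci_cotreatment": r.nci_cotreatment,
                }
            )
            for d, role in r.drugs:
                drugs.append((r.report_id, d, role))
            for p in r.events:
                events.append((r.report_id, p))
        rep = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        dm = pd.DataFrame(drugs, columns=["report_id", "drug_id", "role"])
        ev = pd.DataFrame(events, columns=["report_id", "pt_code"])
        return cls(rep, dm, ev, date_range=date_range)

    def iter_reports(self) -> Iterator[Report]:
        dm_by = {
            k: list(zip(v["drug_id"], v["role"]))
            for k, v in self.drug_mentions.groupby("report_id", sort=False)
        }
        ev_by = {
            k: list(v["pt_code"])
            for k, v in self.events.groupby("report_id", sort=False)
        }
        for row in self.reports.itertuples(index=False):
            age = None if pd.isna(row.age_years) else int(row.age_years)
            yield Report(
                report_id=row.report_id,
                date=pd.Timestamp(row.date).date(),
                sex=row.sex,
                age_years=age,
                region=row.region,
                reporter=row.reporter,
                serious=bool(row.serious),
                action_interrupted=bool(row.action_interrupted),
                nci_comorbidity=bool(row.nci_comorbidity),
                nci_cotreatment=bool(row.nci_cotreatment),
                drugs=tuple(dm_by.get(row.report_id, ())),
                events=tuple(ev_by.get(row.report_id, ())),
            )

    # ---- JSONL external format --------------------------------------

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            if self.date_range is not None:
                meta = {
                    "_meta": {
                        "date_range": [d.isoformat() for d in self.date_range],
                        "n_reports": int(self.n_reports),
                    }
                }
                fh.write(json.dumps(meta, sort_keys=True) + "\n")
            for r in self.iter_reports():
                fh.write(json.dumps(r.to_json_obj(), sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ReportSet":
        date_range = None
        reports: list[Report] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                if "_meta" in obj:
                    rng = obj["_meta"].get("date_range")
                    if rng:
                        date_range = (
                            dt.date.fromisoformat(rng[0]),
                            dt.date.fromisoformat(rng[1]),
                        )
                    continue
                reports.append(Report.from_json_obj(obj))
        return cls.from_reports(reports, date_range=date_range)
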