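"""Shared domain vocabulary: age classes, term hierarchy, drug classes.

Spontaneous-report databases code adverse events against a hierarchical
term dictionary (preferred term -> high-level term -> high-level group term
-> system organ class, plus curated standardized-query groupings) and drugs
against a drug dictionary with therapeutic classes.  This module holds the
in-memory forms of both dictionaries, the age-class bands used for
stratified adjustment, and their CSV readers/writers.

Licensed dictionary content is never shipped; the packaged dictionaries
under ``pvror/data`` are small synthetic stand-ins with the same structure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The six DSM-5 neurocognitive domains used for subgroup analyses.
DSM5_DOMAINS = (
    "social cognition",
    "language",
    "executive function",
    "complex attention",
    "learning and memory",
    "perceptual motor function",
)

DRUG_CLASSES = (
    "AI",
    "SERM",
    "SERD",
    "iCDK46",
    "antineoplastic",
    "immunotherapy",
    "other",
)

#: Drug classes that together constitute endocrine therapy.
ET_CLASSES = ("AI", "SERM", "SERD")

#: The nine study drugs and their fixed class assignments.
STUDY_DRUG_CLASSES: Mapping[str, str] = {
    "anastrozole": "AI",
    "letrozole": "AI",
    "exemestane": "AI",
    "tamoxifen": "SERM",
    "toremifene": "SERM",
    "fulvestrant": "SERD",
    "palbociclib": "iCDK46",
    "ribociclib": "iCDK46",
    "abemaciclib": "iCDK46",
}

STUDY_DRUGS = tuple(STUDY_DRUG_CLASSES)

ROLES = ("suspect", "interacting", "concomitant")
SEXES = ("female", "male", "unknown")
REGIONS = ("Americas", "Europe", "EMediterranean", "Asia", "Africa", "other")
REPORTERS = ("healthcare_professional", "non_hcp", "unknown")


class VocabError(ValueError):
    """Invalid dictionary content or out-of-vocabulary value."""


class AgeClass(str, enum.Enum):
    """Adult age bands (completed years) plus a missing-age class.

    The four adult bands partition [18, inf); under-18 input is a
    validation error because the study population contains no minors.
    """

    A18_44 = "18-44"
    A45_64 = "45-64"
    A65_74 = "65-74"
    A75plus = "75+"
    MISSING = "missing"


#: Bands usable as adjustment strata (MISSING never enters adjustment).
ADULT_AGE_CLASSES = (
    AgeClass.A18_44,
    AgeClass.A45_64,
    AgeClass.A65_74,
    AgeClass.A75plus,
)

AGE_CLASS_ORDER = ADULT_AGE_CLASSES + (AgeClass.MISSING,)

# Closed integer bounds (lower, upper); upper None = unbounded.
AGE_BOUNDS = {
    AgeClass.A18_44: (18, 44),
    AgeClass.A45_64: (45, 64),
    AgeClass.A65_74: (65, 74),
    AgeClass.A75plus: (75, None),
}


def assign_age_class(age_years: int | float | None) -> AgeClass:
    """Map an age in completed years to its :class:`AgeClass`.

    ``None``/NaN maps to ``MISSING``; ages under 18 raise
    :class:`VocabError` (the study bands leave no room for minors).
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return AgeClass.MISSING
    if age_years < 18:
        raise VocabError(f"age {age_years!r} is under 18; not a valid study age")
    for cls, (lo, hi) in AGE_BOUNDS.items():
        if age_years >= lo and (hi is None or age_years <= hi):
            return cls
    raise VocabError(f"age {age_years!r} outside all bands")  # pragma: no cover


def age_class_series(ages: pd.Series) -> pd.Categorical:
    """Vectorised :func:`assign_age_class` over a float series (NaN = missing)."""
    a = pd.to_numeric(ages, errors="raise").to_numpy(dtype=float)
    finite = ~np.isnan(a)
    if np.any(a[finite] < 18):
        bad = a[finite & np.less(np.nan_to_num(a, nan=99.0), 18)]
        raise VocabError(f"ages under 18 present (e.g. {bad[:3]})")
    out = np.full(a.shape, AgeClass.MISSING.value, dtype=object)
    out[finite & (a <= 44)] = AgeClass.A18_44.value
    out[finite & (a >= 45) & (a <= 64)] = AgeClass.A45_64.value
    out[finite & (a >= 65) & (a <= 74)] = AgeClass.A65_74.value
    out[finite & (a >= 75)] = AgeClass.A75plus.value
    return pd.Categorical(out, categories=[c.value for c in AGE_CLASS_ORDER])


@dataclass(frozen=True)
class TermEntry:
    """One preferred term with its hierarchy and query metadata."""

    pt_code: str
    pt_name: str
    hlt: str
    hlgt: str
    soc: str
    smqs: frozenset[str] = frozenset()
    disease_flag: bool = False
    dsm5_domain: str | None = None

    def __post_init__(self):
        if self.dsm5_domain is not None and self.dsm5_domain not in DSM5_DOMAINS:
            raise VocabError(
                f"PT {self.pt_code}: dsm5_domain {self.dsm5_domain!r} is not one of "
                f"the six DSM-5 neurocognitive domains"
            )


@dataclass
class TermDictionary:
    """PT hierarchy plus standardized-query groupings and the DSM-5 map."""

    entries: dict[str, TermEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt_code: str) -> bool:
        return pt_code in self.entries

    def __getitem__(self, pt_code: str) -> TermEntry:
        return self.entries[pt_code]

    def add(self, entry: TermEntry) -> None:
        if entry.pt_code in self.entries:
            raise VocabError(f"duplicate pt_code {entry.pt_code!r}")
        self.entries[entry.pt_code] = entry

    @property
    def pt_codes(self) -> set[str]:
        return set(self.entries)

    @property
    def group_names(self) -> set[str]:
        """All names usable as a query group (HLGTs and SMQs)."""
        names: set[str] = set()
        for e in self.entries.values():
            names.add(e.hlgt)
            names.update(e.smqs)
        return names

    def group_members(self, name: str) -> set[str]:
        """PT codes belonging to an HLGT or SMQ group ``name``."""
        if name not in self.group_names:
            raise VocabError(f"unknown group name {name!r}")
        return {
            c
            for c, e in self.entries.items()
            if e.hlgt == name or name in e.smqs
        }

    @property
    def domain_map(self) -> dict[str, str]:
        """pt_code -> DSM-5 domain, over PTs that carry a domain."""
        return {
            c: e.dsm5_domain
            for c, e in self.entries.items()
            if e.dsm5_domain is not None
        }

    def domain_pts(self, domain: str) -> set[str]:
        if domain not in DSM5_DOMAINS:
            raise VocabError(f"unknown DSM-5 domain {domain!r}")
        return {c for c, e in self.entries.items() if e.dsm5_domain == domain}

    @property
    def disease_pts(self) -> set[str]:
        return {c for c, e in self.entries.items() if e.disease_flag}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pt_code": e.pt_code,
                "pt_name": e.pt_name,
                "hlt": e.hlt,
                "hlgt": e.hlgt,
                "soc": e.soc,
                "smqs": ";".join(sorted(e.smqs)),
                "disease_flag": e.disease_flag,
                "dsm5_domain": e.dsm5_domain or "",
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=TERM_COLUMNS)


TERM_COLUMNS = [
    "pt_code",
    "pt_name",
    "hlt",
    "hlgt",
    "soc",
    "smqs",
    "disease_flag",
    "dsm5_domain",
]


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise VocabError(f"unparseable boolean {x!r}")


def load_term_dictionary(path) -> TermDictionary:
    """Load a term dictionary CSV (columns: pt_code, pt_name, hlt, hlgt,
    soc, smqs semicolon-joined, disease_flag, dsm5_domain).

    Raises :class:`VocabError` naming the offending column/row on a missing
    column, duplicate PT, or a DSM-5 domain outside the six.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TERM_COLUMNS if c not in df.columns]
    if missing:
        raise VocabError(f"term dictionary {path}: missing columns {missing}")
    d = TermDictionary()
    for _, row in df.iterrows():
        smqs = frozenset(s.strip() for s in row["smqs"].split(";") if s.strip())
        domain = row["dsm5_domain"].strip() or None
        entry = TermEntry(
            pt_code=row["pt_code"].strip(),
            pt_name=row["pt_name"].strip(),
            hlt=row["hlt"].strip(),
            hlgt=row["hlgt"].strip(),
            soc=row["soc"].strip(),
            smqs=smqs,
            disease_flag=_parse_bool(row["disease_flag"]),
            dsm5_domain=domain,
        )
        d.add(entry)
    return d


def write_term_dictionary(dictionary: TermDictionary, path) -> None:
    dictionary.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DrugEntry:
    drug_id: str
    name: str
    drug_class: str
    known_nci_cotreatment: bool = False

    def __post_init__(self):
        if self.drug_class not in DRUG_CLASSES:
            raise VocabError(
                f"drug {self.drug_id}: class {self.drug_class!r} not in {DRUG_CLASSES}"
            )


@dataclass
class DrugDictionary:
    entries: dict[str, DrugEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def __getitem__(self, drug_id: str) -> DrugEntry:
        return self.entries[drug_id]

    def add(self, entry: DrugEntry) -> None:
        if entry.drug_id in self.entries:
            raise VocabError(f"duplicate drug_id {entry.drug_id!r}")
        # the nine study drugs have fixed, single class assignments
        expected = STUDY_DRUG_CLASSES.get(entry.name.strip().lower())
        if expected is not None and entry.drug_class != expected:
            raise VocabError(
                f"study drug {entry.name!r} must be class {expected!r}, "
                f"got {entry.drug_class!r}"
            )
        self.entries[entry.drug_id] = entry

    def drugs_in_class(self, *classes: str) -> set[str]:
        for c in classes:
            if c not in DRUG_CLASSES:
                raise VocabError(f"unknown drug class {c!r}")
        return {
            d for d, e in self.entries.items() if e.drug_class in classes
        }

    @property
    def drug_ids(self) -> set[str]:
        return set(self.entries)


DRUG_COLUMNS = ["drug_id", "name", "drug_class", "known_nci_cotreatment"]


def load_drug_dictionary(path) -> DrugDictionary:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise VocabError(f"drug dictionary {path}: missing columns {missing}")
    d = DrugDictionary()
    for _, row in df.iterrows():
        d.add(
            DrugEntry(
                drug_id=row["drug_id"].strip(),
                name=row["name"].strip(),
                drug_class=row["drug_class"].strip(),
                known_nci_cotreatment=_parse_bool(row["known_nci_cotreatment"]),
            )
        )
    return d


def packaged_path(name: str):
    """Path to a packaged synthetic dictionary/config file under pvror/data."""
    from importlib.resources import files

    return files("pvror").joinpath("data", name)


def load_default_term_dictionary() -> TermDictionary:
    return load_term_dictionary(packaged_path("term_dictionary.csv"))


def load_default_drug_dictionary() -> DrugDictionary:
    return load_drug_dictionary(packaged_path("drug_dictionary.csv"))


def iter_study_drug_ids(drug_dict: DrugDictionary) -> list[str]:
    """Drug ids of the nine study drugs, in canonical order, if present."""
    by_name = {e.name.lower(): d for d, e in drug_dict.entries.items()}
    return [by_name[n] for n in STUDY_DRUGS if n in by_name]
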