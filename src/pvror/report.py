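"""End-to-end study runner and table/flow rendering.

``run_study`` executes the whole pipeline (optional synthetic generation,
case labelling, cohort extraction, primary + subgroup + sensitivity
disproportionality analyses) deterministically from one seed, and returns
a :class:`StudyOutputBundle` whose views mirror the field's customary
result tables: per-drug rows with N_observed (case reports with the
drug), N_drug (non-case reports with the drug), the adjusted ROR and its
95% interval, with "NC" marking pairs under the minimum report count and
a signal flag derived solely from the lower interval bound.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .analyses import (
    SENSITIVITY_VARIANTS,
    StudyPlan,
    VariantSkipped,
    combined_results_frame,
    prepare_cohort,
    run_domain_subgroups,
    run_primary,
    run_sensitivity,
)
from .casedef import DOMAIN_COLUMNS
from .reports import ReportSet
from .synth import GeneratorConfig, default_config, generate_reports
from .vocab import (
    AGE_CLASS_ORDER,
    DSM5_DOMAINS,
    DrugDictionary,
    TermDictionary,
    load_default_drug_dictionary,
    load_default_term_dictionary,
)

log = logging.getLogger("pvror")

ROUNDING_RULE = (
    "integer percentages by largest-remainder rounding (always sum to 100)"
)


def integer_shares(counts) -> np.ndarray:
    """Integer percentage shares of ``counts`` (largest-remainder method).

    Each share is the floor of its exact percentage, then the leftover
    points go to the largest fractional remainders, so the rounded shares
    always sum to exactly 100 and each differs from the exact value by
    less than one point.  The rule is recorded in run metadata.
    """
    counts = np.asarray(counts, dtype=float)
    exact = 100.0 * counts / counts.sum()
    floors = np.floor(exact).astype(int)
    leftover = int(round(100 - floors.sum()))
    order = np.argsort(-(exact - floors), kind="stable")
    out = floors.copy()
    out[order[:leftover]] += 1
    return out


def _fmt_or(x) -> str:
    return f"{x:.2f}"


def _fmt_ci(lo, hi) -> str:
    return f"({lo:.2f}-{hi:.2f})"


def _view_rows(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "drug": df["drug"] if "drug" in df else df["drug_id"],
            "outcome": df["outcome"],
            "n_observed": df["n_observed"].astype(int),
            "n_drug": df["n_drug_b"].astype(int),
            "n_drug_total": df["n_drug_total"].astype(int),
            "ror": [
                _fmt_or(r) if c else "NC"
                for r, c in zip(df["ror"], df["computed"])
            ],
            "ci_95": [
                _fmt_ci(lo, hi) if c else "NC"
                for lo, hi, c in zip(df["ci_low"], df["ci_high"], df["computed"])
            ],
            "signal": df["signal"].astype(bool),
        }
    )
    return out.reset_index(drop=True)


def render_table1(results: pd.DataFrame) -> pd.DataFrame:
    """Primary-analysis view: one row per drug for the composite outcome."""
    sel = results[
        (results["analysis"] == "primary")
        & (results["method"] == "logistic_adjusted")
        & (results["outcome"] == "NCI")
    ]
    return _view_rows(sel).drop(columns=["outcome"])


def render_table2(results: pd.DataFrame) -> pd.DataFrame:
    """Subgroup view: one row per (DSM-5 domain, drug), NC where suppressed."""
    sel = results[
        (results["analysis"] == "subgroups")
        & (results["method"] == "logistic_adjusted")
    ]
    view = _view_rows(sel)
    return view[
        ["outcome", "drug", "n_observed", "n_drug", "n_drug_total", "ror", "ci_95", "signal"]
    ]


def _share_block(series: pd.Series, order=None) -> dict:
    counts = series.value_counts()
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    shares = integer_shares(counts.to_numpy()) if counts.sum() else counts.to_numpy()
    return {
        "counts": {str(k): int(v) for k, v in counts.items()},
        "shares_pct": {str(k): int(v) for k, v in zip(counts.index, shares)},
    }


def demographics_summary(cohort: ReportSet, labels: pd.DataFrame) -> dict:
    """Describe the cohort: age/region/reporter mixes over all reports
    (integer percent), plus case-level age counts, seriousness share and
    treatment-interruption share among serious cases."""
    rep = cohort.reports
    is_case = labels["is_case"].to_numpy()
    cases = rep.loc[is_case]
    age_order = [k.value for k in AGE_CLASS_ORDER]
    out: dict = {
        "n_reports": int(len(rep)),
        "n_cases": int(is_case.sum()),
        "rounding": ROUNDING_RULE,
        "age": _share_block(rep["age_class"], age_order),
        "region": _share_block(rep["region"]),
        "reporter": _share_block(rep["reporter"]),
    }
    out["age_shares_pct"] = out["age"]["shares_pct"]
    if len(cases) == 0:
        return out
    out["cases_age"] = _share_block(cases["age_class"], age_order)
    serious = cases["serious"].to_numpy()
    out["cases_serious_pct"] = int(np.rint(100 * serious.mean()))
    if serious.any():
        out["cases_interrupted_share_of_serious"] = float(
            cases.loc[serious, "action_interrupted"].mean()
        )
    return out


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    seed: int = 0
    generator: GeneratorConfig | None = None
    reports_path: str | None = None  # JSONL input instead of generation
    plan_overrides: dict = field(default_factory=dict)
    analyses: tuple[str, ...] = ("primary", "subgroups") + SENSITIVITY_VARIANTS

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        seed = int(obj.get("seed", 0))
        gen = None
        if "generator" in obj:
            g = dict(obj["generator"])
            n = int(g.pop("n_reports", 50_000))
            g.pop("seed", None)
            gen = default_config(n_reports=n, seed=seed, **g)
        return cls(
            seed=seed,
            generator=gen,
            reports_path=obj.get("reports"),
            plan_overrides=obj.get("plan", {}) or {},
            analyses=tuple(obj.get("analyses") or ("primary", "subgroups") + SENSITIVITY_VARIANTS),
        )

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "generator": None if self.generator is None else repr(self.generator),
            "reports_path": self.reports_path,
            "plan_overrides": self.plan_overrides,
            "analyses": list(self.analyses),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyOutputBundle:
    """Everything one study run produces."""

    results: pd.DataFrame  # long format, all analyses and methods
    table1: pd.DataFrame
    table2: pd.DataFrame
    flow: dict
    demographics: dict
    metadata: dict
    report_set: ReportSet | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outdir / "results.csv", index=False)
        self.table1.to_csv(outdir / "table1.csv", index=False)
        self.table2.to_csv(outdir / "table2.csv", index=False)
        with open(outdir / "flow.json", "w") as fh:
            json.dump(self.flow, fh, indent=2)
        with open(outdir / "demographics.json", "w") as fh:
            json.dump(self.demographics, fh, indent=2)
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2)
        forest = self.results[
            (self.results["method"] == "logistic_adjusted")
            & self.results["computed"]
        ][["analysis", "drug", "outcome", "ror", "ci_low", "ci_high"]]
        forest.to_csv(outdir / "forest_data.csv", index=False)


def run_study(
    config: StudyConfig | str | Path,
    term_dict: TermDictionary | None = None,
    drug_dict: DrugDictionary | None = None,
    report_set: ReportSet | None = None,
) -> StudyOutputBundle:
    """Execute the configured study end to end (deterministic per seed)."""
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    term_dict = term_dict or load_default_term_dictionary()
    drug_dict = drug_dict or load_default_drug_dictionary()

    t0 = time.time()
    if report_set is None:
        if config.reports_path:
            report_set = ReportSet.from_jsonl(config.reports_path)
        else:
            gen = config.generator or default_config(seed=config.seed)
            report_set = generate_reports(gen, term_dict, drug_dict)
    log.info("reports ready: n=%d (%.1fs)", report_set.n_reports, time.time() - t0)

    plan = StudyPlan.default(drug_dict)
    if config.plan_overrides:
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
            yaml.safe_dump(config.plan_overrides, fh)
            plan = StudyPlan.from_yaml(fh.name, drug_dict)

    named: dict[str, list] = {}
    skipped: dict[str, str] = {}
    for name in config.analyses:
        t1 = time.time()
        try:
            if name == "primary":
                named[name] = run_primary(report_set, plan, term_dict, drug_dict)
            elif name == "subgroups":
                named[name] = run_domain_subgroups(report_set, plan, term_dict, drug_dict)
            elif name in SENSITIVITY_VARIANTS:
                named[name] = run_sensitivity(
                    report_set, plan, name, term_dict, drug_dict
                )
            else:
                raise ValueError(f"unknown analysis {name!r}")
        except VariantSkipped as exc:
            skipped[name] = str(exc)
            continue
        log.info("analysis %s: %d rows (%.1fs)", name, len(named[name]), time.time() - t1)

    results = combined_results_frame(named, drug_dict)
    _, _, flow = prepare_cohort(report_set, plan, term_dict, drug_dict)
    # demographics are described before the missing-age exclusion, so the
    # missing-age share is visible in the summary
    from dataclasses import replace as _replace

    demo_filter = _replace(plan.primary_filter, require_age=False)
    cohort, labels, _ = prepare_cohort(
        report_set, plan, term_dict, drug_dict, filt=demo_filter
    )
    bundle = StudyOutputBundle(
        results=results,
        table1=render_table1(results),
        table2=render_table2(results) if "subgroups" in named else pd.DataFrame(),
        flow=flow.to_dict(),
        demographics=demographics_summary(cohort, labels),
        metadata={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package_version": _pkg_version,
            "rounding": ROUNDING_RULE,
            "skipped_analyses": skipped,
            "n_reports_in": int(report_set.n_reports),
        },
        report_set=report_set,
    )
    return bundle
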