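"""Synthetic spontaneous-report generator with known ground truth.

Real pharmacovigilance databases are access-restricted, so every stage of
the pipeline is exercised against synthetic report streams whose
drug-event association structure is known exactly.  Case status arises
from six independent per-domain Bernoulli channels (one per DSM-5
neurocognitive domain).  Each channel is a logistic model in age class and
drug exposures:

    logit P(Y_d = 1 | age k, exposures x) =
        logit(base_k * w_d) + sum_j ln(theta_{j,d}) x_j

where ``base_k`` is the age-stratum NCI baseline probability, ``w_d`` the
domain's share of that baseline, and ``theta_{j,d}`` the configured
conditional odds ratio of drug j on domain d.  A domain-targeted effect
multiplies only its own channel, so the within-stratum conditional odds
ratio for that domain outcome equals the configured value exactly.  An
NCI-level effect multiplies every channel, making the union ("any
domain") odds ratio equal to the configured value up to a second-order
term that is negligible at the configured event rarity.

Age confounding is built in by default: older age classes have both
higher drug exposure and higher baseline case odds, so the crude pooled
odds ratio deviates from the generating conditional value while
within-stratum odds ratios do not - the fixture that makes age adjustment
meaningful.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .reports import REPORT_COLUMNS, ReportSet
from .vocab import (
    AGE_CLASS_ORDER,
    DSM5_DOMAINS,
    ET_CLASSES,
    REGIONS,
    REPORTERS,
    ROLES,
    SEXES,
    AgeClass,
    DrugDictionary,
    TermDictionary,
    load_default_drug_dictionary,
    load_default_term_dictionary,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

#: Adult age-class mix of the study population, plus missing-age share.
AGE_PROBS = {
    AgeClass.A18_44: 0.05,
    AgeClass.A45_64: 0.29,
    AgeClass.A65_74: 0.26,
    AgeClass.A75plus: 0.23,
    AgeClass.MISSING: 0.17,
}

SEX_PROBS = {"female": 0.88, "male": 0.10, "unknown": 0.02}

REGION_PROBS = {
    "Americas": 0.75,
    "Europe": 0.21,
    "EMediterranean": 0.01,
    "Asia": 0.01,
    "Africa": 0.01,
    "other": 0.01,
}

REPORTER_PROBS = {
    "healthcare_professional": 0.55,
    "non_hcp": 0.40,
    "unknown": 0.05,
}

#: Baseline probability that a report is an NCI case, by age class.
BASELINE_CASE_PROBS = {
    AgeClass.A18_44: 0.008,
    AgeClass.A45_64: 0.014,
    AgeClass.A65_74: 0.026,
    AgeClass.A75plus: 0.045,
    AgeClass.MISSING: 0.020,
}

#: Exposure multiplier by age class (induces age confounding).
EXPOSURE_AGE_FACTORS = {
    AgeClass.A18_44: 0.25,
    AgeClass.A45_64: 0.5,
    AgeClass.A65_74: 1.0,
    AgeClass.A75plus: 2.0,
    AgeClass.MISSING: 1.0,
}

#: Base exposure probability per study drug (at age factor 1), sized so the
#: relative report volumes loosely mirror the real database (palbociclib
#: most reported, toremifene nearly absent).
BASE_EXPOSURE = {
    "anastrozole": 0.012,
    "letrozole": 0.024,
    "exemestane": 0.010,
    "tamoxifen": 0.012,
    "toremifene": 0.0002,
    "fulvestrant": 0.012,
    "palbociclib": 0.040,
    "ribociclib": 0.020,
    "abemaciclib": 0.008,
}

#: Split of the NCI baseline across the six DSM-5 domains, loosely
#: following the study's most-reported symptom mix (memory terms dominate).
DOMAIN_WEIGHTS = {
    "learning and memory": 0.45,
    "complex attention": 0.20,
    "language": 0.12,
    "perceptual motor function": 0.12,
    "executive function": 0.08,
    "social cognition": 0.03,
}

#: Age-independent mention probabilities for non-study (background) drugs.
BACKGROUND_DRUG_PROBS = {
    "capecitabine": 0.05,
    "paclitaxel": 0.04,
    "trastuzumab": 0.03,
    "pembrolizumab": 0.02,
    "atezolizumab": 0.01,
    "paracetamol": 0.20,
    "omeprazole": 0.10,
    "levothyroxine": 0.06,
    "oxycodone": 0.015,
    "zolpidem": 0.010,
    "amlodipine": 0.08,
}

#: Approximate first-marketing dates used by the demo configuration so the
#: pre-iCDK4/6 sensitivity window is non-degenerate.
DEMO_LAUNCH_DATES = {
    "palbociclib": dt.date(2015, 2, 1),
    "ribociclib": dt.date(2017, 3, 1),
    "abemaciclib": dt.date(2017, 9, 1),
}

STUDY_WINDOW = (dt.date(2014, 1, 1), dt.date(2022, 3, 16))


@dataclass(frozen=True)
class Effect:
    """A generating conditional odds ratio for one drug-outcome pair.

    ``outcome`` is ``"NCI"`` (applies to every domain channel) or one of
    the six DSM-5 domain names (applies to that channel only, overriding
    any NCI-level effect for the same drug on that domain).
    """

    drug: str
    outcome: str
    odds_ratio: float


@dataclass
class GeneratorConfig:
    """Full description of one synthetic report database."""

    n_reports: int
    seed: int
    date_range: tuple[dt.date, dt.date] = STUDY_WINDOW
    age_probs: dict[AgeClass, float] = field(default_factory=lambda: dict(AGE_PROBS))
    sex_probs: dict[str, float] = field(default_factory=lambda: dict(SEX_PROBS))
    region_probs: dict[str, float] = field(default_factory=lambda: dict(REGION_PROBS))
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: dict(REPORTER_PROBS)
    )
    drug_exposure: dict[str, float] = field(
        default_factory=lambda: dict(BASE_EXPOSURE)
    )  # drug name -> base exposure prob (multiplied by age factors)
    exposure_age_factors: dict[AgeClass, float] = field(
        default_factory=lambda: dict(EXPOSURE_AGE_FACTORS)
    )
    background_drug_probs: dict[str, float] = field(
        default_factory=lambda: dict(BACKGROUND_DRUG_PROBS)
    )
    baseline_case_probs: dict[AgeClass, float] = field(
        default_factory=lambda: dict(BASELINE_CASE_PROBS)
    )
    domain_weights: dict[str, float] = field(
        default_factory=lambda: dict(DOMAIN_WEIGHTS)
    )
    effects: tuple[Effect, ...] = ()
    drug_launch_dates: dict[str, dt.date] = field(default_factory=dict)
    serious_prob_given_case: float = 0.57
    serious_prob_given_noncase: float = 0.30
    interrupted_prob_given_serious_case: float = 1 / 3
    comorbidity_prob: float = 0.019
    cotreatment_prob: float = 0.007
    coupling_prob: float = 0.0  # ET -> iCDK4/6 co-prescription coupling
    extra_pt_rate: float = 0.4  # Poisson rate of extra non-NCI PTs per report
    extra_domain_pt_prob: float = 0.15  # second PT from a fired domain
    missing_age_extra_prob_if_case: float = 0.0  # stress knob, default off
    fallback_drug: str = "paracetamol"  # guarantees >=1 drug per report

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        for name, block, keys in [
            ("age_probs", self.age_probs, set(AGE_CLASS_ORDER)),
            ("sex_probs", self.sex_probs, set(SEXES)),
            ("region_probs", self.region_probs, set(REGIONS)),
            ("reporter_probs", self.reporter_probs, set(REPORTERS)),
            ("domain_weights", self.domain_weights, set(DSM5_DOMAINS)),
        ]:
            if set(block) != keys:
                raise ConfigError(f"{name}: keys must be exactly {sorted(map(str, keys))}")
            vals = np.array(list(block.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
            if not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name}: probabilities must sum to 1")
        for name, probs in [
            ("drug_exposure", self.drug_exposure),
            ("background_drug_probs", self.background_drug_probs),
            ("baseline_case_probs", self.baseline_case_probs),
        ]:
            for k, v in probs.items():
                if not 0 <= float(v) <= 1:
                    raise ConfigError(f"{name}[{k}]: probability {v} outside [0, 1]")
        for f in self.exposure_age_factors.values():
            if f < 0:
                raise ConfigError("exposure age factors must be nonnegative")
        for e in self.effects:
            if e.odds_ratio <= 0:
                raise ConfigError(f"effect {e}: odds ratio must be > 0")
            if e.outcome != "NCI" and e.outcome not in DSM5_DOMAINS:
                raise ConfigError(f"effect {e}: unknown outcome {e.outcome!r}")
            if e.drug not in self.drug_exposure:
                raise ConfigError(f"effect {e}: drug {e.drug!r} has no exposure spec")
        for p in (
            self.serious_prob_given_case,
            self.serious_prob_given_noncase,
            self.interrupted_prob_given_serious_case,
            self.comorbidity_prob,
            self.cotreatment_prob,
            self.coupling_prob,
            self.extra_domain_pt_prob,
            self.missing_age_extra_prob_if_case,
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.extra_pt_rate < 0:
            raise ConfigError("extra_pt_rate must be >= 0")
        if self.date_range[0] > self.date_range[1]:
            raise ConfigError("date_range start after end")


#: Printed primary-analysis adjusted RORs used as the demo ground truth.
DEMO_EFFECTS = (
    Effect("anastrozole", "NCI", 1.52),
    Effect("letrozole", "NCI", 1.37),
    Effect("exemestane", "NCI", 1.37),
    Effect("tamoxifen", "NCI", 1.25),
    Effect("fulvestrant", "NCI", 1.19),
    Effect("palbociclib", "NCI", 1.41),
    Effect("ribociclib", "NCI", 0.73),
    Effect("abemaciclib", "NCI", 0.65),
)


def default_config(n_reports: int = 50_000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Demo configuration: study-condition mixes, paper-estimate effects,
    pre-window dates and iCDK4/6 launch gating (so the pre-iCDK4/6
    sensitivity window is meaningful)."""
    cfg = GeneratorConfig(
        n_reports=n_reports,
        seed=seed,
        date_range=(dt.date(2012, 1, 1), STUDY_WINDOW[1]),
        effects=DEMO_EFFECTS,
        drug_launch_dates=dict(DEMO_LAUNCH_DATES),
        coupling_prob=0.15,
    )
    return replace(cfg, **overrides) if overrides else cfg


def recovery_config(
    effects: tuple[Effect, ...],
    n_reports: int,
    seed: int,
    **overrides,
) -> GeneratorConfig:
    """Parameter-recovery configuration: study window only, no launch
    gating, independent exposures, the built-in age confounding."""
    cfg = GeneratorConfig(n_reports=n_reports, seed=seed, effects=effects)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Tabulated generating parameters for one configuration."""

    effects: pd.DataFrame  # columns: drug, outcome, true_or
    baseline_case_odds: dict[AgeClass, float]

    def true_or(self, drug: str, outcome: str = "NCI") -> float:
        m = (self.effects["drug"] == drug) & (self.effects["outcome"] == outcome)
        if not m.any():
            raise KeyError((drug, outcome))
        return float(self.effects.loc[m, "true_or"].iloc[0])


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Deterministic tabulation of the configured effects.

    Pairs absent from ``config.effects`` are reported as OR 1.  Note that
    a domain-only effect implies a diluted (between 1 and the domain OR)
    odds ratio at the any-domain NCI level; that dilution is an emergent
    property of the union outcome, not a configured parameter, so the
    NCI-level row for such a drug still reads 1.
    """
    config.validate()
    configured = {(e.drug, e.outcome): e.odds_ratio for e in config.effects}
    rows = []
    for drug in config.drug_exposure:
        for outcome in ("NCI",) + DSM5_DOMAINS:
            rows.append(
                {
                    "drug": drug,
                    "outcome": outcome,
                    "true_or": configured.get((drug, outcome), 1.0),
                }
            )
    baseline_odds = {
        k: p / (1 - p) for k, p in config.baseline_case_probs.items()
    }
    return GroundTruth(pd.DataFrame(rows), baseline_odds)


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------


def _categorical_draw(rng, probs: dict, order: tuple, n: int) -> np.ndarray:
    p = np.array([probs[k] for k in order], dtype=float)
    return rng.choice(len(order), size=n, p=p / p.sum())


def generate_reports(
    config: GeneratorConfig,
    term_dict: TermDictionary | None = None,
    drug_dict: DrugDictionary | None = None,
) -> ReportSet:
    """Generate ``config.n_reports`` synthetic reports (seeded, vectorised).

    The same config and seed always produce the same ReportSet (and hence
    byte-identical JSONL).
    """
    config.validate()
    term_dict = term_dict or load_default_term_dictionary()
    drug_dict = drug_dict or load_default_drug_dictionary()
    name_to_id = {e.name: d for d, e in drug_dict.entries.items()}
    for drug in list(config.drug_exposure) + list(config.background_drug_probs):
        if drug not in name_to_id:
            raise ConfigError(f"drug {drug!r} not in the drug dictionary")

    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    # --- demographics, dates -----------------------------------------
    age_idx = _categorical_draw(rng, config.age_probs, AGE_CLASS_ORDER, n)
    lows = np.array([18, 45, 65, 75, 0], dtype=float)
    highs = np.array([44, 64, 74, 95, 0], dtype=float)
    spans = highs - lows + 1
    age_u = rng.random(n)
    age_years = lows[age_idx] + np.floor(age_u * spans[age_idx])
    age_years[age_idx == 4] = np.nan  # MISSING

    sex_idx = _categorical_draw(rng, config.sex_probs, SEXES, n)
    region_idx = _categorical_draw(rng, config.region_probs, REGIONS, n)
    reporter_idx = _categorical_draw(rng, config.reporter_probs, REPORTERS, n)

    start, end = config.date_range
    ndays = (end - start).days + 1
    day_off = rng.integers(0, ndays, size=n)
    dates = np.datetime64(start, "D") + day_off

    # --- drug exposures ------------------------------------------------
    study_drugs = list(config.drug_exposure)
    factors = np.array(
        [config.exposure_age_factors[k] for k in AGE_CLASS_ORDER], dtype=float
    )
    X = np.zeros((n, len(study_drugs)), dtype=bool)
    for j, drug in enumerate(study_drugs):
        p = np.minimum(config.drug_exposure[drug] * factors[age_idx], 1.0)
        launch = config.drug_launch_dates.get(drug)
        if launch is not None:
            p = np.where(dates >= np.datetime64(launch, "D"), p, 0.0)
        X[:, j] = rng.random(n) < p

    # optional ET + iCDK4/6 co-prescription coupling
    if config.coupling_prob > 0:
        et_ids = drug_dict.drugs_in_class(*ET_CLASSES)
        icdk_ids = drug_dict.drugs_in_class("iCDK46")
        et_cols = [j for j, d in enumerate(study_drugs) if name_to_id[d] in et_ids]
        icdk_cols = [j for j, d in enumerate(study_drugs) if name_to_id[d] in icdk_ids]
        if et_cols and icdk_cols:
            cand = X[:, et_cols].any(axis=1) & ~X[:, icdk_cols].any(axis=1)
            cand &= rng.random(n) < config.coupling_prob
            w = np.array([config.drug_exposure[study_drugs[j]] for j in icdk_cols])
            pick = rng.choice(len(icdk_cols), size=n, p=w / w.sum())
            for kk, j in enumerate(icdk_cols):
                sel = cand & (pick == kk)
                launch = config.drug_launch_dates.get(study_drugs[j])
                if launch is not None:
                    sel &= dates >= np.datetime64(launch, "D")
                X[sel, j] = True

    # --- per-domain case channels --------------------------------------
    log_or = np.zeros((len(DSM5_DOMAINS), len(study_drugs)))
    nci_level = {e.drug: math.log(e.odds_ratio) for e in config.effects if e.outcome == "NCI"}
    for d_i in range(len(DSM5_DOMAINS)):
        for j, drug in enumerate(study_drugs):
            log_or[d_i, j] = nci_level.get(drug, 0.0)
    for e in config.effects:
        if e.outcome != "NCI":
            d_i = DSM5_DOMAINS.index(e.outcome)
            j = study_drugs.index(e.drug)
            log_or[d_i, j] = math.log(e.odds_ratio)

    base = np.array(
        [config.baseline_case_probs[k] for k in AGE_CLASS_ORDER], dtype=float
    )[age_idx]
    Xf = X.astype(float)
    Y = np.zeros((n, len(DSM5_DOMAINS)), dtype=bool)
    for d_i, domain in enumerate(DSM5_DOMAINS):
        p0 = base * config.domain_weights[domain]
        eta = np.log(p0 / (1 - p0)) + Xf @ log_or[d_i]
        Y[:, d_i] = rng.random(n) < expit(eta)
    is_case = Y.any(axis=1)

    # --- events ---------------------------------------------------------
    ev_rep: list[np.ndarray] = []
    ev_pt: list[np.ndarray] = []
    for d_i, domain in enumerate(DSM5_DOMAINS):
        pts = np.array(sorted(term_dict.domain_pts(domain)))
        idx = np.nonzero(Y[:, d_i])[0]
        if idx.size == 0:
            continue
        ev_rep.append(idx)
        ev_pt.append(pts[rng.integers(0, len(pts), idx.size)])
        extra = rng.random(idx.size) < config.extra_domain_pt_prob
        if extra.any():
            ev_rep.append(idx[extra])
            ev_pt.append(pts[rng.integers(0, len(pts), int(extra.sum()))])
    # non-NCI PTs: everything without a DSM-5 domain (incl. disease terms)
    noncase_pool = np.array(
        sorted(c for c, e in term_dict.entries.items() if e.dsm5_domain is None)
    )
    k_extra = rng.poisson(config.extra_pt_rate, n)
    k_extra = k_extra + (~is_case).astype(int)  # non-cases need >=1 event
    rep_idx = np.repeat(np.arange(n), k_extra)
    ev_rep.append(rep_idx)
    ev_pt.append(noncase_pool[rng.integers(0, len(noncase_pool), rep_idx.size)])

    events = pd.DataFrame(
        {
            "report_id": np.concatenate(ev_rep),
            "pt_code": pd.Categorical(np.concatenate(ev_pt)),
        }
    )
    events = events.drop_duplicates(["report_id", "pt_code"])
    events = events.sort_values(["report_id", "pt_code"], kind="stable").reset_index(
        drop=True
    )

    # --- drug mentions ---------------------------------------------------
    dm_rep: list[np.ndarray] = []
    dm_drug: list[np.ndarray] = []
    dm_role: list[np.ndarray] = []
    role_arr = np.array(ROLES)
    for j, drug in enumerate(study_drugs):
        idx = np.nonzero(X[:, j])[0]
        if idx.size == 0:
            continue
        roles = rng.choice(3, size=idx.size, p=[0.70, 0.05, 0.25])
        dm_rep.append(idx)
        dm_drug.append(np.full(idx.size, name_to_id[drug], dtype=object))
        dm_role.append(role_arr[roles])
    study_set = set(study_drugs)
    for drug, p in config.background_drug_probs.items():
        if drug in study_set:
            continue
        mask = rng.random(n) < p
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        roles = rng.choice(3, size=idx.size, p=[0.10, 0.02, 0.88])
        dm_rep.append(idx)
        dm_drug.append(np.full(idx.size, name_to_id[drug], dtype=object))
        dm_role.append(role_arr[roles])
    rep_all = np.concatenate(dm_rep) if dm_rep else np.array([], dtype=int)
    mentioned = np.zeros(n, dtype=bool)
    mentioned[rep_all] = True
    orphan = np.nonzero(~mentioned)[0]
    if orphan.size:
        dm_rep.append(orphan)
        dm_drug.append(np.full(orphan.size, name_to_id[config.fallback_drug], dtype=object))
        dm_role.append(np.full(orphan.size, "concomitant", dtype=object))

    drug_mentions = pd.DataFrame(
        {
            "report_id": np.concatenate(dm_rep),
            "drug_id": pd.Categorical(np.concatenate(dm_drug)),
            "role": pd.Categorical(np.concatenate(dm_role), categories=list(ROLES)),
        }
    )
    drug_mentions = drug_mentions.sort_values(
        ["report_id", "drug_id", "role"], kind="stable"
    ).reset_index(drop=True)

    # --- remaining report-level fields ------------------------------------
    p_serious = np.where(
        is_case, config.serious_prob_given_case, config.serious_prob_given_noncase
    )
    serious = rng.random(n) < p_serious
    interrupted = (
        serious
        & is_case
        & (rng.random(n) < config.interrupted_prob_given_serious_case)
    )
    comorbidity = rng.random(n) < config.comorbidity_prob
    cotreatment = rng.random(n) < config.cotreatment_prob
    if config.missing_age_extra_prob_if_case > 0:
        drop = (
            is_case
            & ~np.isnan(age_years)
            & (rng.random(n) < config.missing_age_extra_prob_if_case)
        )
        age_years = np.where(drop, np.nan, age_years)

    reports = pd.DataFrame(
        {
            "report_id": np.arange(n, dtype=np.int64),
            "date": pd.to_datetime(dates),
            "sex": pd.Categorical(np.array(SEXES)[sex_idx], categories=list(SEXES)),
            "age_years": age_years,
            "region": pd.Categorical(
                np.array(REGIONS)[region_idx], categories=list(REGIONS)
            ),
            "reporter": pd.Categorical(
                np.array(REPORTERS)[reporter_idx], categories=list(REPORTERS)
            ),
            "serious": serious,
            "action_interrupted": interrupted,
            "nci_comorbidity": comorbidity,
            "nci_cotreatment": cotreatment,
        },
        columns=REPORT_COLUMNS,
    )
    return ReportSet(reports, drug_mentions, events, date_range=config.date_range)


# ---------------------------------------------------------------------------
# direct 2x2 simulation (cheap null/recovery experiments at the table level)
# ---------------------------------------------------------------------------


def simulate_stratified_tables(
    n_tables: int,
    stratum_sizes: dict[AgeClass, int],
    exposure_probs: dict[AgeClass, float],
    baseline_probs: dict[AgeClass, float],
    theta: float = 1.0,
    seed: int = 0,
    drug_id: str = "drug",
):
    """Yield stratified 2x2 tables drawn from a known conditional-OR model.

    Within each stratum, exposure is Bernoulli(``exposure_probs``) and case
    status is Bernoulli with baseline ``baseline_probs`` whose odds are
    multiplied by ``theta`` under exposure.  Useful for calibration and
    coverage experiments without full report generation.
    """
    from .extract import StratifiedTable

    rng = np.random.default_rng(seed)
    strata = list(stratum_sizes)
    for _ in range(n_tables):
        cells = {}
        for k in strata:
            n_k = stratum_sizes[k]
            e = exposure_probs[k]
            p0 = baseline_probs[k]
            odds1 = theta * p0 / (1 - p0)
            p1 = odds1 / (1 + odds1)
            n_exp = rng.binomial(n_k, e)
            a = rng.binomial(n_exp, p1)
            c = rng.binomial(n_k - n_exp, p0)
            cells[k] = (a, n_exp - a, c, n_k - n_exp - c)
        yield StratifiedTable(drug_id=drug_id, strata=cells)
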