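"""Generator determinism, demographic targets, and ground-truth recovery."""

import math

import numpy as np
import pytest

from pvror.casedef import label_reports
from pvror.disprop import crude_ror
from pvror.extract import ALL_ROLES, build_table
from pvror.synth import (
    AGE_PROBS,
    ConfigError,
    Effect,
    GeneratorConfig,
    default_config,
    generate_reports,
    ground_truth,
    recovery_config,
)
from pvror.vocab import AGE_CLASS_ORDER, AgeClass, iter_study_drug_ids


def _flat_config(n, seed, effects=(), exposure=0.03, baseline=0.10):
    """Null design without age confounding: flat exposure and baseline."""
    return recovery_config(
        effects=effects,
        n_reports=n,
        seed=seed,
        drug_exposure={d: exposure for d in (
            "anastrozole", "letrozole", "exemestane", "tamoxifen", "toremifene",
            "fulvestrant", "palbociclib", "ribociclib", "abemaciclib",
        )},
        exposure_age_factors={k: 1.0 for k in AGE_CLASS_ORDER},
        baseline_case_probs={k: baseline for k in AGE_CLASS_ORDER},
    )


def _single_stratum_config(n, seed, effects=(), exposure=0.05, baseline=0.05):
    probs = {k: 0.0 for k in AGE_CLASS_ORDER}
    probs[AgeClass.A45_64] = 1.0
    return recovery_config(
        effects=effects,
        n_reports=n,
        seed=seed,
        age_probs=probs,
        drug_exposure={"anastrozole": exposure, "palbociclib": exposure},
        exposure_age_factors={k: 1.0 for k in AGE_CLASS_ORDER},
        baseline_case_probs={k: baseline for k in AGE_CLASS_ORDER},
        background_drug_probs={"paracetamol": 0.3},
    )


def _crude_or_for(rs, drug_id, term_dict, case_set, domain_map):
    labels = label_reports(rs, case_set, domain_map)
    table = build_table(rs, drug_id, labels, roles=ALL_ROLES)
    return crude_ror(table), table


def test_seeded_determinism(tmp_path, term_dict, drug_dict):
    cfg = default_config(n_reports=400, seed=3)
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    generate_reports(cfg, term_dict, drug_dict).to_jsonl(p1)
    generate_reports(cfg, term_dict, drug_dict).to_jsonl(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_structure_valid(term_dict, drug_dict):
    rs = generate_reports(default_config(n_reports=3000, seed=1), term_dict, drug_dict)
    rs.validate()  # nonempty events, no duplicate mentions, ages >= 18
    # every report has at least one drug mention
    assert rs.drug_mentions["report_id"].nunique() == rs.n_reports


def test_age_class_shares(term_dict, drug_dict):
    cfg = recovery_config(effects=(), n_reports=50_000, seed=5)
    rs = generate_reports(cfg, term_dict, drug_dict)
    shares = (
        rs.reports["age_class"].value_counts(normalize=True)
        .reindex([k.value for k in AGE_CLASS_ORDER])
    )
    for k in AGE_CLASS_ORDER:
        assert abs(shares[k.value] - AGE_PROBS[k]) < 0.015


def test_null_unconfounded_crude_near_one(term_dict, drug_dict, case_set, domain_map):
    """With all generating ORs at 1 and no confounding, every drug's crude
    reporting odds ratio stays in [0.8, 1.25]."""
    rs = generate_reports(_flat_config(100_000, seed=9), term_dict, drug_dict)
    for drug_id in iter_study_drug_ids(drug_dict):
        res, _ = _crude_or_for(rs, drug_id, term_dict, case_set, domain_map)
        assert res.computed
        assert 0.8 < res.point < 1.25, drug_id


def test_single_stratum_effect_recovery(term_dict, drug_dict, case_set, domain_map):
    """One stratum, one configured effect: the empirical odds ratio
    converges to the generating value within 3 Monte-Carlo SEs."""
    theta = 1.5
    cfg = _single_stratum_config(
        200_000, seed=13, effects=(Effect("anastrozole", "NCI", theta),)
    )
    rs = generate_reports(cfg, term_dict, drug_dict)
    res, _ = _crude_or_for(rs, "D01", term_dict, case_set, domain_map)
    se = (math.log(res.ci_high) - math.log(res.ci_low)) / (2 * 1.959964)
    assert abs(math.log(res.point) - math.log(theta)) < 3 * se


def test_confounded_null_crude_biased_within_strata_clean(
    term_dict, drug_dict, case_set, domain_map
):
    """Age confounding with theta = 1: pooled crude OR deviates from 1
    while every within-stratum OR stays near 1."""
    cfg = recovery_config(effects=(), n_reports=200_000, seed=21)
    rs = generate_reports(cfg, term_dict, drug_dict)
    res, table = _crude_or_for(rs, "D07", term_dict, case_set, domain_map)  # palbociclib
    assert res.point > 1.12  # visibly biased upward by confounding
    for k, (a, b, c, d) in table.adult_strata().items():
        if min(a, b, c, d) == 0:  # sparse young stratum: continuity-correct
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_k = (a * d) / (b * c)
        se_k = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(math.log(or_k)) < 3 * se_k, k


def test_domain_effect_dilutes_to_nci_level(term_dict, drug_dict, case_set, domain_map):
    """A language-only effect yields an any-domain OR strictly between 1
    and the domain OR (the union outcome dilutes the effect)."""
    theta_lang = 3.0
    cfg = _single_stratum_config(
        200_000, seed=17, effects=(Effect("palbociclib", "language", theta_lang),)
    )
    rs = generate_reports(cfg, term_dict, drug_dict)
    res, _ = _crude_or_for(rs, "D07", term_dict, case_set, domain_map)
    assert 1.05 < res.point < theta_lang - 0.5


def test_ground_truth_tabulation():
    cfg = recovery_config(
        effects=(Effect("palbociclib", "NCI", 1.41),), n_reports=10, seed=0
    )
    gt = ground_truth(cfg)
    assert gt.true_or("palbociclib", "NCI") == 1.41
    assert gt.true_or("palbociclib", "language") == 1.0
    assert gt.true_or("anastrozole", "NCI") == 1.0
    empty = ground_truth(recovery_config(effects=(), n_reports=10, seed=0))
    assert (empty.effects["true_or"] == 1.0).all()
    assert empty.baseline_case_odds[AgeClass.A75plus] == pytest.approx(
        0.045 / 0.955
    )


@pytest.mark.parametrize(
    "breaker",
    [
        dict(n_reports=0),
        dict(age_probs={k: (0.5 if k is AgeClass.MISSING else 0.2) for k in AGE_CLASS_ORDER}),
        dict(effects=(Effect("anastrozole", "NCI", -2.0),)),
        dict(effects=(Effect("anastrozole", "mood", 1.2),)),
        dict(effects=(Effect("unknowndrug", "NCI", 1.2),)),
        dict(coupling_prob=1.5),
    ],
)
def test_invalid_configs_rejected(breaker):
    cfg = recovery_config(effects=(), n_reports=100, seed=0)
    for k, v in breaker.items():
        setattr(cfg, k, v)
    with pytest.raises(ConfigError):
        cfg.validate()


def test_unknown_drug_in_config_rejected(term_dict, drug_dict):
    cfg = recovery_config(effects=(), n_reports=100, seed=0)
    cfg.drug_exposure = {"notadrug": 0.1}
    with pytest.raises(ConfigError, match="notadrug"):
        generate_reports(cfg, term_dict, drug_dict)
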