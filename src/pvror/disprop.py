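"""Reporting odds ratios: crude, Mantel-Haenszel and logistic age-adjusted.

The reporting odds ratio (ROR) for a drug-event pair in a case/non-case
design is OR = (a*d)/(b*c) on the pooled 2x2.  The age-adjusted ROR is
estimated two ways:

* ``lr_adjusted_ror`` - logistic regression of case status on exposure
  plus age-class indicators (reference 45-64).  This is the primary
  adjustment method.
* ``mh_adjusted_ror`` - Mantel-Haenszel pooled odds ratio over age strata
  with the Robins-Breslow-Greenland variance.  Used as an independent
  cross-check; the two must agree on homogeneous-odds-ratio data.

Intervals are 95% Wald/Woolf on the log scale with z = 1.959964 (stated
so bounds are reproducible bit-for-bit).  A pair is a *signal* when the
interval's lower bound strictly exceeds 1 and at least ``min_count``
(default 5) case reports carry the drug; below the minimum the ROR is not
calculated at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .extract import ALL_ROLES, StratifiedTable, build_table
from .reports import ReportSet
from .vocab import AgeClass

#: 97.5% standard-normal quantile, fixed to this precision on purpose.
Z95 = 1.959964

MIN_REPORTS_DEFAULT = 5


@dataclass(frozen=True)
class RorResult:
    """One ROR estimate with interval, metadata and signal flag."""

    drug_id: str
    outcome: str
    method: str  # crude | mantel_haenszel | logistic_adjusted
    n_observed: int
    n_drug_b: int
    n_drug_total: int
    point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    computed: bool = False
    signal: bool = False
    reason: str | None = None
    zero_cell_corrected: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.computed:
            assert self.point is not None
            assert self.ci_low <= self.point <= self.ci_high
        else:
            assert self.point is None and self.ci_low is None and self.ci_high is None

    def to_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "outcome": self.outcome,
            "method": self.method,
            "n_observed": self.n_observed,
            "n_drug_b": self.n_drug_b,
            "n_drug_total": self.n_drug_total,
            "ror": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "computed": self.computed,
            "signal": self.signal,
            "reason": self.reason or "",
            "zero_cell_corrected": self.zero_cell_corrected,
        }


def results_frame(results: list[RorResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _not_computed(table: StratifiedTable, method: str, reason: str) -> RorResult:
    return RorResult(
        drug_id=table.drug_id,
        outcome=table.outcome,
        method=method,
        n_observed=table.n_observed,
        n_drug_b=table.b,
        n_drug_total=table.n_drug_total,
        computed=False,
        signal=False,
        reason=reason,
    )


def crude_ror(table: StratifiedTable) -> RorResult:
    """Pooled ROR = ad/bc with the Woolf (log) 95% interval.

    If any pooled cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) and the result is flagged ``zero_cell_corrected``.
    A drug absent from the cohort (a + b = 0) is not computable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0:
        return _not_computed(table, "crude", "drug absent from cohort (a+b=0)")
    if c + d == 0:
        return _not_computed(table, "crude", "no unexposed reports (c+d=0)")
    corrected = 0 in (a, b, c, d)
    fa, fb, fc, fd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    point = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    log_point = math.log(point)
    return RorResult(
        drug_id=table.drug_id,
        outcome=table.outcome,
        method="crude",
        n_observed=a,
        n_drug_b=b,
        n_drug_total=a + b,
        point=point,
        ci_low=math.exp(log_point - Z95 * se),
        ci_high=math.exp(log_point + Z95 * se),
        computed=True,
        signal=math.exp(log_point - Z95 * se) > 1,
        zero_cell_corrected=corrected,
    )


def mh_adjusted_ror(table: StratifiedTable) -> RorResult:
    """Mantel-Haenszel age-adjusted ROR with the Robins-Breslow-Greenland
    variance.  Strata are the four adult age classes (missing excluded);
    empty strata are skipped."""
    strata = [v for v in table.adult_strata().values() if sum(v) > 0]
    if not strata:
        return _not_computed(table, "mantel_haenszel", "no usable strata")
    A = np.array(strata, dtype=float)
    a, b, c, d = A[:, 0], A[:, 1], A[:, 2], A[:, 3]
    n = a + b + c + d
    R = a * d / n
    S = b * c / n
    sum_R, sum_S = R.sum(), S.sum()
    n_obs = int(a.sum())
    if sum_R == 0 or sum_S == 0:
        return _not_computed(
            table, "mantel_haenszel", "degenerate strata (zero MH numerator or denominator)"
        )
    point = sum_R / sum_S
    P = (a + d) / n
    Q = (b + c) / n
    var = (
        (P * R).sum() / (2 * sum_R**2)
        + ((P * S + Q * R)).sum() / (2 * sum_R * sum_S)
        + (Q * S).sum() / (2 * sum_S**2)
    )
    se = math.sqrt(var)
    log_point = math.log(point)
    lo, hi = math.exp(log_point - Z95 * se), math.exp(log_point + Z95 * se)
    return RorResult(
        drug_id=table.drug_id,
        outcome=table.outcome,
        method="mantel_haenszel",
        n_observed=n_obs,
        n_drug_b=int(b.sum()),
        n_drug_total=int((a + b).sum()),
        point=point,
        ci_low=lo,
        ci_high=hi,
        computed=True,
        signal=lo > 1,
    )


def lr_from_table(table: StratifiedTable) -> RorResult:
    """Logistic age-adjusted ROR fitted on the aggregated stratum counts.

    Model: logit P(case) = b0 + b1*exposed + age-class indicators
    (reference 45-64 when present).  Point = exp(b1) with the Wald 95%
    interval.  Aggregated binomial fitting is exactly equivalent to the
    report-level fit and independent of cohort size.
    """
    strata = {k: v for k, v in table.adult_strata().items() if sum(v) > 0}
    if not strata:
        return _not_computed(table, "logistic_adjusted", "no usable strata")
    a_tot = sum(v[0] for v in strata.values())
    b_tot = sum(v[1] for v in strata.values())
    c_tot = sum(v[2] for v in strata.values())
    d_tot = sum(v[3] for v in strata.values())
    if a_tot + b_tot == 0:
        return _not_computed(table, "logistic_adjusted", "drug absent from cohort (a+b=0)")
    if c_tot + d_tot == 0:
        return _not_computed(table, "logistic_adjusted", "no unexposed reports (c+d=0)")
    if a_tot + c_tot == 0 or b_tot + d_tot == 0:
        return _not_computed(table, "logistic_adjusted", "all-case or all-non-case cohort")
    if a_tot == 0 or b_tot == 0:
        return _not_computed(
            table, "logistic_adjusted",
            "exposure coefficient unidentified (zero exposed-case or exposed-non-case cell)",
        )

    # strata with no cases or no non-cases carry no information about the
    # exposure odds ratio and would only drive their age dummy to +/-inf
    strata = {
        k: v for k, v in strata.items()
        if (v[0] + v[2]) > 0 and (v[1] + v[3]) > 0
    }
    if not strata:
        return _not_computed(table, "logistic_adjusted", "no informative strata")
    present = list(strata)
    ref = AgeClass.A45_64 if AgeClass.A45_64 in strata else present[0]
    dummy_classes = [k for k in present if k != ref]
    rows_X, rows_y = [], []
    for k in present:
        a, b, c, d = strata[k]
        for exposed, cases, noncases in ((1, a, b), (0, c, d)):
            if cases + noncases == 0:
                continue
            x = [1.0, float(exposed)] + [1.0 if k == dc else 0.0 for dc in dummy_classes]
            rows_X.append(x)
            rows_y.append([cases, noncases])
    X = np.array(rows_X)
    y = np.array(rows_y, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation reported via diagnostics
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10
            )
    except Exception as exc:  # separation / singular design
        return _not_computed(table, "logistic_adjusted", f"fit failed: {exc}")
    beta1 = float(fit.params[1])
    se1 = float(fit.bse[1])
    if not (np.isfinite(beta1) and np.isfinite(se1)) or abs(beta1) > 15 or se1 > 50:
        return _not_computed(
            table, "logistic_adjusted", "separation or non-convergence diagnostic"
        )
    point = math.exp(beta1)
    lo, hi = math.exp(beta1 - Z95 * se1), math.exp(beta1 + Z95 * se1)
    return RorResult(
        drug_id=table.drug_id,
        outcome=table.outcome,
        method="logistic_adjusted",
        n_observed=a_tot,
        n_drug_b=b_tot,
        n_drug_total=a_tot + b_tot,
        point=point,
        ci_low=lo,
        ci_high=hi,
        computed=True,
        signal=lo > 1,
        diagnostics={"log_se": se1},
    )


def lr_adjusted_ror(
    cohort: ReportSet,
    drug_id: str,
    labels: pd.DataFrame,
    roles: frozenset[str] = ALL_ROLES,
    outcome_col: str = "is_case",
    outcome: str = "NCI",
) -> RorResult:
    """Logistic age-adjusted ROR for one drug on a labelled cohort.

    The cohort should already be restricted to reports with known age;
    any missing-age stratum in the table is excluded from the fit.
    """
    table = build_table(
        cohort, drug_id, labels, roles=roles, outcome_col=outcome_col, outcome=outcome
    )
    return lr_from_table(table)


def apply_signal_rules(
    result: RorResult, min_count: int = MIN_REPORTS_DEFAULT
) -> RorResult:
    """Apply the minimum-report rule and the lower-bound signal rule.

    Pairs with fewer than ``min_count`` observed case reports are marked
    not computed (the ROR is suppressed entirely); otherwise the signal
    flag is (lower CI bound strictly greater than 1).
    """
    if result.n_observed < min_count:
        return replace(
            result,
            point=None,
            ci_low=None,
            ci_high=None,
            computed=False,
            signal=False,
            reason=f"fewer than {min_count} observed reports (n={result.n_observed})",
        )
    if not result.computed:
        return replace(result, signal=False)
    return replace(result, signal=result.ci_low > 1)
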