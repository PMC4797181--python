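"""Sex-differentiated regression estimate test.

Given sex-specific additive log-ORs and standard errors (beta_f, se_f)
and (beta_m, se_m) for a variant-outcome pair, three chi-square
statistics summarise the evidence:

* per-sex 1-df Wald statistics  chi2_s = (beta_s / se_s)^2,
* their 2-df joint sum          chi2_joint = chi2_f + chi2_m,
* a 1-df heterogeneity test     chi2_het = (beta_f - beta_m)^2 /
                                           (se_f^2 + se_m^2),

the last assuming the two strata are disjoint samples (zero covariance;
an optional covariance term is accepted for correlated estimates).  A
variant-outcome pair is flagged as a potential sex difference when a
sex-specific P value is below 0.05 in at least one sex AND the
heterogeneity P value is below 0.05 (both strict).

A reanalysis path reconstructs beta/SE from printed OR and 95% CI
bounds, so the test can be applied to published tables with no genotype
data at all.  Note that printed values are rounded: heterogeneity P
values recomputed from them agree with published ones only to rounding
error, i.e. within a small constant factor.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AssocResult, DataError, SexDiffResult

logger = logging.getLogger(__name__)

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964


def wald_chi2(beta: float, se: float) -> tuple[float, float]:
    """1-df Wald chi-square ``(beta/se)**2`` and its upper-tail P value."""
    if se <= 0:
        raise DataError("se must be > 0")
    chi2 = (beta / se) ** 2
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def joint_2df(chi2_f: float, chi2_m: float) -> tuple[float, float]:
    """Sum of the two sex-specific statistics against chi-square(2)."""
    if chi2_f < 0 or chi2_m < 0:
        raise DataError("chi-square inputs must be >= 0")
    chi2 = chi2_f + chi2_m
    return float(chi2), float(stats.chi2.sf(chi2, 2))


def het_test(
    beta_f: float,
    se_f: float,
    beta_m: float,
    se_m: float,
    cov: float = 0.0,
) -> tuple[float, float]:
    """1-df heterogeneity test of equality of the two allelic effects.

    ``chi2 = (beta_f - beta_m)^2 / (se_f^2 + se_m^2 - 2 cov)``; the
    default zero covariance is exact for disjoint sex strata.
    """
    if se_f <= 0 or se_m <= 0:
        raise DataError("standard errors must be > 0")
    denom = se_f**2 + se_m**2 - 2 * cov
    if denom <= 0:
        raise DataError("variance of the effect difference must be > 0")
    chi2 = (beta_f - beta_m) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def beta_se_from_or_ci(
    or_: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Reconstruct (beta, se) from a printed OR and Wald CI.

    ``beta = ln OR``; ``se = (ln ci_high - ln ci_low) / (2 z)`` with z
    the two-sided normal quantile of the level.  Inverse of
    :func:`sexassoc.assoc.or_ci` up to floating-point round-off.
    """
    if not 0 < ci_low < or_ < ci_high:
        raise DataError(
            f"need 0 < ci_low < OR < ci_high, got ({ci_low}, {or_}, {ci_high})"
        )
    if not 0 < level < 1:
        raise DataError("level must be in (0,1)")
    z = stats.norm.ppf(0.5 + level / 2)
    beta = math.log(or_)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
    return float(beta), float(se)


def sexdiff_pair(
    rsid: str,
    outcome: str,
    beta_f: float,
    se_f: float,
    beta_m: float,
    se_m: float,
    alpha_sex: float = 0.05,
    alpha_het: float = 0.05,
) -> SexDiffResult:
    """All four statistics for one variant-outcome pair, with flagging."""
    chi2_f, p_f = wald_chi2(beta_f, se_f)
    chi2_m, p_m = wald_chi2(beta_m, se_m)
    chi2_j, p_j = joint_2df(chi2_f, chi2_m)
    chi2_h, p_h = het_test(beta_f, se_f, beta_m, se_m)
    return SexDiffResult(
        rsid=rsid,
        outcome=outcome,
        beta_f=beta_f,
        se_f=se_f,
        beta_m=beta_m,
        se_m=se_m,
        chi2_f=chi2_f,
        chi2_m=chi2_m,
        chi2_joint=chi2_j,
        chi2_het=chi2_h,
        p_f=p_f,
        p_m=p_m,
        p_joint=p_j,
        p_het=p_h,
        flagged=(p_f < alpha_sex or p_m < alpha_sex) and p_h < alpha_het,
    )


def sexdiff_scan(
    results_f: Sequence[AssocResult],
    results_m: Sequence[AssocResult],
    alpha_sex: float = 0.05,
    alpha_het: float = 0.05,
) -> list[SexDiffResult]:
    """Sex-differentiated test over matched female/male association scans.

    The two inputs must cover the same (variant, outcome) pairs; pairs
    where either fit is flagged separated/degenerate are skipped with a
    log message.  Output follows the female scan's order.
    """
    key_f = {(r.rsid, r.outcome): r for r in results_f}
    key_m = {(r.rsid, r.outcome): r for r in results_m}
    if set(key_f) != set(key_m):
        only_f = sorted(set(key_f) - set(key_m))
        only_m = sorted(set(key_m) - set(key_f))
        raise DataError(
            f"mismatched (variant, outcome) pairs: {len(only_f)} only in F "
            f"(e.g. {only_f[:3]}), {len(only_m)} only in M (e.g. {only_m[:3]})"
        )
    out: list[SexDiffResult] = []
    for r_f in results_f:
        r_m = key_m[(r_f.rsid, r_f.outcome)]
        if not (r_f.ok and r_m.ok):
            logger.info(
                "skipping %s/%s: flags F=%s M=%s",
                r_f.rsid,
                r_f.outcome,
                r_f.status_flag,
                r_m.status_flag,
            )
            continue
        out.append(
            sexdiff_pair(
                r_f.rsid,
                r_f.outcome,
                r_f.beta,
                r_f.se,
                r_m.beta,
                r_m.se,
                alpha_sex=alpha_sex,
                alpha_het=alpha_het,
            )
        )
    return out


def sexdiff_from_or_ci(
    table: pd.DataFrame,
    outcome: str = "melanoma",
    level: float = 0.95,
    alpha_sex: float = 0.05,
    alpha_het: float = 0.05,
) -> list[SexDiffResult]:
    """Run the sex-differentiated test on a table of printed OR/CI pairs.

    ``table`` needs columns ``rsid, or_f, ci_low_f, ci_high_f, or_m,
    ci_low_m, ci_high_m`` (the layout of a published sex-stratified
    association table).  This enables reanalysis of published results
    without genotype data; expect rounding-level discrepancies from the
    original unrounded internals.
    """
    required = {"rsid", "or_f", "ci_low_f", "ci_high_f", "or_m", "ci_low_m", "ci_high_m"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"OR/CI table missing columns {sorted(missing)}")
    out = []
    for row in table.itertuples():
        beta_f, se_f = beta_se_from_or_ci(row.or_f, row.ci_low_f, row.ci_high_f, level)
        beta_m, se_m = beta_se_from_or_ci(row.or_m, row.ci_low_m, row.ci_high_m, level)
        out.append(
            sexdiff_pair(
                row.rsid, outcome, beta_f, se_f, beta_m, se_m, alpha_sex, alpha_het
            )
        )
    return out
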