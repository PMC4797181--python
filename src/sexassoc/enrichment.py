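"""Direction-of-effect enrichment between sexes.

Each significant (P < alpha, default 0.05) SNP-trait association is
classified as protective (OR < 1: dark pigmentation / good sun
tolerance) or risk (OR > 1: light pigmentation / poor tolerance).  Per
trait, the counts form a 2x2 table (sex x direction); a pooled table
sums the six traits at the SNP-trait-pair level (a SNP significant for
two traits counts twice).  Two tests of the female-male difference are
attached to every table: the Pearson 1-df chi-square without continuity
correction and the two-sided Fisher exact test.  The published study's
P values correspond to the uncorrected Pearson chi-square.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import AssocResult, DataError, EnrichmentTable


def classify_direction(result: AssocResult, alpha: float = 0.05) -> str:
    """'protective' (OR < 1), 'risk' (OR > 1) or 'not_significant'.

    Requires an ok fit; significance is strict ``p < alpha``.  An OR of
    exactly 1 cannot be significant under a Wald test and is classed
    not_significant.
    """
    if not result.ok:
        raise DataError(f"{result.rsid}: cannot classify a {result.status_flag} fit")
    if not (result.p < alpha) or result.or_ == 1.0:
        return "not_significant"
    return "protective" if result.or_ < 1.0 else "risk"


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Shortcut form ``n (ad - bc)^2 / (r1 r2 c1 c2)``; P from the 1-df
    upper tail.  All four margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("need a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DataError("all margins must be positive for the chi-square test")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact P: sum of hypergeometric probabilities of
    all tables with the observed margins whose probability does not
    exceed the observed table's."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(t)[1])


def attach_tests(table: EnrichmentTable) -> EnrichmentTable:
    """Fill percentages and both association tests in place.

    A sex with zero significant associations keeps its counts but the
    tests are skipped (NaN); a zero direction column yields Fisher only.
    """
    nf = table.prot_f + table.risk_f
    nm = table.prot_m + table.risk_m
    table.pct_prot_f = 100.0 * table.prot_f / nf if nf else float("nan")
    table.pct_prot_m = 100.0 * table.prot_m / nm if nm else float("nan")
    if nf == 0 or nm == 0:
        return table
    counts = table.counts
    table.p_fisher = fisher_exact_2x2(counts)
    if counts.sum(axis=0).min() > 0:
        table.chi2, table.p_chi2 = pearson_chi2_2x2(counts)
    return table


def build_trait_table(
    results_f: Sequence[AssocResult],
    results_m: Sequence[AssocResult],
    trait: str,
    alpha: float = 0.05,
) -> EnrichmentTable:
    """Classify both sexes' scans for one trait and test the difference."""
    counts = {"F": {"protective": 0, "risk": 0}, "M": {"protective": 0, "risk": 0}}
    for sex, results in (("F", results_f), ("M", results_m)):
        for r in results:
            if r.outcome != trait:
                raise DataError(f"{r.rsid}: outcome {r.outcome!r} is not {trait!r}")
            if not r.ok:
                continue
            cls = classify_direction(r, alpha)
            if cls != "not_significant":
                counts[sex][cls] += 1
    table = EnrichmentTable(
        trait=trait,
        prot_f=counts["F"]["protective"],
        risk_f=counts["F"]["risk"],
        prot_m=counts["M"]["protective"],
        risk_m=counts["M"]["risk"],
    )
    return attach_tests(table)


def pooled_enrichment(tables: Sequence[EnrichmentTable]) -> EnrichmentTable:
    """Sum per-trait tables into a pooled 2x2 and re-test.

    Counting is at the SNP-trait-pair level, so the pooled margins are
    the sums of the per-trait margins.
    """
    if not tables:
        raise DataError("need at least one trait table")
    pooled = EnrichmentTable(
        trait="pooled",
        prot_f=sum(t.prot_f for t in tables),
        risk_f=sum(t.risk_f for t in tables),
        prot_m=sum(t.prot_m for t in tables),
        risk_m=sum(t.risk_m for t in tables),
    )
    return attach_tests(pooled)


def enrichment_analysis(
    results_f: Sequence[AssocResult],
    results_m: Sequence[AssocResult],
    traits: Sequence[str],
    alpha: float = 0.05,
) -> list[EnrichmentTable]:
    """Per-trait tables plus the pooled table (last element)."""
    per_trait = [
        build_trait_table(
            [r for r in results_f if r.outcome == t],
            [r for r in results_m if r.outcome == t],
            t,
            alpha,
        )
        for t in traits
    ]
    return per_trait + [pooled_enrichment(per_trait)]
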