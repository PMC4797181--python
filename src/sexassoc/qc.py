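"""Genotype quality control.

Call-rate filtering, orientation of dosages to the sample minor allele,
per-sex minor-allele frequency summaries, the exact conditional
Hardy-Weinberg test with Bonferroni screening, and the between-sex
allele-count comparison (Fisher's exact test on the 2x2 allele table).

X-chromosome convention: males are treated as hemizygous by default —
their X dosages live in {0, 1} and contribute one allele to allele
tables; HWE on X is assessed in females only.  Pass ``x_mode="autosomal"``
to disable this and treat every variant identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .datamodel import (
    DataError,
    GenotypeMatrix,
    HWEResult,
    MafSummary,
    SampleRecord,
    sex_mask,
)

X_MODES = ("hemizygous", "autosomal")


@dataclass
class CallRateReport:
    """Accounting of a call-rate filter pass."""

    min_call_rate: float
    n_input: int
    n_removed: int
    removed_rsids: list[str] = field(default_factory=list)
    warning: str = ""

    @property
    def removal_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def call_rate_filter(
    gm: GenotypeMatrix, min_call_rate: float = 0.9
) -> tuple[GenotypeMatrix, CallRateReport]:
    """Drop variants whose non-missing fraction is below ``min_call_rate``.

    This is the dosage-level stand-in for instrument-level genotyping
    failure triage (no amplification, poor cluster separation), which is
    not reproducible from dosage data.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise DataError(f"min_call_rate must be in [0,1], got {min_call_rate}")
    rates = gm.call_rate()
    keep = [j for j in range(gm.n_variants) if rates[j] >= min_call_rate]
    removed = [gm.variants[j].rsid for j in range(gm.n_variants) if rates[j] < min_call_rate]
    report = CallRateReport(
        min_call_rate=min_call_rate,
        n_input=gm.n_variants,
        n_removed=len(removed),
        removed_rsids=removed,
    )
    if not keep and gm.n_variants:
        report.warning = "all variants removed by call-rate filter"
    return gm.subset_variants(keep), report


def _ploidy(gm: GenotypeMatrix, samples: Sequence[SampleRecord] | None, x_mode: str) -> np.ndarray:
    """Per-(sample, variant) allele count: 2, or 1 for male X hemizygotes."""
    pl = np.full((gm.n_samples, gm.n_variants), 2.0)
    if samples is not None and x_mode == "hemizygous":
        male = np.array([s.sex == "M" for s in samples])
        x_cols = [j for j, v in enumerate(gm.variants) if v.is_x]
        for j in x_cols:
            pl[male, j] = 1.0
    return pl


def orient_minor_allele(
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord] | None = None,
    x_mode: str = "hemizygous",
) -> GenotypeMatrix:
    """Reflect dosages so the coded allele is the pooled-sample minor allele.

    For each variant, if the pooled frequency of the coded allele exceeds
    0.5 the dosages are reflected (d -> ploidy - d) and the allele labels
    swapped.  A frequency of exactly 0.5 keeps the input orientation.
    Idempotent.  When ``samples`` is given, male X genotypes count one
    allele under the hemizygous convention.
    """
    if x_mode not in X_MODES:
        raise DataError(f"x_mode must be one of {X_MODES}")
    pl = _ploidy(gm, samples, x_mode)
    dosage = gm.dosage.copy()
    variants = list(gm.variants)
    with np.errstate(invalid="ignore"):
        obs = np.isfinite(dosage)
        alleles = np.where(obs, pl, 0.0).sum(axis=0)
        counts = np.where(obs, dosage, 0.0).sum(axis=0)
    for j in range(gm.n_variants):
        if alleles[j] > 0 and counts[j] / alleles[j] > 0.5:
            dosage[:, j] = np.where(obs[:, j], pl[:, j] - dosage[:, j], np.nan)
            v = variants[j]
            variants[j] = type(v)(
                rsid=v.rsid,
                chromosome=v.chromosome,
                position=v.position,
                gene=v.gene,
                minor_allele=v.major_allele,
                major_allele=v.minor_allele,
            )
    return GenotypeMatrix(samples=list(gm.samples), variants=variants, dosage=dosage)


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_Aa, n_aa) with A the minor allele, over non-missing diploid calls."""
    d = dosage[np.isfinite(dosage)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test P value.

    Conditions on the observed allele counts and sums, over all
    heterozygote counts compatible with those margins, the conditional
    probabilities that do not exceed the observed configuration's
    (two-sided by probability ordering).  The conditional distribution
    puts weight proportional to ``n! / (nAA! nAa! naa!) * 2**nAa`` on each
    genotype table.  Monomorphic variants return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("at least one genotype required")
    n_minor = 2 * n_AA + n_Aa
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    n_aa_h = (n_minor - hs) // 2
    n_AA_h = n - n_aa_h - hs  # note: here AA = major homozygote bucket
    logw = (
        hs * np.log(2.0)
        - gammaln(hs + 1)
        - gammaln(n_aa_h + 1)
        - gammaln(n_AA_h + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    obs = w[hs == n_Aa][0]
    return float(min(1.0, w[w <= obs * (1 + 1e-12)].sum()))


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance level alpha/m."""
    if m < 1:
        raise DataError("m must be >= 1")
    if not 0 < alpha < 1:
        raise DataError("alpha must be in (0,1)")
    return alpha / m


def hwe_screen(
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord] | None = None,
    alpha: float = 0.05,
    m: int | None = None,
    x_mode: str = "hemizygous",
) -> tuple[list[HWEResult], float]:
    """Exact HWE test per variant, per stratum, with Bonferroni flagging.

    A variant is flagged out of HWE iff ``p_exact < alpha / m`` (strict:
    P values at or above the threshold count as in HWE).  ``m`` defaults
    to the number of variants.  When sample records are supplied the test
    is run within each sex and pooled; on the X chromosome (hemizygous
    mode) only females are tested.  Returns the results and the threshold.
    """
    if m is None:
        m = max(1, gm.n_variants)
    threshold = bonferroni_threshold(alpha, m)
    strata: list[tuple[str, np.ndarray]]
    if samples is None:
        strata = [("all", np.ones(gm.n_samples, dtype=bool))]
    else:
        strata = [(s, sex_mask(samples, s)) for s in ("F", "M", "all")]
    results: list[HWEResult] = []
    for j, v in enumerate(gm.variants):
        for name, mask in strata:
            if v.is_x and x_mode == "hemizygous" and name != "F":
                continue
            n_AA, n_Aa, n_aa = genotype_counts(gm.dosage[mask, j])
            if n_AA + n_Aa + n_aa == 0:
                continue
            p = hwe_exact_test(n_AA, n_Aa, n_aa)
            results.append(
                HWEResult(
                    rsid=v.rsid,
                    stratum=name,
                    n_AA=n_AA,
                    n_Aa=n_Aa,
                    n_aa=n_aa,
                    p_exact=p,
                    in_hwe=p >= threshold,
                )
            )
    return results, threshold


def _stratum_freq(dosage: np.ndarray, ploidy: np.ndarray) -> tuple[float, int]:
    obs = np.isfinite(dosage)
    alleles = ploidy[obs].sum()
    if alleles == 0:
        return float("nan"), 0
    return float(dosage[obs].sum() / alleles), int(obs.sum())


def maf_by_sex(
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    x_mode: str = "hemizygous",
) -> tuple[list[MafSummary], float]:
    """Per-variant minor-allele frequency in females, males and pooled.

    Returns the per-variant summaries plus the panel-level squared
    Pearson correlation between the female and male frequency vectors
    (variants with a frequency missing in either sex are excluded from
    the correlation).  Expects an oriented matrix.
    """
    pl = _ploidy(gm, samples, x_mode)
    fmask = sex_mask(samples, "F")
    mmask = sex_mask(samples, "M")
    out: list[MafSummary] = []
    for j, v in enumerate(gm.variants):
        maf_f, n_f = _stratum_freq(gm.dosage[fmask, j], pl[fmask, j])
        maf_m, n_m = _stratum_freq(gm.dosage[mmask, j], pl[mmask, j])
        maf_all, _ = _stratum_freq(gm.dosage[:, j], pl[:, j])
        out.append(MafSummary(rsid=v.rsid, maf_f=maf_f, maf_m=maf_m, maf_all=maf_all, n_f=n_f, n_m=n_m))
    ff = np.array([s.maf_f for s in out])
    mm = np.array([s.maf_m for s in out])
    ok = np.isfinite(ff) & np.isfinite(mm)
    if ok.sum() >= 2 and np.std(ff[ok]) > 0 and np.std(mm[ok]) > 0:
        r = np.corrcoef(ff[ok], mm[ok])[0, 1]
        r2 = float(r * r)
    else:
        r2 = float("nan")
    return out, r2


def allele_count_sex_test(
    gm: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    rsid: str,
    x_mode: str = "hemizygous",
) -> float:
    """Two-sided Fisher exact P comparing minor/major allele counts F vs M.

    On the X chromosome (hemizygous mode) each male contributes a single
    allele; autosomes contribute two per genotype.
    """
    j = gm.rsids.index(rsid) if rsid in gm.rsids else None
    if j is None:
        raise DataError(f"variant {rsid!r} not in matrix")
    pl = _ploidy(gm, samples, x_mode)
    table = np.zeros((2, 2))
    for row, stratum in enumerate(("F", "M")):
        mask = sex_mask(samples, stratum)
        d = gm.dosage[mask, j]
        p = pl[mask, j]
        obs = np.isfinite(d)
        total = p[obs].sum()
        if total == 0:
            raise DataError(f"{rsid}: no alleles observed in stratum {stratum}")
        minor = d[obs].sum()
        table[:, row] = (minor, total - minor)
    return float(stats.fisher_exact(table)[1])
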