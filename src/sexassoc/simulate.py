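"""Synthetic genotype-phenotype study generator.

Emulates the layout of the melanoma case-control study the pipeline is
built for: 599 females (316 cases / 283 controls), 458 males (234 / 224),
363 SNPs with minor-allele frequencies in [0.05, 0.5], genotypes in
Hardy-Weinberg proportions, no linkage disequilibrium between SNPs and
no population structure.  Sex-specific per-allele log-odds effects can
be planted on melanoma status and on any of the six binary traits; a
truth table records them for recovery testing.

Melanoma case/control status is generated by rejection sampling against
a prospective logistic disease model until the configured case and
control counts are hit exactly — under a logistic model the per-allele
odds ratio is invariant to such outcome-dependent sampling, so planted
betas remain the estimands of the retrospective analysis.  Trait
phenotypes are drawn independently of melanoma status given genotype.

All randomness flows from the single config seed through named
substreams, so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import TRAITS, DataError, GenotypeMatrix, SampleRecord, VariantInfo


@dataclass(frozen=True)
class Effect:
    """A planted sex-specific per-allele log-odds effect.

    ``snp`` indexes the panel; ``outcome`` is a trait name or
    ``"melanoma"``; ``beta_f``/``beta_m`` are the true log-ORs per
    minor-allele copy in females and males.
    """

    snp: int
    outcome: str
    beta_f: float = 0.0
    beta_m: float = 0.0


@dataclass
class SimulationConfig:
    """Study-layout defaults mirror the emulated case-control design."""

    n_female_case: int = 316
    n_female_control: int = 283
    n_male_case: int = 234
    n_male_control: int = 224
    n_snps: int = 363
    n_x_snps: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    effects: list[Effect] = field(default_factory=list)
    trait_prevalence: dict[str, float] = field(
        default_factory=lambda: {t: 0.5 for t in TRAITS}
    )
    missing_rate: float = 0.01
    x_hemizygous_males: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (
            self.n_female_case,
            self.n_female_control,
            self.n_male_case,
            self.n_male_control,
        ):
            if n <= 0:
                raise DataError("all sample counts must be positive")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise DataError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must be in [0, 1)")
        if not 0 <= self.n_x_snps <= self.n_snps:
            raise DataError("n_x_snps must be between 0 and n_snps")
        for e in self.effects:
            if not 0 <= e.snp < self.n_snps:
                raise DataError(f"effect SNP index {e.snp} out of range")
            if e.outcome not in (*TRAITS, "melanoma"):
                raise DataError(f"unknown effect outcome {e.outcome!r}")


def sample_genotypes(
    maf: float,
    n: int,
    seed: int | np.random.Generator = 0,
    hemizygous: bool = False,
) -> np.ndarray:
    """Draw dosages for one SNP under HWE (two independent allele draws).

    ``hemizygous`` draws a single allele (male X convention), so dosages
    are 0/1.
    """
    if not 0 < maf <= 0.5:
        raise DataError(f"maf must be in (0, 0.5], got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(1 if hemizygous else 2, maf, size=n).astype(float)


def simulate_binary_outcome(
    dosages: np.ndarray,
    beta0: float,
    beta: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a binary outcome with ``P(y=1) = expit(beta0 + beta * dosage)``."""
    if not np.isfinite(beta0):
        raise DataError("beta0 must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = expit(beta0 + beta * np.asarray(dosages, dtype=float))
    return (rng.random(p.shape) < p).astype(float)


def _draw_genotype_batch(
    rng: np.random.Generator,
    mafs: np.ndarray,
    n: int,
    hemizygous_cols: np.ndarray,
) -> np.ndarray:
    ploidy = np.where(hemizygous_cols, 1, 2)
    return rng.binomial(ploidy[None, :], mafs[None, :], size=(n, mafs.size)).astype(float)


def simulate_case_control(
    mafs: np.ndarray,
    betas: np.ndarray,
    n_case: int,
    n_control: int,
    seed: int | np.random.Generator = 0,
    hemizygous_cols: np.ndarray | None = None,
    max_draws: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample genotypes and disease status to exact quotas.

    Individuals are drawn prospectively (genotypes from HWE, disease from
    the logistic liability ``expit(beta0 + G @ betas)`` with the intercept
    centred so the marginal prevalence matches the target case fraction)
    and kept until ``n_case`` cases and ``n_control`` controls have
    accumulated.  Returns ``(G, y)`` with cases first.
    """
    mafs = np.asarray(mafs, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if mafs.shape != betas.shape:
        raise DataError("mafs and betas must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if hemizygous_cols is None:
        hemizygous_cols = np.zeros(mafs.size, dtype=bool)
    ploidy = np.where(hemizygous_cols, 1.0, 2.0)
    target_frac = n_case / (n_case + n_control)
    beta0 = float(logit(target_frac) - np.sum(betas * ploidy * mafs))
    G_cases: list[np.ndarray] = []
    G_controls: list[np.ndarray] = []
    need_case, need_control = n_case, n_control
    drawn = 0
    batch = max(256, 2 * (n_case + n_control))
    while need_case > 0 or need_control > 0:
        batch_n = min(batch, max_draws - drawn)
        if batch_n <= 0:
            raise DataError(
                "rejection sampling exceeded the draw budget; "
                "reduce the planted effect sizes or quotas"
            )
        G = _draw_genotype_batch(rng, mafs, batch_n, hemizygous_cols)
        p = expit(beta0 + G @ betas)
        y = rng.random(batch_n) < p
        drawn += batch_n
        if need_case > 0:
            take = G[y][:need_case]
            G_cases.append(take)
            need_case -= take.shape[0]
        if need_control > 0:
            take = G[~y][:need_control]
            G_controls.append(take)
            need_control -= take.shape[0]
    G_out = np.vstack([np.vstack(G_cases), np.vstack(G_controls)])
    y_out = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    return G_out, y_out


def _panel_variants(config: SimulationConfig, mafs: np.ndarray) -> list[VariantInfo]:
    autosomes = [str(c) for c in range(1, 23)]
    variants = []
    per_chrom_count: dict[str, int] = {}
    n_auto = config.n_snps - config.n_x_snps
    for j in range(config.n_snps):
        chrom = "X" if j >= n_auto else autosomes[j % 22]
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        variants.append(
            VariantInfo(
                rsid=f"snp{j + 1:04d}",
                chromosome=chrom,
                position=10_000 + 5_000 * k,
                gene=f"GENE{j // 6 + 1}",
                minor_allele="A",
                major_allele="G",
            )
        )
    return variants


def generate_study(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[SampleRecord], pd.DataFrame]:
    """Generate the full synthetic study.

    Returns the genotype matrix (females first, cases before controls
    within each sex), the matching sample records, and a truth table with
    one row per planted effect (rsid, outcome, beta_f, beta_m).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_maf, rng_f, rng_m, rng_trait, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    lo, hi = config.maf_range
    mafs = rng_maf.uniform(lo, hi, size=config.n_snps)
    variants = _panel_variants(config, mafs)
    x_cols = np.array([v.is_x for v in variants])

    mel_beta_f = np.zeros(config.n_snps)
    mel_beta_m = np.zeros(config.n_snps)
    for e in config.effects:
        if e.outcome == "melanoma":
            mel_beta_f[e.snp] += e.beta_f
            mel_beta_m[e.snp] += e.beta_m

    G_f, y_f = simulate_case_control(
        mafs, mel_beta_f, config.n_female_case, config.n_female_control, rng_f
    )
    hemi = x_cols if (config.x_hemizygous_males and config.n_x_snps) else None
    G_m, y_m = simulate_case_control(
        mafs,
        mel_beta_m,
        config.n_male_case,
        config.n_male_control,
        rng_m,
        hemizygous_cols=hemi,
    )
    G = np.vstack([G_f, G_m])
    n_f, n_m = G_f.shape[0], G_m.shape[0]
    sexes = ["F"] * n_f + ["M"] * n_m
    status = ["case" if y else "control" for y in np.concatenate([y_f, y_m])]

    # traits: logistic in genotype, independent of melanoma given genotype
    trait_values: dict[str, np.ndarray] = {}
    female = np.array([s == "F" for s in sexes])
    for t in TRAITS:
        prev = config.trait_prevalence.get(t, 0.5)
        if not 0 < prev < 1:
            raise DataError(f"trait prevalence for {t} must be in (0,1)")
        bf = np.zeros(config.n_snps)
        bm = np.zeros(config.n_snps)
        for e in config.effects:
            if e.outcome == t:
                bf[e.snp] += e.beta_f
                bm[e.snp] += e.beta_m
        ploidy_f = 2.0 * mafs
        ploidy_m = np.where(x_cols & (hemi is not None), mafs, 2.0 * mafs)
        eta0_f = logit(prev) - np.sum(bf * ploidy_f)
        eta0_m = logit(prev) - np.sum(bm * ploidy_m)
        eta = np.where(female, eta0_f + G @ bf, eta0_m + G @ bm)
        trait_values[t] = (rng_trait.random(len(sexes)) < expit(eta)).astype(int)

    if config.missing_rate > 0:
        mask = rng_miss.random(G.shape) < config.missing_rate
        G = np.where(mask, np.nan, G)

    samples = [
        SampleRecord(
            sample_id=f"S{i + 1:04d}",
            sex=sexes[i],
            status=status[i],
            **{t: int(trait_values[t][i]) for t in TRAITS},
        )
        for i in range(len(sexes))
    ]
    gm = GenotypeMatrix(samples=[s.sample_id for s in samples], variants=variants, dosage=G)
    truth = pd.DataFrame(
        [
            {
                "rsid": variants[e.snp].rsid,
                "outcome": e.outcome,
                "beta_f": e.beta_f,
                "beta_m": e.beta_m,
                "maf": mafs[e.snp],
            }
            for e in config.effects
        ],
        columns=["rsid", "outcome", "beta_f", "beta_m", "maf"],
    )
    return gm, samples, truth
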