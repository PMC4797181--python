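"""Core containers for a sex-stratified SNP association study.

A study is held as a :class:`GenotypeMatrix` (samples x variants,
minor-allele dosage 0/1/2 with NaN for missing calls) plus one
:class:`SampleRecord` per individual carrying sex, melanoma case/control
status and six binary phenotype codes.

Phenotype coding is normalised so that 1 always means the
light-pigmentation / poor-sun-tolerance (melanoma risk) category:
blue/green eyes, blond/red hair, fair skin, >= 50 naevi, lentigines
present, childhood sunburns present.  Under that convention an odds
ratio above 1 uniformly reads "risk direction" for every trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np

#: traits analysed as binary outcomes, in canonical report order
TRAITS = ("eye", "hair", "skin", "naevi", "lentigines", "sunburn")
#: all outcomes: the six questionnaire traits plus melanoma case/control status
OUTCOMES = TRAITS + ("melanoma",)

SEXES = ("F", "M")
STRATA = ("F", "M", "all")

#: chromosome labels accepted for the SNP panel (autosomes and X)
CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X",)


class DataError(ValueError):
    """Malformed or inconsistent study data."""


@dataclass(frozen=True)
class VariantInfo:
    """Identity of one SNP on the panel.

    ``minor_allele`` is the allele whose copies the dosage counts; the
    orientation is data-driven (see :func:`sexassoc.qc.orient_minor_allele`)
    rather than taken from any reference population.
    """

    rsid: str
    chromosome: str
    position: int
    gene: str = ""
    minor_allele: str = "A"
    major_allele: str = "G"

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise DataError(
                f"{self.rsid}: chromosome {self.chromosome!r} not in 1..22, X"
            )
        if self.position < 0:
            raise DataError(f"{self.rsid}: negative position {self.position}")
        if self.minor_allele == self.major_allele:
            raise DataError(f"{self.rsid}: minor and major allele both {self.minor_allele!r}")

    @property
    def is_x(self) -> bool:
        return self.chromosome == "X"


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of minor-allele dosages.

    ``dosage`` is a float array of shape ``(n_samples, n_variants)`` whose
    finite entries are 0, 1 or 2 (copies of the variant's minor allele);
    missing calls are NaN.  Hemizygous male X genotypes are stored as 0/1.
    """

    samples: list[str]
    variants: list[VariantInfo]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise DataError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise DataError(f"non-missing dosages must be 0/1/2; found {bad[:5]}")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise DataError(f"duplicated rsID(s): {', '.join(dupes)}")
        self._index = {r: j for j, r in enumerate(rsids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def column(self, rsid: str) -> np.ndarray:
        """Dosage vector (copy) for one variant."""
        return self.dosage[:, self._index[rsid]].copy()

    def variant(self, rsid: str) -> VariantInfo:
        return self.variants[self._index[rsid]]

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            variants=list(self.variants),
            dosage=self.dosage[keep, :].copy(),
        )

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return np.isfinite(self.dosage).mean(axis=0)


@dataclass(frozen=True)
class SampleRecord:
    """One individual: sex, melanoma status and six binary trait codes.

    Trait values are 0 (protective phenotype), 1 (risk phenotype) or None
    (questionnaire answer missing); sex and status are never missing.
    """

    sample_id: str
    sex: str
    status: str
    eye: int | None = None
    hair: int | None = None
    skin: int | None = None
    naevi: int | None = None
    lentigines: int | None = None
    sunburn: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"sample {self.sample_id}: sex must be F or M, got {self.sex!r}")
        if self.status not in ("case", "control"):
            raise DataError(
                f"sample {self.sample_id}: status must be case or control, got {self.status!r}"
            )
        for t in TRAITS:
            v = getattr(self, t)
            if v is not None and v not in (0, 1):
                raise DataError(f"sample {self.sample_id}: {t} must be 0/1/None, got {v!r}")

    def outcome(self, name: str) -> float:
        """Outcome value as float (NaN if missing); melanoma = case indicator."""
        if name == "melanoma":
            return 1.0 if self.status == "case" else 0.0
        if name not in TRAITS:
            raise DataError(f"unknown outcome {name!r}")
        v = getattr(self, name)
        return float("nan") if v is None else float(v)


def outcome_vector(samples: Sequence[SampleRecord], outcome: str) -> np.ndarray:
    """Stack one outcome across samples (NaN marks missing answers)."""
    return np.array([s.outcome(outcome) for s in samples], dtype=float)


def sex_mask(samples: Sequence[SampleRecord], stratum: str) -> np.ndarray:
    """Boolean mask selecting a sex stratum ('F', 'M' or 'all')."""
    if stratum == "all":
        return np.ones(len(samples), dtype=bool)
    if stratum not in SEXES:
        raise DataError(f"unknown stratum {stratum!r}")
    return np.array([s.sex == stratum for s in samples], dtype=bool)


@dataclass
class AssocResult:
    """Additive logistic fit of one outcome on one variant in one stratum."""

    rsid: str
    stratum: str
    outcome: str
    n_used: int
    beta: float = float("nan")
    se: float = float("nan")
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    status_flag: str = "ok"  # ok | separated | degenerate

    @property
    def ok(self) -> bool:
        return self.status_flag == "ok"


@dataclass
class SexDiffResult:
    """Sex-differentiated test for one (variant, outcome) pair.

    Carries the two sex-specific 1-df Wald chi-squares, their 2-df sum,
    and the 1-df heterogeneity statistic on the difference of log-ORs.
    ``flagged`` marks a potential sex difference: sex-specific P < 0.05 in
    at least one sex AND heterogeneity P < 0.05.
    """

    rsid: str
    outcome: str
    beta_f: float
    se_f: float
    beta_m: float
    se_m: float
    chi2_f: float
    chi2_m: float
    chi2_joint: float
    chi2_het: float
    p_f: float
    p_m: float
    p_joint: float
    p_het: float
    flagged: bool = False


@dataclass
class HWEResult:
    """Exact Hardy-Weinberg test of one variant in one stratum."""

    rsid: str
    stratum: str
    n_AA: int
    n_Aa: int
    n_aa: int
    p_exact: float
    in_hwe: bool = True


@dataclass
class MafSummary:
    """Per-variant minor-allele frequency by sex (after orientation)."""

    rsid: str
    maf_f: float
    maf_m: float
    maf_all: float
    n_f: int
    n_m: int


@dataclass
class EnrichmentTable:
    """Protective/risk counts of significant associations by sex for one trait.

    ``prot_*`` counts significant (P < alpha) associations with OR < 1
    (dark pigmentation / good tolerance direction), ``risk_*`` those with
    OR > 1.  Percentages are of each sex's significant total.
    """

    trait: str
    prot_f: int
    risk_f: int
    prot_m: int
    risk_m: int
    pct_prot_f: float = float("nan")
    pct_prot_m: float = float("nan")
    chi2: float = float("nan")
    p_chi2: float = float("nan")
    p_fisher: float = float("nan")

    @property
    def counts(self) -> np.ndarray:
        """2x2 table rows = (F, M), columns = (protective, risk)."""
        return np.array([[self.prot_f, self.risk_f], [self.prot_m, self.risk_m]])


def records_to_rows(records: Iterable) -> list[dict]:
    """Dataclass instances -> list of plain dicts (for TSV output)."""
    rows = []
    for r in records:
        rows.append({f.name: getattr(r, f.name) for f in fields(r)})
    return rows
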