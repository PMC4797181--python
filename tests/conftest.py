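import numpy as np
import pytest

from sexassoc.datamodel import GenotypeMatrix, SampleRecord, VariantInfo
from sexassoc.simulate import SimulationConfig, generate_study


def make_variant(rsid="rs1", chrom="1", pos=100, **kw):
    return VariantInfo(rsid=rsid, chromosome=chrom, position=pos, **kw)


def make_matrix(dosage, chroms=None, samples=None):
    """Small GenotypeMatrix from a 2-D list; NaN for missing."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chroms = chroms or ["1"] * m
    variants = [make_variant(rsid=f"rs{j + 1}", chrom=chroms[j], pos=100 * (j + 1)) for j in range(m)]
    samples = samples or [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def make_samples(sexes, statuses=None, **traits):
    statuses = statuses or ["control"] * len(sexes)
    out = []
    for i, (sex, st) in enumerate(zip(sexes, statuses)):
        tv = {k: (v[i] if v is not None else None) for k, v in traits.items()}
        out.append(SampleRecord(sample_id=f"S{i + 1}", sex=sex, status=st, **tv))
    return out


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by several suites (40 SNPs)."""
    cfg = SimulationConfig(
        seed=11,
        n_snps=40,
        n_x_snps=4,
        n_female_case=80,
        n_female_control=80,
        n_male_case=60,
        n_male_control=60,
        missing_rate=0.02,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def study_layout():
    """Full study-layout simulation with a planted male-only melanoma effect."""
    from sexassoc.simulate import Effect

    cfg = SimulationConfig(
        seed=5150,
        n_snps=60,
        effects=[Effect(snp=7, outcome="melanoma", beta_f=0.0, beta_m=np.log(1.9))],
    )
    return generate_study(cfg)
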