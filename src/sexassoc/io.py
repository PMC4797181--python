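"""Reading and writing the study's tabular formats.

Canonical interchange is plain TSV with ``NA`` for missing values:

* genotype TSV — first column ``sample_id``, remaining columns rsIDs,
  cells in {0, 1, 2, NA};
* variant TSV — columns ``rsid, chrom, pos, gene, minor_allele,
  major_allele``;
* phenotype TSV — columns ``sample_id, sex, status`` plus the six trait
  columns, either pre-coded 0/1 or as questionnaire categories
  (``blue``/``brown``, ``fair``/``dark``, ``yes``/``no``, ...).

VCF 4.x import is provided because SNP panels commonly ship as VCF; GT
pairs are converted to ALT-allele counts and re-oriented to the sample
minor allele downstream by :func:`sexassoc.qc.orient_minor_allele`.
"""

from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    TRAITS,
    DataError,
    EnrichmentTable,
    GenotypeMatrix,
    SampleRecord,
    VariantInfo,
    records_to_rows,
)

MISSING_TOKEN = "NA"

# questionnaire category -> risk coding (1 = light pigmentation / poor
# tolerance phenotype, uniformly the melanoma-risk direction)
_TRAIT_CODES: dict[str, dict[str, int]] = {
    "eye": {"blue": 1, "green": 1, "brown": 0, "black": 0},
    "hair": {"blond": 1, "red": 1, "brown": 0, "black": 0},
    "skin": {"fair": 1, "dark": 0},
    "naevi": {">=50": 1, "<50": 0, "ge50": 1, "lt50": 0},
    "lentigines": {"yes": 1, "no": 0, "present": 1, "absent": 0},
    "sunburn": {"yes": 1, "no": 0, "present": 1, "absent": 0},
}

_SEX_CODES = {"f": "F", "female": "F", "m": "M", "male": "M"}
_STATUS_CODES = {"case": "case", "control": "control", "1": "case", "0": "control"}


def read_variants(path: str | Path) -> list[VariantInfo]:
    """Read a variant annotation TSV into a list of :class:`VariantInfo`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "chrom", "pos", "gene", "minor_allele", "major_allele"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: variant table missing columns {sorted(missing)}")
    out = [
        VariantInfo(
            rsid=r.rsid,
            chromosome=str(r.chrom),
            position=int(r.pos),
            gene="" if pd.isna(r.gene) else str(r.gene),
            minor_allele=r.minor_allele,
            major_allele=r.major_allele,
        )
        for r in df.itertuples()
    ]
    rsids = [v.rsid for v in out]
    if len(set(rsids)) != len(rsids):
        raise DataError(f"{path}: duplicated rsIDs in variant table")
    return out


def _parse_dosage_cell(value: str, row: str, col: str) -> float:
    v = value.strip()
    if v in (MISSING_TOKEN, "", "."):
        return float("nan")
    if v not in ("0", "1", "2"):
        raise DataError(f"bad dosage {value!r} at sample {row!r}, variant {col!r}")
    return float(v)


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    variants: Sequence[VariantInfo] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF.

    Parameters
    ----------
    path
        Input file.  TSV: header ``sample_id`` then rsIDs, one row per
        sample, cells in {0,1,2,NA}.  VCF: one biallelic record per SNP,
        dosage = count of ALT alleles per GT.
    dialect
        ``"tsv"`` or ``"vcf"``.
    variants
        Optional annotation used to attach gene/allele metadata to TSV
        columns; for VCF the record fields themselves are used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_genotypes_tsv(path, variants)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise DataError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(
    path: Path, variants: Sequence[VariantInfo] | None
) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or header[0] != "sample_id":
            raise DataError(f"{path}: genotype TSV must start with a sample_id column")
        rsids = header[1:]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise DataError(f"{path}: duplicated rsID column(s): {', '.join(dupes)}")
        samples: list[str] = []
        rows: list[list[float]] = []
        for rec in reader:
            if not rec:
                continue
            if len(rec) != len(rsids) + 1:
                raise DataError(f"{path}: row for {rec[0]!r} has {len(rec) - 1} cells, expected {len(rsids)}")
            samples.append(rec[0])
            rows.append([_parse_dosage_cell(c, rec[0], r) for r, c in zip(rsids, rec[1:])])
    if variants is not None:
        by_id = {v.rsid: v for v in variants}
        missing = [r for r in rsids if r not in by_id]
        if missing:
            raise DataError(f"{path}: rsIDs absent from variant table: {missing[:5]}")
        vlist = [by_id[r] for r in rsids]
    else:
        # placeholder annotation; orientation/alleles refined downstream
        vlist = [
            VariantInfo(rsid=r, chromosome="1", position=j + 1, minor_allele="A", major_allele="G")
            for j, r in enumerate(rsids)
        ]
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, len(rsids)))
    return GenotypeMatrix(samples=samples, variants=vlist, dosage=dosage)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        rsid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if rsid in seen:
            raise DataError(f"{path}: duplicated rsID {rsid!r} in VCF")
        seen.add(rsid)
        if len(rec.ALT) != 1:
            raise DataError(f"{path}: {rsid} is not biallelic (ALT={rec.ALT})")
        chrom = rec.CHROM.removeprefix("chr")
        variants.append(
            VariantInfo(
                rsid=rsid,
                chromosome=chrom,
                position=rec.POS,
                gene="",
                minor_allele=rec.ALT[0],
                major_allele=rec.REF,
            )
        )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(dos)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def _code_trait(trait: str, value: str, sample_id: str) -> int | None:
    v = value.strip()
    if v in (MISSING_TOKEN, "", "."):
        return None
    if v in ("0", "1"):
        return int(v)
    coded = _TRAIT_CODES[trait].get(v.lower())
    if coded is None:
        raise DataError(f"sample {sample_id!r}: unknown {trait} category {value!r}")
    return coded


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read the phenotype/questionnaire TSV into :class:`SampleRecord` s.

    Rows with missing sex or status are rejected with an error naming the
    sample; missing trait answers become None (complete-case handling is
    applied per analysis downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "sex", "status", *TRAITS}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: phenotype table missing columns {sorted(missing)}")
    records: list[SampleRecord] = []
    for row in df.itertuples():
        sid = row.sample_id
        sex_raw = row.sex.strip()
        if sex_raw in (MISSING_TOKEN, "", "."):
            raise DataError(f"{path}: sample {sid!r} has missing sex; record rejected")
        sex = _SEX_CODES.get(sex_raw.lower())
        if sex is None:
            raise DataError(f"{path}: sample {sid!r} has unknown sex {sex_raw!r}")
        status_raw = row.status.strip()
        status = _STATUS_CODES.get(status_raw.lower())
        if status is None:
            raise DataError(f"{path}: sample {sid!r} has bad status {status_raw!r}; record rejected")
        traits = {t: _code_trait(t, getattr(row, t), sid) for t in TRAITS}
        records.append(SampleRecord(sample_id=sid, sex=sex, status=status, **traits))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicated sample_id in phenotype table")
    return records


# ---------------------------------------------------------------------------
# writers


def _fmt(value) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, float):
        if np.isnan(value):
            return MISSING_TOKEN
        if float(value).is_integer() and abs(value) < 1e15:
            return str(int(value))
        return f"{value:.6g}"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    return str(value)


def write_results(records: Sequence, path: str | Path) -> None:
    """Write any homogeneous list of result dataclasses as TSV.

    Floats are rendered with 6 significant digits; output is byte-stable
    for identical input.  An empty list yields a header-only file when the
    record type can be inferred, otherwise an empty file.
    """
    rows = records_to_rows(records)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if not rows:
            fh.write("")
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r[c]) for c in cols) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the same TSV dialect (NA for missing)."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN, float_format="%.6g")


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\t" + "\t".join(gm.rsids) + "\n")
        for i, sid in enumerate(gm.samples):
            cells = [
                MISSING_TOKEN if not np.isfinite(d) else str(int(d))
                for d in gm.dosage[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def write_variants(variants: Iterable[VariantInfo], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("rsid\tchrom\tpos\tgene\tminor_allele\tmajor_allele\n")
        for v in variants:
            fh.write(
                f"{v.rsid}\t{v.chromosome}\t{v.position}\t{v.gene}\t"
                f"{v.minor_allele}\t{v.major_allele}\n"
            )


def write_phenotypes(samples: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\tsex\tstatus\t" + "\t".join(TRAITS) + "\n")
        for s in samples:
            cells = [
                MISSING_TOKEN if getattr(s, t) is None else str(getattr(s, t))
                for t in TRAITS
            ]
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.status}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("sexassoc").joinpath("data", name))


def load_enrichment_reference() -> list[EnrichmentTable]:
    """Per-trait 2x2 protective/risk counts of the published study.

    The integer counts were reconstructed from the published percentages
    and pooled totals (107 female-protective vs 75 male-protective
    significant SNP-trait associations); see the packaged file's header.
    Tests are not attached — run them with
    :func:`sexassoc.enrichment.attach_tests`.
    """
    df = pd.read_csv(_data_path("enrichment_reference.tsv"), sep="\t", comment="#")
    return [
        EnrichmentTable(
            trait=r.trait,
            prot_f=int(r.prot_f),
            risk_f=int(r.risk_f),
            prot_m=int(r.prot_m),
            risk_m=int(r.risk_m),
        )
        for r in df.itertuples()
    ]


def load_melanoma_reference() -> pd.DataFrame:
    """Published sex-stratified melanoma ORs/CIs for 16 SNPs.

    Columns: gene, rsid, chrom, minor_allele, then per sex the printed
    P value, OR and 95% CI bounds, and the printed sex-differentiated P.
    Used by the reanalysis path that reconstructs beta/SE from printed
    OR/CI pairs.
    """
    return pd.read_csv(
        _data_path("melanoma_reference.tsv"), sep="\t", comment="#", dtype={"chrom": str}
    )
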