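"""End-to-end pipeline: QC -> per-sex association -> sex-differentiated
tests -> enrichment -> plots, with a manifest recording inputs, config
and seed for reproducibility.

The stages can be driven from files (genotype/variant/phenotype TSVs) or
from a simulation block; every output lands in one directory tree:

    out/
      qc/        hwe.tsv  maf.tsv  qc_report.txt
      assoc/     assoc_<outcome>_<stratum>.tsv   (7 outcomes x 2 sexes)
      sexdiff/   sexdiff_<outcome>.tsv
      enrichment/enrichment.tsv
      figures/   volcano_*.png  manhattan_*.png  maf_scatter.png  enrichment_bars.png
      manifest.json

With ``resume=True`` stages whose outputs already exist are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .datamodel import OUTCOMES, TRAITS, DataError
from . import assoc as assoc_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import plots as plots_mod
from . import qc as qc_mod
from . import sexdiff as sexdiff_mod
from .simulate import SimulationConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "sexassoc_run"
    genotypes: str | None = None
    variants: str | None = None
    phenotypes: str | None = None
    genotype_dialect: str = "tsv"
    simulate: SimulationConfig | None = None
    min_call_rate: float = 0.9
    hwe_alpha: float = 0.05
    alpha_report: float = 0.01
    alpha_enrichment: float = 0.05
    alpha_sexdiff: float = 0.05
    x_mode: str = "hemizygous"
    seed: int = 0
    resume: bool = False

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "alpha_report", "alpha_enrichment", "alpha_sexdiff"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise DataError(f"{name} must be in (0,1), got {a}")
        if not 0 <= self.min_call_rate <= 1:
            raise DataError("min_call_rate must be in [0,1]")
        if self.simulate is None and not (self.genotypes and self.phenotypes):
            raise DataError("provide input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            from .simulate import Effect

            effects = [Effect(**e) for e in sim.pop("effects", [])]
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimulationConfig(effects=effects, **sim)
        return cls(simulate=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict.

    Raises on missing inputs before any computation; on a stage failure
    the completed outputs are kept and the manifest records the failure
    point before the exception propagates.
    """
    out = Path(config.out_dir)
    for sub in ("qc", "assoc", "sexdiff", "enrichment", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "inputs": {},
        "stages_completed": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # ---- inputs
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        gm, samples, truth = generate_study(sim)
        io_mod.write_genotypes(gm, out / "genotypes.tsv")
        io_mod.write_variants(gm.variants, out / "variants.tsv")
        io_mod.write_phenotypes(samples, out / "phenotypes.tsv")
        io_mod.write_table(truth, out / "truth.tsv")
        manifest["inputs"]["simulated"] = True
    else:
        for name in ("genotypes", "phenotypes", "variants"):
            p = getattr(config, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        variants = io_mod.read_variants(config.variants) if config.variants else None
        gm = io_mod.read_genotypes(
            config.genotypes, dialect=config.genotype_dialect, variants=variants
        )
        samples = io_mod.read_phenotypes(config.phenotypes)
        by_id = {s.sample_id: s for s in samples}
        missing = [s for s in gm.samples if s not in by_id]
        if missing:
            raise DataError(f"samples with genotypes but no phenotype record: {missing[:5]}")
        samples = [by_id[s] for s in gm.samples]
        for name in ("genotypes", "phenotypes", "variants"):
            p = getattr(config, name)
            if p:
                manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    def done(stage: str, *paths: Path) -> bool:
        return config.resume and all(p.exists() for p in paths)

    try:
        # ---- qc
        gm, report = qc_mod.call_rate_filter(gm, config.min_call_rate)
        logger.info(
            "call-rate filter: %d of %d variants removed (%.1f%%)",
            report.n_removed,
            report.n_input,
            100 * report.removal_fraction,
        )
        gm = qc_mod.orient_minor_allele(gm, samples, x_mode=config.x_mode)
        hwe_paths = (out / "qc/hwe.tsv", out / "qc/maf.tsv", out / "qc/qc_report.txt")
        hwe_results, threshold = qc_mod.hwe_screen(
            gm, samples, alpha=config.hwe_alpha, x_mode=config.x_mode
        )
        mafs, r2 = qc_mod.maf_by_sex(gm, samples, x_mode=config.x_mode)
        if not done("qc", *hwe_paths):
            io_mod.write_results(hwe_results, hwe_paths[0])
            io_mod.write_results(mafs, hwe_paths[1])
            n_out = sum(1 for h in hwe_results if not h.in_hwe)
            with open(hwe_paths[2], "w") as fh:
                fh.write(
                    f"variants in: {report.n_input}\n"
                    f"removed by call rate < {config.min_call_rate}: {report.n_removed} "
                    f"({100 * report.removal_fraction:.1f}%)\n"
                    f"removed rsids: {', '.join(report.removed_rsids) or '-'}\n"
                    f"HWE Bonferroni threshold ({config.hwe_alpha}/{max(1, gm.n_variants)}): "
                    f"{threshold:.6g}\n"
                    f"HWE tests out of equilibrium: {n_out} of {len(hwe_results)}\n"
                    f"female/male MAF R^2: {r2:.4f}\n"
                )
        manifest["stages_completed"].append("qc")
        manifest["qc"] = {
            "n_variants": gm.n_variants,
            "n_removed_call_rate": report.n_removed,
            "hwe_threshold": threshold,
            "maf_r_squared": r2,
        }

        # ---- association scans
        scans: dict[tuple[str, str], list] = {}
        for outcome in OUTCOMES:
            for stratum in ("F", "M"):
                path = out / f"assoc/assoc_{outcome}_{stratum}.tsv"
                res = assoc_mod.assoc_scan(gm, samples, outcome, stratum)
                scans[(outcome, stratum)] = res
                if not done("assoc", path):
                    io_mod.write_results(res, path)
        manifest["stages_completed"].append("assoc")

        # ---- sex-differentiated tests
        sexdiff_results = {}
        for outcome in OUTCOMES:
            res = sexdiff_mod.sexdiff_scan(
                scans[(outcome, "F")],
                scans[(outcome, "M")],
                alpha_het=config.alpha_sexdiff,
            )
            sexdiff_results[outcome] = res
            path = out / f"sexdiff/sexdiff_{outcome}.tsv"
            if not done("sexdiff", path):
                io_mod.write_results(res, path)
        manifest["stages_completed"].append("sexdiff")

        # ---- enrichment over the six traits
        tables = enrich_mod.enrichment_analysis(
            [r for t in TRAITS for r in scans[(t, "F")]],
            [r for t in TRAITS for r in scans[(t, "M")]],
            TRAITS,
            alpha=config.alpha_enrichment,
        )
        if not done("enrichment", out / "enrichment/enrichment.tsv"):
            io_mod.write_results(tables, out / "enrichment/enrichment.tsv")
        pooled = tables[-1]
        manifest["stages_completed"].append("enrichment")
        manifest["enrichment"] = {
            "pooled_prot_f": pooled.prot_f,
            "pooled_prot_m": pooled.prot_m,
            "pooled_p_chi2": pooled.p_chi2,
        }

        # ---- figures
        figures = out / "figures"
        for outcome in ("melanoma", "eye"):
            for stratum in ("F", "M"):
                plots_mod.volcano(
                    scans[(outcome, stratum)],
                    figures / f"volcano_{outcome}_{stratum}.png",
                    threshold=config.alpha_report,
                    title=f"{outcome} ({stratum})",
                )
        plots_mod.manhattan_sexdiff(
            sexdiff_results["melanoma"],
            gm.variants,
            figures / "manhattan_melanoma.png",
            threshold=config.alpha_report,
            title="melanoma sex-differentiated",
        )
        plots_mod.maf_scatter(mafs, figures / "maf_scatter.png", r_squared=r2)
        plots_mod.enrichment_bars(tables[:-1], figures / "enrichment_bars.png")
        manifest["stages_completed"].append("figures")
    except Exception as exc:  # record the failure point, keep partial outputs
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
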