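"""End-to-end orchestration: QC -> GRMs -> pruning -> REML -> scans -> calls.

``RunConfig`` carries every threshold with the standard defaults (MAF 0.05,
missing 0.1, rarest genotype 10, relatedness pruning 0.7, 2 Mb cis window,
2.0 LOD drop, 5 s.d. outlier clip) and round-trips through YAML.
``run_pipeline`` executes the stages in order, logs parameters and row
counts, writes every table as TSV, and finishes with a JSON manifest; a
stage failure leaves partial artifacts plus a manifest naming the failed
stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import eqtl as eqtl_mod
from .genotype_io import (
    PhenotypeVector,
    adjust_phenotype,
    qc_filter,
    read_genotypes,
    read_phenotypes,
)
from .qtl_calling import call_qtls, qtl_table, significance_thresholds
from .relatedness import build_grms, prune_related, write_grm_tsv
from .scan import genome_scan
from .varcomp import reml_fit

logger = logging.getLogger("adqtl")

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    genotypes: str = ""
    genotype_format: str = "tsv-dosage"
    snp_map: str | None = None
    phenotypes: str = ""
    covariates: str | None = None
    expression: str | None = None
    annotation: str | None = None
    traits: list[str] = field(default_factory=list)  # empty = all columns
    out_dir: str = "adqtl_out"
    maf_min: float = 0.05
    missing_max: float = 0.1
    min_genotype_count: int = 10
    prune_threshold: float = 0.7
    sd_clip: float = 5.0
    cis_window: int = 2_000_000
    lod_drop: float = 2.0
    alpha: float = 0.05
    level: str = "suggestive"
    hotspot_min_members: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not self.genotypes:
            raise ConfigError("genotypes path is required")
        if not (0 <= self.maf_min <= 0.5):
            raise ConfigError(f"maf_min {self.maf_min} outside [0, 0.5]")
        if not (0 <= self.missing_max <= 1):
            raise ConfigError(f"missing_max {self.missing_max} outside [0, 1]")
        if self.min_genotype_count < 0:
            raise ConfigError("min_genotype_count must be >= 0")
        if self.prune_threshold <= 0:
            raise ConfigError("prune_threshold must be positive")
        if self.lod_drop <= 0:
            raise ConfigError("lod_drop must be positive")
        if self.level not in ("suggestive", "genomewide"):
            raise ConfigError(f"unknown significance level {self.level!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "failed_stage": None, "config": dataclasses.asdict(config)}
    config.to_yaml(out / "config.yaml")

    def _stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        _stage("qc")
        g = read_genotypes(config.genotypes, config.genotype_format, snp_map=config.snp_map)
        logger.info("loaded %d samples x %d SNPs", g.n_samples, g.n_snps)
        g, qc_report = qc_filter(
            g, config.maf_min, config.missing_max, config.min_genotype_count
        )
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        logger.info(
            "QC (maf>=%g, missing<=%g, rarest>=%d): %d SNPs retained",
            config.maf_min, config.missing_max, config.min_genotype_count, g.n_snps,
        )

        _stage("grm")
        grms = build_grms(g)
        _stage("prune")
        kept = prune_related(
            grms.K_a, threshold=config.prune_threshold, seed=config.seed,
            samples=grms.samples,
        )
        if len(kept) < g.n_samples:
            logger.info(
                "pruned %d of %d samples at |relatedness| > %g",
                g.n_samples - len(kept), g.n_samples, config.prune_threshold,
            )
            keep_idx = [g.samples.index(s) for s in kept]
            g = g.subset_samples(keep_idx)
            grms = build_grms(g)
        write_grm_tsv(out / "grm_additive.tsv", grms.K_a, grms.samples)
        write_grm_tsv(out / "grm_dominance.tsv", grms.K_d, grms.samples)

        pheno = read_phenotypes(config.phenotypes) if config.phenotypes else pd.DataFrame(index=g.samples)
        pheno = pheno.reindex(g.samples)
        covar = read_phenotypes(config.covariates).reindex(g.samples) if config.covariates else None
        traits = config.traits or list(pheno.columns)

        _stage("varcomp")
        thresholds = significance_thresholds(g.n_snps, alpha=config.alpha)
        logger.info(
            "thresholds: suggestive %.1f, genome-wide %.1f (-log10 p, N=%d)",
            thresholds.suggestive_display, thresholds.genomewide_display, g.n_snps,
        )
        vc_rows, all_calls = [], []
        _stage("scan")
        for trait in traits:
            y = adjust_phenotype(
                PhenotypeVector(pheno[trait].to_numpy(dtype=float), trait_name=trait),
                covariates=covar, sd_clip=config.sd_clip,
            )
            vc = reml_fit(y, grms)
            vc_rows.append(
                {
                    "trait": trait, "sigma_a2": vc.sigma_a2, "se_a": vc.se_a,
                    "sigma_d2": vc.sigma_d2, "se_d": vc.se_d,
                    "sigma_e2": vc.sigma_e2, "se_e": vc.se_e,
                    "loglik": vc.loglik, "converged": vc.converged, "n": vc.n,
                }
            )
            scan = genome_scan(y, g, vc, grms)
            scan.to_csv(out / f"scan_{trait}.tsv", sep="\t", index=False)
            all_calls.extend(
                call_qtls(scan, thresholds, level=config.level, trait=trait, drop=config.lod_drop)
            )
        pd.DataFrame(vc_rows).to_csv(out / "varcomp.tsv", sep="\t", index=False)
        _stage("call")
        qtls = qtl_table(all_calls)
        qtls.to_csv(out / "qtls.tsv", sep="\t", index=False)
        logger.info("%d QTLs called at %s level", len(qtls), config.level)

        if config.expression and config.annotation:
            _stage("eqtl")
            expr = read_phenotypes(config.expression).reindex(g.samples)
            annot = eqtl_mod.read_annotation(config.annotation)
            ecalls = eqtl_mod.map_eqtls(
                expr, g, grms, annot, level=config.level, thresholds=thresholds,
                drop=config.lod_drop,
            )
            eqtl_mod.eqtl_table(ecalls).to_csv(out / "eqtls.tsv", sep="\t", index=False)
            _stage("enrich")
            try:
                odds, p, table = eqtl_mod.dominance_cis_trans_enrichment(ecalls)
                enrich = table.copy()
                enrich["odds_ratio"] = odds
                enrich["p"] = p
                enrich.to_csv(out / "enrichment.tsv", sep="\t")
            except ValueError as exc:
                logger.warning("enrichment skipped: %s", exc)
            _stage("hotspots")
            hs = eqtl_mod.detect_hotspots(ecalls, min_members=config.hotspot_min_members)
            pd.DataFrame(
                [
                    {
                        "chrom": h.chromosome, "start": h.start, "end": h.end,
                        "n_members": len(h.members), "n_trans": h.n_trans,
                        "n_distinct_targets": h.n_distinct_targets,
                    }
                    for h in hs
                ]
            ).to_csv(out / "hotspots.tsv", sep="\t", index=False)

        manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
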