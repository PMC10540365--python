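"""Seeded generators for genotypes, traits, and gene/isoform expression.

These generators define the study conditions used throughout the tests:
biallelic SNPs with counted-allele frequency drawn uniformly from the MAF
band surviving QC ([0.05, 0.5]), Hardy-Weinberg genotypes (optionally with
block LD through a shared latent Gaussian), traits with additive
heritability in the 0.2-0.5 range and dominance heritability in the
0.1-0.25 range plus focal QTLs with arbitrary (a, d) effects, and
expression matrices with cis-additive and trans-dominant eQTLs, including
genes whose 1-3 isoforms are under antagonistic or synergistic genetic
control.

Every generator takes an explicit integer seed, derives child streams
deterministically, and is bit-reproducible.  Truth objects record the
planted architecture, including the realised single-locus (V_A, V_D) of
each planted QTL under the classical partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import CIS_WINDOW, FeatureAnnotation, annotate_isoform_counts, sum_isoforms
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeVector,
    SnpRecord,
    encode_additive,
    encode_heterozygote,
)
from .relatedness import GrmPair
from .varcomp import single_locus_partition

__all__ = [
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_expression",
    "make_features",
]

N_CHROMOSOMES = 5
SNP_SPACING = 100_000  # bp; 0.1 Mb grid exercises the 2 Mb cis window

# study-condition defaults for polygenic background (mid-range of the
# additive 0.2-0.5 and dominance 0.1-0.25 bands)
DEFAULT_SIGMA_A2 = 0.3
DEFAULT_SIGMA_D2 = 0.15


@dataclass
class SimulationTruth:
    """Planted architecture serialised alongside every simulated dataset."""

    seed: int
    qtls: dict = field(default_factory=dict)  # trait/feature -> list of effects
    sigma_a2: float = 0.0
    sigma_d2: float = 0.0
    sigma_e2: float = 1.0
    ld_spec: dict | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_blocks: tuple[int, float] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """HWE genotypes on a 5-chromosome grid, 0.1 Mb SNP spacing.

    Per SNP the counted-allele frequency is Uniform(maf_range) and calls
    are Binomial(2, p).  With ``ld_blocks = (size, rho)`` each block of
    ``size`` adjacent SNPs shares an exchangeable latent Gaussian of
    correlation ``rho`` per gamete, thresholded at the allele frequency,
    producing positive within-block LD.  ``missing_rate`` masks calls at
    random with the MISSING code.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    if ld_blocks is None:
        calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    else:
        size, rho = ld_blocks
        if size < 1 or not 0 <= rho < 1:
            raise ValueError("ld_blocks must be (size >= 1, 0 <= rho < 1)")
        calls = np.zeros((n, m), dtype=np.int8)
        thresh = stats.norm.ppf(p)  # latent < thresh -> counted allele
        for start in range(0, m, size):
            stop = min(start + size, m)
            width = stop - start
            for _gamete in range(2):
                shared = rng.standard_normal((n, 1))
                noise = rng.standard_normal((n, width))
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
                calls[:, start:stop] += (z < thresh[start:stop]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    per_chrom = -(-m // N_CHROMOSOMES)  # ceil
    snps = []
    for j in range(m):
        chrom = j // per_chrom + 1
        offset = j % per_chrom
        snps.append(
            SnpRecord(
                id=f"snp{j:05d}",
                chromosome=str(chrom),
                position=(offset + 1) * SNP_SPACING,
            )
        )
    samples = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix.from_calls(samples, snps, calls)


def _grm_factor(K: np.ndarray) -> np.ndarray:
    """Factor L with L L' = K, eigen-flooring negatives to zero."""
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def simulate_trait(
    g: GenotypeMatrix,
    qtls: list[tuple[str, float, float]],
    sigma_a2: float = DEFAULT_SIGMA_A2,
    sigma_d2: float = DEFAULT_SIGMA_D2,
    sigma_e2: float | None = None,
    grms: GrmPair | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[PhenotypeVector, SimulationTruth]:
    """Trait with focal QTLs plus polygenic background and noise.

    ``qtls`` is a list of (snp_id, a, d): genotypic values 0 / a + d / 2a
    for 0/1/2 copies of the counted allele.  The polygenic terms are
    ``g_a ~ N(0, K_a sigma_a2)`` and ``g_d ~ N(0, K_d sigma_d2)`` through
    eigen-floored factors of the GRMs (omitted when ``grms`` is None), and
    ``e ~ N(0, I sigma_e2)`` with ``sigma_e2`` defaulting to
    ``1 - sigma_a2 - sigma_d2``.  The returned trait is standardised; the
    truth records each planted QTL's realised Falconer (V_A, V_D).
    """
    if sigma_e2 is None:
        sigma_e2 = max(1.0 - sigma_a2 - sigma_d2, 0.0)
    if min(sigma_a2, sigma_d2, sigma_e2) < 0:
        raise ValueError("variance components must be non-negative")
    n = g.n_samples
    rng = np.random.default_rng(seed)
    snp_index = {s.id: j for j, s in enumerate(g.snps)}
    xa = encode_additive(g)
    xh = encode_heterozygote(g)
    y = np.zeros(n)
    truth_qtls = []
    for snp_id, a, d in qtls:
        if snp_id not in snp_index:
            raise KeyError(f"QTL SNP {snp_id!r} not in genotype matrix")
        j = snp_index[snp_id]
        y += a * xa[:, j] + d * xh[:, j]
        p = float(xa[:, j].mean() / 2.0)
        va, vd = single_locus_partition(a, d, p) if 0 < p < 1 else (0.0, 0.0)
        truth_qtls.append(
            {"snp_id": snp_id, "a": a, "d": d, "freq": p, "v_a": va, "v_d": vd}
        )
    if grms is not None and (sigma_a2 > 0 or sigma_d2 > 0):
        if sigma_a2 > 0:
            y += np.sqrt(sigma_a2) * (_grm_factor(grms.K_a) @ rng.standard_normal(n))
        if sigma_d2 > 0:
            y += np.sqrt(sigma_d2) * (_grm_factor(grms.K_d) @ rng.standard_normal(n))
    if sigma_e2 > 0:
        y += np.sqrt(sigma_e2) * rng.standard_normal(n)
    if standardize:
        y = (y - y.mean()) / y.std()
    truth = SimulationTruth(
        seed=seed,
        qtls={"trait": truth_qtls},
        sigma_a2=sigma_a2,
        sigma_d2=sigma_d2,
        sigma_e2=sigma_e2,
    )
    return PhenotypeVector(values=y, trait_name="sim_trait", samples=list(g.samples)), truth


def make_features(
    g: GenotypeMatrix,
    n_genes: int,
    isoforms_per_gene: list[int] | int = 1,
    gene_span: int = 20_000,
    seed: int = 0,
) -> list[FeatureAnnotation]:
    """Gene/isoform annotation laid out across the simulated genome.

    Genes are placed at evenly spaced SNP positions (so each has SNPs
    within the cis window); each gene expresses 1-3 isoforms named
    ``<gene>_iso<k>`` sharing the gene span.
    """
    if isinstance(isoforms_per_gene, int):
        iso_counts = [isoforms_per_gene] * n_genes
    else:
        iso_counts = list(isoforms_per_gene)
        if len(iso_counts) != n_genes:
            raise ValueError("isoforms_per_gene must match n_genes")
    anchors = np.linspace(0, g.n_snps - 1, n_genes).astype(int)
    feats: list[FeatureAnnotation] = []
    for gi, (anchor, n_iso) in enumerate(zip(anchors, iso_counts)):
        rec = g.snps[int(anchor)]
        gene = f"gene{gi:04d}"
        for k in range(n_iso):
            feats.append(
                FeatureAnnotation(
                    feature_id=f"{gene}_iso{k}" if n_iso > 1 else gene,
                    gene_id=gene,
                    chromosome=rec.chromosome,
                    start=rec.position,
                    end=rec.position + gene_span,
                )
            )
    return annotate_isoform_counts(feats)


def simulate_expression(
    g: GenotypeMatrix,
    annot: list[FeatureAnnotation],
    cis_genes: list[str] | None = None,
    trans_genes: list[str] | None = None,
    antagonistic_genes: list[str] | None = None,
    cis_effect: float = 0.6,
    trans_effect: float = 0.6,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Expression matrices with planted cis-additive / trans-dominant eQTLs.

    * cis genes: every isoform gets an additive effect (``cis_effect``)
      from a SNP within the 2 Mb cis window of the gene (error if none).
    * trans genes: every isoform gets a heterozygote-coded (dominance)
      effect (``trans_effect``) from a SNP on a different chromosome.
    * antagonistic genes (must have >= 2 isoforms): the first two isoforms
      receive +effect and -effect from the same shared cis SNP, so the
      gene-level sum has attenuated signal while each isoform is under
      strong genetic control.

    Returns (isoform matrix, gene matrix = sum of isoforms, truth).
    """
    cis_genes = list(cis_genes or [])
    trans_genes = list(trans_genes or [])
    antagonistic_genes = list(antagonistic_genes or [])
    rng = np.random.default_rng(seed)
    n = g.n_samples
    xa = encode_additive(g)
    xh = encode_heterozygote(g)
    positions = np.array([s.position for s in g.snps])
    chroms = np.array([s.chromosome for s in g.snps])

    by_gene: dict[str, list[FeatureAnnotation]] = {}
    for f in annot:
        by_gene.setdefault(f.gene_id, []).append(f)

    def _cis_snp(feat: FeatureAnnotation) -> int:
        near = np.flatnonzero(
            (chroms == feat.chromosome)
            & (np.minimum(np.abs(positions - feat.start), np.abs(positions - feat.end)) < CIS_WINDOW)
        )
        if near.size == 0:
            raise ValueError(f"no SNP within 2 Mb of cis gene {feat.gene_id}")
        return int(rng.choice(near))

    def _trans_snp(feat: FeatureAnnotation) -> int:
        away = np.flatnonzero(chroms != feat.chromosome)
        if away.size == 0:
            raise ValueError("need at least two chromosomes for trans effects")
        return int(rng.choice(away))

    iso = {}
    truth_qtls: dict[str, list] = {}
    for f in annot:
        iso[f.feature_id] = noise_sd * rng.standard_normal(n)
        truth_qtls[f.feature_id] = []

    for gene in antagonistic_genes:
        feats = by_gene[gene]
        if len(feats) < 2:
            raise ValueError(f"antagonistic gene {gene} needs >= 2 isoforms")
        j = _cis_snp(feats[0])
        for f, sign in zip(feats[:2], (1.0, -1.0)):
            beta = sign * cis_effect
            iso[f.feature_id] += beta * xa[:, j]
            truth_qtls[f.feature_id].append(
                {"snp_id": g.snps[j].id, "a": beta, "d": 0.0, "kind": "cis-antagonistic"}
            )

    for gene in cis_genes:
        if gene in antagonistic_genes:
            continue
        for f in by_gene[gene]:
            j = _cis_snp(f)
            iso[f.feature_id] += cis_effect * xa[:, j]
            truth_qtls[f.feature_id].append(
                {"snp_id": g.snps[j].id, "a": cis_effect, "d": 0.0, "kind": "cis-additive"}
            )

    for gene in trans_genes:
        for f in by_gene[gene]:
            j = _trans_snp(f)
            iso[f.feature_id] += trans_effect * xh[:, j]
            truth_qtls[f.feature_id].append(
                {"snp_id": g.snps[j].id, "a": 0.0, "d": trans_effect, "kind": "trans-dominant"}
            )

    iso_df = pd.DataFrame(iso, index=list(g.samples))
    gene_df = sum_isoforms(iso_df, annot)
    truth = SimulationTruth(
        seed=seed,
        qtls=truth_qtls,
        sigma_a2=0.0,
        sigma_d2=0.0,
        sigma_e2=noise_sd**2,
    )
    return iso_df, gene_df, truth
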