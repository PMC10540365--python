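# adqtl — additive + dominance QTL mapping

Most genome-wide association scans assume alleles act additively, yet at a
biallelic locus the heterozygote need not sit at the midpoint of the two
homozygotes.  `adqtl` is a toolkit for quantitative-genetic analyses that
model **both** additive and dominance effects throughout: variance
decomposition with two genomic relationship matrices, mixed-model
association scans with joint additive + heterozygote fixed effects, QTL
calling with degree-of-dominance classification, and eQTL layers
(cis/trans annotation, dominance enrichment, trans-eQTL hotspots,
isoform-level analyses).  It is aimed at analyses of experimental mammal
populations (F2 intercrosses, heterogeneous stocks) where intermediate
allele frequencies make dominance detectable, and it ships a seeded
synthetic-data generator so every stage can be validated against known
truth.

## The model

For a trait `y` (covariate-adjusted, unit variance) and genotypes coded as
additive dosage `x ∈ {0,1,2}` and heterozygote dosage `h ∈ {0,1,0}`:

* **Variance decomposition.**  `y ~ N(Xβ, V)` with
  `V = K_a σ²_a + K_d σ²_d + I σ²_e`, where `K_a` is the
  column-standardised additive GRM (`z = (x − 2p)/√(2pq)`) and `K_d` the
  orthogonal dominance GRM (genotype codes `−2p², 2pq, −2q²` scaled by
  `2pq`).  Components are estimated by AI-REML with an EM safeguard and a
  non-negativity constraint; on a unit-variance trait they are the
  additive and dominance heritabilities (V_a, V_d).
* **Association scans.**  Whitening by `V^{−1/2}` turns the mixed model
  into OLS with i.i.d. errors.  Per SNP, three designs are fitted: the A
  model (intercept + `x`), the D model (intercept + `h`), and the AD model
  (intercept + `x` + `h`).  `p_AD` is the 2-df test of the AD model
  against the null; `p_AvsAD` the 1-df dominance test of AD against A
  (identical to the t-test on the heterozygote coefficient, F = t²).
* **Thresholds.**  Suggestive `−log10 p = log10(N_SNP)` (one false
  positive expected per scan) and genome-wide `log10(N_SNP/0.05)`.
* **Classification.**  The degree-of-dominance ratio `|t_Dom/t_Add|`
  assigns each QTL to additive (< 0.2), partial- (0.2–0.8), complete-
  (0.8–1.2) or over-dominance (≥ 1.2).
* **QTL intervals.**  2-LOD-drop intervals from iterative peak-picking;
  the explained variance at a peak is partitioned by the classical
  single-locus formulas `V_A = 2pq[a + d(q−p)]²`, `V_D = (2pq·d)²`.
* **eQTLs.**  cis if the peak SNP is within 2 Mb of the target gene span
  on the same chromosome, else trans; classes collapse to G-Add (A+PD) vs
  G-Dom (CD+OD) for Fisher-exact enrichment against cis/trans, chi-squared
  enrichment against isoform counts, and overlap-based hotspot and
  cross-tissue colocalisation summaries.

## Worked example

```python
import pandas as pd
from adqtl import *
from adqtl.relatedness import build_grms
from adqtl.qtl_calling import qtl_table

g = simulate_genotypes(n=500, m=1000, seed=42)          # 5 chromosomes, HWE
grms = build_grms(g)
y, truth = simulate_trait(                              # one additive QTL,
    g, qtls=[("snp00357", 0.4, 0.0),                    # one pure-dominance QTL
             ("snp00748", 0.0, 0.6)],
    sigma_a2=0.25, sigma_d2=0.12, grms=grms, seed=43,
)

vc = reml_fit(y, grms)
print(f"sigma_a2 = {vc.sigma_a2:.3f} (SE {vc.se_a:.3f})")
print(f"sigma_d2 = {vc.sigma_d2:.3f} (SE {vc.se_d:.3f})")
print(f"sigma_e2 = {vc.sigma_e2:.3f} (SE {vc.se_e:.3f})")

scan = genome_scan(y, g, vc, grms)
th = significance_thresholds(g.n_snps)
calls = call_qtls(scan, th, level="genomewide", trait="sim_trait")
print(qtl_table(calls)[["peak_snp", "chrom", "peak_logp_AD", "logp_A",
                        "ratio", "class", "v_a_qtl", "v_d_qtl",
                        "novel_vs_A"]].round(3).to_string(index=False))
```

prints

```
sigma_a2 = 0.265 (SE 0.099)
sigma_d2 = 0.039 (SE 0.085)
sigma_e2 = 0.697 (SE 0.125)
peak_snp chrom  peak_logp_AD  logp_A  ratio class  v_a_qtl  v_d_qtl  novel_vs_A
snp00357     2         7.843   8.023  0.342    PD    0.068    0.006       False
snp00748     4         6.765   0.191  4.833    OD    0.000    0.059        True
```

The REML fit attributes most heritability to the additive component (the
planted dominance QTL contributes only ≈ 0.06 to V_d, within one SE of the
estimate).  Both planted loci are genome-wide significant under the AD
model (`peak_logp_AD` above the genome-wide threshold of 4.3 for 1,000
SNPs).  The additive locus is equally visible to the additive-only scan
(`logp_A = 8.0`), while the pure-dominance locus is *invisible* to it
(`logp_A = 0.19`), is classified over-dominant (ratio 4.8), and is flagged
`novel_vs_A` — the class of association an additive-only GWAS silently
misses.

## Command line

```bash
adqtl simulate --n 500 --m 1000 --seed 1 --qtl snp00357:0.4:0 --out data/
adqtl run --genotypes data/genotypes.tsv --phenotypes data/phenotypes.tsv \
          --out results/run1
adqtl scan --genotypes data/genotypes.tsv --snp-map data/snp_map.tsv \
           --phenotypes data/phenotypes.tsv --trait trait --out scan.tsv
```

`adqtl run` executes QC → GRMs → relatedness pruning → REML → scans →
QTL/eQTL calling from a YAML config (all thresholds default to the
standard values: MAF ≥ 0.05, missing rate ≤ 0.1, rarest genotype ≥ 10,
pruning at |relatedness| > 0.7, 2 Mb cis window, 2-LOD drop, 5 s.d.
outlier clip) and writes TSV tables plus a JSON manifest.

Genotype dialects: PLINK text (`.ped/.map`), PLINK binary
(`.bed/.bim/.fam`, SNP-major), and a TSV dosage matrix (header row of SNP
ids, first column the sample id, `NA` for missing).

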