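# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `adqtl`, together with what the synthetic-data
generator does and does not emulate.

## Genotype model and codings

Genotypes are biallelic SNP calls, 0/1/2 copies of a counted allele
(missing = −1).  Two fixed-effect codings are used everywhere:

* additive dosage `x`: AA/AB/BB → 0/1/2;
* heterozygote dosage `h`: AA/AB/BB → 0/1/0.

Any single-locus genotype–phenotype map can be written as
`β_a·x + β_d·h`, so the AD design spans additive, partial-, complete- and
over-dominant architectures.  Missing calls are mean-imputed per column by
the encoders, which keeps the sample size constant across SNPs and leaves
degrees-of-freedom bookkeeping simple; this is adequate at the low
missingness rates that survive QC (≤ 10%).

SNP QC keeps markers with MAF ≥ 0.05, missing rate ≤ 0.1 and every
genotype class observed in at least 10 individuals.  The rarest-genotype
rule matters specifically for dominance work: the heterozygote contrast is
unidentifiable when one homozygote class is (nearly) empty.  Where a SNP
with only two observed genotype classes nevertheless reaches a scan
(e.g. QC relaxed on small simulated panels), the AD design is rank-
deficient (`h` is collinear with the intercept and `x`); the scan then
reports the A-model fit for that SNP with `β_d = 0` and flags it
`ad_collinear` rather than failing.

Phenotype preparation follows the standard order: outliers beyond 5 s.d.
of the raw trait mean are set missing first, then covariates are removed
by OLS (dummy-coded factors, redundant columns dropped with a warning),
then residuals are standardised to mean 0, variance 1.  Covariate
regression is refit per trait.  Expression traits are prepared with the
rank-based inverse normal transform using the Blom offset
`(rank − 3/8)/(n + 1/4)`, ties sharing the average rank.

## Relationship matrices

`K_a` uses the column-standardised coding `z = (x − 2p)/√(2pq)`;
`K_d` uses the dominance-deviation recode 0/`2p`/`4p−2` centred by `2p²`
and scaled by `2pq` (standardised codes `−2p², 2pq, −2q²` over `2pq`).
Both are `(1/m)ZZ'`.  Under Hardy–Weinberg equilibrium the two codings
are uncorrelated, which is what makes σ²_a and σ²_d separable in a joint
fit.  Allele frequencies are in-sample frequencies, recomputed after QC
and after relatedness pruning; missing calls contribute zero after
centring and the denominator is the total SNP count.  Pairs with
|K_a entry| > 0.7 are randomly downsampled to single individuals with a
seed-deterministic loop (uniform random offending pair, uniform random
member), after which the GRMs are rebuilt on the retained samples.  The
pruning threshold is applied to K_a entries directly, treating them as
additive genetic correlations.

## REML

`reml_fit` maximises the restricted likelihood of
`y ~ N(Xβ, K_aσ²_a + K_dσ²_d + Iσ²_e)` by average-information REML:

* start at (⅓, ⅓, ⅓)·var(y); the first step is an EM update;
* subsequent steps solve the AI system on the free components only — a
  component pinned at the floor (10⁻⁸·var(y)) whose score still points
  outward is held fixed (active set);
* the AI step is projected onto the feasible box; if it would decrease
  the likelihood, halved steps (1, ½, ¼, 1/10) are tried and the EM update
  is the last resort;
* convergence when |Δ log-likelihood| < 10⁻⁶, at most 100 iterations; a
  non-converged fit is returned with `converged = False`, never raised;
* standard errors come from the inverse AI matrix at the optimum;
* if a variance matrix loses positive-definiteness numerically, its
  eigenvalues are clipped before the Cholesky factorisation.

Components are constrained non-negative (the usual GREML convention);
with unconstrained software a trait whose unconstrained optimum is
negative will instead show a small negative estimate where we report a
boundary value.  The fit with the dominance component omitted
(`include_dominance=False`) gives the nested single-GRM model used for
likelihood comparisons.

## Scans

Variance components are estimated once per trait and the whitening
`W = V^{−1/2}` (symmetric inverse square root; eigenvalues floored at
10⁻⁸ of the maximum before inversion) is reused at every SNP, so a scan
costs one eigendecomposition plus an O(n·m) batched OLS.  This two-stage
scheme is the standard mixed-model GWAS approximation; it does not refit
the variance components per SNP.  The per-SNP tests are

* `p_A`: t-test on the dosage coefficient in the A model;
* `p_D`: t-test on the heterozygote coefficient in the D model;
* `p_AD`: 2-df F-test of the AD model against the base (intercept +
  conditioning columns) — the headline statistic for calling;
* `p_AvsAD`: 1-df F-test of AD against A, algebraically the square of the
  heterozygote t-statistic; this is the dominance-specific test.

Conditional scans append the additive and heterozygote dosages of the
conditioning SNPs to the base design (whitened); collinear conditioning
columns are dropped via an orthonormal basis of the base span, which
leaves all SNP tests unchanged because only that span matters.

Monomorphic dosage columns yield p = 1 with a `monomorphic` flag; a
single bad SNP never aborts a scan.

## Calling, classification, intervals

Suggestive and genome-wide thresholds are `log10(N)` and `log10(N/0.05)`
on the −log10 p scale.  Calls compare exact values; the one-decimal
*floor* is display-only (reproducing the conventional printed values,
e.g. 4.5/5.8 at N = 39,298 and 3.9/5.2 at N = 9,142).  "LOD" here is
−log10 p, the common usage in this GWAS literature.

QTLs are called per chromosome by iterative peak-picking: strongest
remaining SNP above threshold, 2-LOD-drop interval (boundary = last SNP
before the first one that falls more than `drop` below the peak), members
assigned, repeat.  The walk is restricted to the contiguous run of
still-unassigned SNPs around the peak so intervals never span a
previously called QTL; intervals are therefore disjoint by construction.
"Independent QTLs" are exactly these disjoint intervals — no merging rule
is applied; conditional scans are available for finer dissection.

The degree-of-dominance ratio is `|t_Dom/t_Add|` with left-closed bands
A < 0.2 ≤ PD < 0.8 ≤ CD < 1.2 ≤ OD (closing the bands removes the
measure-zero gaps of strict inequalities).  The bands apply to the raw
ratio; log2 of the ratio is reported for plotting only.  `t_Add = 0` with
`t_Dom ≠ 0` is treated as an infinite ratio (OD); both zero degenerates
to A with a flag.  Explained variance at a peak uses the classical
single-locus partition `V_A = 2pq[a + d(q−p)]²`, `V_D = (2pq·d)²` with
`a = β_a`, `d = β_d` and the counted-allele frequency `p`; summing over
peak SNPs gives the trait-level QTL-explained (V_a, V_d).

## eQTL layers

cis/trans: cis iff the peak SNP shares the target's chromosome and the
minimum distance to the gene span boundaries is strictly less than 2 Mb
(distance 0 inside the span; invariant to start/end labelling).  Classes
collapse to G-Add (A + PD) and G-Dom (CD + OD).  Enrichment of dominance
among trans-eQTLs uses the two-sided Fisher exact test on the
(G-Add, G-Dom) × (cis, trans) table; isoform-count enrichment uses the
1-df Pearson chi-squared without continuity correction, reporting the
G-Dom:G-Add ratio per stratum and attaching a warning when an expected
cell is below 1.  Hotspots are connected components of the
interval-overlap graph per chromosome (computed by a sorted sweep, which
yields exactly the transitive closure for genomic intervals), reported at
≥ 5 members by default — a package choice, as no standard count threshold
exists.  Cross-tissue pairs with overlapping intervals are
tissue-consistent if they regulate the same gene, else tissue-specific.
Isoform pairs with overlapping eQTL intervals are antagonistic when their
signed additive effects at the respective peaks have opposite signs,
synergistic when the same sign, and independent when the intervals are
disjoint — an operational criterion chosen here because the phenomenon is
usually shown only as genotype-stratified scatter plots.

Per-feature eQTL mapping runs REML per expression feature by default; a
shared `VarianceComponents` may be passed to amortise cost across
thousands of features (with essentially unrelated samples the whitening
is close to the identity and this approximation is mild).

## Synthetic data

The generator defines the study conditions used by the tests:

* genotypes: counted-allele frequency ~ Uniform(0.05, 0.5) per SNP,
  Binomial(2, p) per individual (HWE), on a 5-chromosome grid at 0.1 Mb
  spacing so the 2 Mb cis window and interval logic are exercised;
  optional block LD via an exchangeable latent Gaussian per gamete;
  optional uniform missingness;
* traits: focal QTLs with genotypic values 0/(a+d)/2a, polygenic terms
  drawn through eigen-floored factors of K_a and K_d, Gaussian noise;
  defaults σ²_a = 0.3, σ²_d = 0.15 (mid-range of the additive 0.2–0.5 and
  dominance 0.1–0.25 heritability bands typical of these stocks); traits
  standardised; the truth object records each planted QTL's realised
  single-locus (V_A, V_D);
* expression: cis genes get additive effects from SNPs within 2 Mb,
  trans genes get heterozygote-coded effects from other chromosomes,
  antagonistic genes get ±β at a shared cis SNP on their first two
  isoforms; gene expression is always the sum of its isoforms.

Not emulated: heterogeneous-stock founder mosaics and F2 pedigree
structure, recombination maps, selection, and population structure beyond
the GRM-mediated polygenic terms.  Passing tests therefore demonstrate
correctness of the statistical machinery under idealised HWE/LD
conditions, not robustness to the haplotype structure of real stocks.

## Problem sizes and determinism

Simulation-based checks use n = 500–800 individuals and m = 2,000 SNPs
with 20 seeds for parameter-recovery and power studies, and n = 400–500
with a few hundred SNPs/features for the eQTL constructions — sizes at
which the expected effects are comfortably identifiable while a full
validation run stays in the minutes range on one CPU.  All generators
take explicit integer seeds, derive child streams deterministically
(`numpy` SeedSequence), and are bit-reproducible; pipeline reruns with
identical config and seed produce byte-identical tables.

## Known limitations

* No leave-one-chromosome-out GRMs: the focal SNP contributes to the
  background covariance, giving slight proximal contamination
  (conservative at these panel sizes).
* Exact per-SNP mixed-model refits and score-test speedups are out of
  scope; the two-stage whitening is the intended approximation.
* Column-mean imputation only; no reference-panel imputation.
* Fisher/chi-squared delegate to scipy; the Fisher implementation is an
  exact enumeration at any table size.
* X-chromosome dosage compensation and multi-allelic sites are not
  handled.
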