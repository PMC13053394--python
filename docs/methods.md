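# Methods

`sspleio` implements the complete computational chain of a single-step
genomic evaluation and GWAS for repeated-record cattle traits, followed by
a Cholesky-decorrelated multi-trait (pleiotropy) meta-analysis and
window-based gene/QTL annotation. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generator does and does not emulate.

## 1. Single-trait evaluation model

Each trait is analysed with a repeatability animal model

    y = Xb + Za + W pe + e

where `y` are the phenotypic records, `b` the fixed effects, `a` the
additive genetic effects over all pedigree animals with
Var(a) = **H** σ²a, `pe` the permanent-environment effects (one per
recorded animal, shared by that animal's repeated records) with
Var(pe) = I σ²pe, and Var(e) = I σ²e.

Fixed effects follow common practice for mature-cow-size evaluations:
contemporary group (herd–year–season) and parity as class effects, and age
in days as a linear covariate nested within age-in-years class (one slope
per year class; the age covariate is mean-centred for conditioning).
Identifiability: the first level of each class factor is constrained to
zero, so the reported coefficients are contrasts against that reference
level.

Variance components are *inputs*, not estimated — matching evaluation
practice where they are fixed at previously published pedigree-based
estimates. No REML or Gibbs machinery is included.

Henderson's mixed-model equations are assembled with λa = σ²e/σ²a
multiplying **H⁻¹** and λpe = σ²e/σ²pe on the pe block and solved by dense
Cholesky factorization (the package targets desk-scale problems of up to a
few thousand animals; relative-residual tolerance 1e-10, with a
pseudo-inverse fallback for rank-deficient fixed blocks that logs the
constrained columns).

## 2. Relationship matrices

* **A** — numerator relationship matrix, tabular method.
* **A⁻¹** — Henderson's rules with inbreeding; Mendelian-sampling variance
  d = 0.5 − 0.25(F_s + F_d) (one/no-parent variants accordingly), with F
  taken from the tabular A diagonal. Equality with the dense inverse of A
  is a tested invariant.
* **G** — VanRaden method I: G = ZZ′ / 2Σp_i(1−p_i), Z the allele counts
  centred by 2p_i, frequencies observed in the post-QC genotyped set
  (base-population frequencies are unavailable in practice). Missing
  genotypes are mean-imputed (2p) beforehand.
* **Blending** — G is blended as 0.95 G + 0.05 A22 by default before
  inversion. The weight follows the conventional default of evaluation
  software; with observed-frequency centring G is singular by construction
  (its rows sum to zero because Z′1 = 0), so some blend is mandatory, and
  the weight used is carried in the object's metadata. No tuning of G's
  mean to A22 is applied by default.
* **H⁻¹** = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹] with the correction block scattered
  onto the genotyped indices. Tested degenerate identities: with no
  genotyped animals, and with G := A22, H⁻¹ equals A⁻¹.

## 3. SNP effects from GEBVs (ssGWAS)

SNP substitution effects are back-solved from the GEBVs of the genotyped
animals under the equal-variance (infinitesimal) assumption:

    û = Z′ (ZZ′)⁻¹ â

Since ZZ′ = scale · G is singular with observed-frequency centring, the
inverse is taken of the *blended* ZZ′ (scale × blended G) — the same
regularization used in the evaluation itself. A trace-scaled ridge
(1e-8 · tr/n) is the fallback when no blend is available; its use is
warned about.

Standard errors propagate linearly: with K = Z′(ZZ′)⁻¹,
Var(û) = K Var(â) K′, where Var(â) = G σ²a − PEV(â) is the covariance of
the GEBV *estimates* (for BLUP with known variances,
Cov(â, a) = Var(â)); PEV comes from the inverse of the MME coefficient
matrix times σ²e. Var(â) is symmetrized and eigenvalue-floored at zero.

P-values are two-sided standard normal, p = 2(1 − Φ(|û/SD(û)|)). The
per-SNP share of additive variance is reported as 2p(1−p)û²/σ²a (additive
over disjoint SNP sets; LD covariance between SNPs is ignored, so sums
over dense regions overstate the joint contribution).

**Multiple testing.** Chromosome-wise Bonferroni thresholds are based on
the effective number of independent chromosomal segments,

    Me_c = 2 · Ne · L_c / ln(4 · Ne · L_c),    α_c = 0.05 / Me_c

with Ne = 182 (a published effective population size for American Angus)
and L_c the chromosome length in Morgans at the 1 cM/Mb convention.
The exact segment formula is not uniquely fixed in the literature chain
this follows (Goddard/Corbin variants differ in constants); the form above
is flagged prominently here and in the configuration. Both per-chromosome
lengths (default) and a genome-average length are supported. Significance
is called at p ≤ α_c (boundary inclusive).

## 4. Pleiotropy meta-analysis

1. Records are pre-adjusted for fixed effects (y − Xb̂) and averaged per
   animal, one value per animal per trait.
2. Traits are z-scored on complete-case means/SDs; COV, the covariance of
   the z-scores on complete cases, is their correlation matrix (its
   diagonal is set to exactly 1 so the transform is exact).
3. Cholesky scores c = L⁻¹ g with L L′ = COV, in the fixed trait order
   body condition score → mature weight → mature height. CT_1 is the first
   z-scored trait; CT_j is trait j corrected for traits 1..j−1. An animal
   receives CT_j when it observes traits 1..j of the order (so CT record
   counts decrease along the order, mirroring unbalanced real data); COV
   is estimated on complete cases only.
4. Each CT is analysed with a mean-only animal model (the phenotypes are
   already adjusted). Genotyped-only GBLUP on the blended G is the default
   analysis set; a single-step mode over the full pedigree with H⁻¹ is
   available. The variance ratio is derived from the source trait's
   components and the mean record count per animal,
   h²_eff = σ²a / (σ²a + σ²pe + σ²e/m̄), because averaging m records leaves
   the permanent-environment variance whole but shrinks the residual;
   per-CT values can be supplied instead.
5. Signed t-values t = û/SD(û) feed the per-SNP multi-trait statistic
   χ² = t′ V⁻¹ t with V the correlation matrix of signed t-values across
   all SNPs, referred to χ² with k = 3 degrees of freedom, and the same
   chromosome-wise Bonferroni thresholds.

V is inverted by pseudo-inverse with a condition-number warning above 1e8
(near-duplicated CTs). Changing the trait order changes the CTs but leaves
the χ² invariant up to Monte-Carlo noise once V is re-estimated — a tested
property, not an identity.

## 5. Quality control

Phenotypes, in order, applied once (non-iteratively): age window 1–15
years; contemporary groups with fewer than 3 animals removed; per-CG
3-SD outlier removal for the measured traits (weight, height); removal of
zero-variance CGs for the scored trait (body condition). Genotypes, in
order: unknown/duplicated positions → non-autosomes (1–29 default) → SNP
call rate < 0.90 → animal call rate < 0.90 → MAF < 0.05 → absolute
difference between observed and expected (2p(1−p)) heterozygosity > 0.15.
All inequalities are strict exactly as stated; frequencies for the later
rules are recomputed on retained animals. An exact HWE chi-square p-value
per SNP is emitted for inspection but is not itself a filter. Every filter
logs before/after counts in application order.

## 6. Annotation and enrichment

Significant SNPs get ±100 kb windows (clamped at position 1, never
merged, so each SNP reports its own hits); a gene or QTL-database record
hits a window when the 1-based inclusive intervals intersect on the same
chromosome. Enrichment of QTL trait terms among window-hit records uses
the exact hypergeometric upper tail against the full database background
(optionally stratified by chromosome), Benjamini–Hochberg corrected
across terms with enrichment declared at FDR < 0.05, plus the richness
factor (hit records of the term / background records of the term). The
hypergeometric choice is an assumption — the upstream annotation tooling
this mirrors does not publish its exact statistic — and a one-sided
chi-square approximation is available behind a flag. The six-category
trait grouping (Production, Meat and Carcass, Health, Milk, Exterior,
Reproduction) comes from the QTL-database `trait_type` attribute.

## 7. Synthetic data generator

The generator produces the full data bundle with known truth:

* **Pedigree** — non-overlapping generations, random sire×dam mating
  without selfing, n_founders/2 matings per generation.
* **Genotypes** — founder haplotypes are mosaics of a small ancestral pool
  (default 20 haplotypes): the copied ancestor switches between adjacent
  SNPs with probability 1 − exp(−ld_decay_rate · d) for d bp, giving r²
  that decays with distance; descendants are gene-dropped with Haldane
  (Poisson) recombination at 1 Morgan ≡ 100 Mb. Mendelian consistency and
  monotone r² decay are tested invariants.
* **Phenotypes** — true breeding value = explicit QTL effects on centred
  genotypes + a pedigree-recursive polygenic term (parent average +
  Mendelian sampling with inbreeding-corrected variance), so the polygenic
  variance equals σ²a by construction and QTL signal is cleanly separable
  from polygenic background. Permanent environment is drawn once per
  animal; each record adds CG, parity and nested age-slope effects plus
  residual noise. Optional per-trait missingness emulates unbalanced
  record counts across traits. All randomness is derived from a single
  seed; identical configs give bit-identical outputs.

Defaults represent a moderate-heritability cow-size trait: σ²a = 0.4,
σ²pe = 0.2, σ²e = 0.4 (h² = 0.4, repeatability 0.6), 1–3 records per
animal, 25 contemporary groups with SD 0.5, ages 2–10 years, half the
population genotyped.

**What the generator does not emulate:** selection and assortative mating,
realistic bovine demographic history (the mosaic founder LD is a
phenomenological stand-in), genotyping-platform error patterns,
sex-limited traits, and maternal effects. Passing tests therefore show
that the *algorithms* recover what their assumptions promise under a
correctly specified model — not that the pipeline is robust to model
misspecification in real cattle data.

## 8. Problem sizes used in the test and acceptance runs

Chosen for a one-CPU desk-scale run: oracle equivalence on pedigrees up to
200 animals; GEBV-accuracy replicates on ~2,000-animal pedigrees with
2,000 SNPs and half genotyped; null calibration of the multi-trait test on
~500 genotyped animals × 2,000 SNPs (LD map for the distributional checks,
a sparse low-LD map for significance-count checks, where per-SNP binomial
bounds require near-independent tests); pleiotropy rank-advantage
replicates on 1,000-animal populations with 70% genotyped and a
three-trait QTL at ~7% of σ²a. `scripts/acceptance.py` re-runs the same
chain at these sizes from a single command-line seed.

## 9. Known limitations

* Dense factorizations bound the practical size to a few thousand
  animals; no iteration-on-data or APY-style approximations.
* Single back-solving pass only (no iterative SNP reweighting), by design:
  SNP effects are assumed to share a common variance.
* The variance-explained decomposition ignores LD covariance.
* Unknown-parent groups and metafounders are not modelled.
* The text PLINK dialect (.ped/.map) is supported; binary .bed is not.
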