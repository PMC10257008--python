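# Methods

## The analysis

`transcore` implements an aggregated trans-effect analysis for case-control
studies. The premise is the sparse-effector ("omnigenic") view of complex
disease: most heritability flows through many weak *trans*-acting variants
whose effects converge on the expression of a small set of core effector
genes. Single-SNP tests mostly detect the rarer, larger *cis* effects; a
score that aggregates a gene's many weak *trans*-eQTLs amplifies the signal
of a core gene while bystander genes — whose expression happens to respond to
the same pleiotropic loci without mediating disease — gain little, because
their per-locus disease effects are incoherent in sign and partially cancel
in the sum.

The pipeline, given expression-GWAS summary statistics, an LD reference
panel, and a genotyped case-control study:

1. **Filter and clump.** Per target gene, records with p < `p_retain`
   (default 1e-5) are chained per chromosome into positional clumps:
   consecutive retained SNPs closer than `clump_gap_bp` (1 Mb) join the same
   clump; a clump is kept only if its best p-value is below `p_lead` (1e-6).
   The retain threshold is deliberately more permissive than a genome-wide
   significance level: the goal is prediction, not discovery.
2. **LD-adjust.** For each clump, the Pearson dosage correlation matrix R of
   its SNPs is estimated in the reference panel and the marginal betas β are
   converted to joint weights w = (R + λI)⁻¹β. This approximates the
   coefficients of a multiple regression on individual-level GWAS data.
3. **Score and classify.** Each individual's locus score is the dot product
   of their dosages with w. A locus is *cis* if its minimum distance to the
   target's transcription site is ≤ 50 kb, *cis-x* between 50 kb and 5 Mb,
   and *trans* beyond 5 Mb or on another chromosome (boundaries inclusive on
   the cis side; distance 0 when the clump overlaps the site).
4. **Aggregate.** The genome-wide trans-score of a gene is the plain sum of
   its trans-class locus scores, excluding any locus overlapping the HLA
   region (chr6:25–34 Mb), scaled to unit standard deviation in the analysis
   sample. cis-x loci are reported separately and never aggregated.
5. **Diversity.** The effective number of contributing eQTLs is the Hill
   number 2^(−Σ pᵢ log₂ pᵢ) with pᵢ = σᵢ²/Σσ², σᵢ² the sample variance of
   locus score i. It ranges from 1 (one dominant locus) to K (equal
   variances), with 0·log 0 = 0.
6. **Associate.** Each standardized score is tested by maximum-likelihood
   logistic regression of case-control status on the score plus covariates
   (default: the first three genotypic principal components), reporting the
   per-SD log odds ratio, its Wald p-value, and the information for
   discrimination b²/2 in natural-log units. Non-convergence and separation
   are flagged, never silently estimated.
7. **Select.** A target is called a putative core gene if (criterion 1) its
   effective eQTL number exceeds 5 — strictly — and p < 1e-9, or
   (criterion 2) it is on the monogenic-disease list and p < 1e-6; criterion
   1 takes precedence when both hold. A cis-score association is attached as
   corroborating evidence when its p < 1e-3. Overlapping clumps contributing
   to scores associated at p < 1e-9 are merged (any-overlap chains, interval
   union) into regions; regions feeding more than two distinct scores —
   again strictly — are flagged as candidate peripheral master regulators.

Auxiliary operations: a per-SNP logistic GWAS (MAF ≥ 0.5%), an HLA summary
risk score learned by multiple logistic regression on eight variables
derived from five tag SNPs, a case-only interaction test (linear regression
of the trans-score on the HLA risk score among cases, valid when the two are
independent in the population and the disease is rare), and a control-group
score-correlation check flagging pairs with r² > 0.7.

## Design choices where the procedure was open

- **Clump formation** is single-linkage chaining of retained SNPs with gaps
  below 1 Mb: deterministic and invariant to input order, unlike greedy
  lead-SNP windows. The separation property (every pair of emitted clumps
  ≥ 1 Mb apart member-to-member) is tested.
- **Clump-to-gene distance** is the minimum over member SNPs to the nearer
  transcription-site edge; upstream and downstream are symmetric.
- **HLA exclusion** removes a clump on any overlap with the window, not only
  containment — conservative confounding control.
- **Intervals** are 1-based and closed throughout.
- **Ridge and pruning.** Correlation matrices of clumped SNPs are routinely
  near-singular, so near-duplicate variants (|r| > 0.99) are pruned (the
  smaller p-value is kept) and λ = 0.001 is added to the diagonal by
  default; λ is configurable down to 0 for the exact inverse.
- **Standardization sample** for both the score SD and the Hill-number
  variances is the full analysis sample (cases plus controls), on
  unstandardized locus scores; locus scores are summed first and the sum
  standardized once.
- **Harmonization** matches summary statistics to genotypes on the unordered
  allele pair, flips beta when effect alleles are swapped, and drops
  strand-ambiguous A/T and C/G variants with MAF > 0.4.
- **Fixed p-value thresholds**, no multiple-testing correction: the
  selection criteria are defined by fixed cut-offs.
- **Covariates** for score associations default to three genotypic PCs; the
  per-SNP GWAS additionally adjusts for sex and age. Both sets are
  configurable.
- **The eight HLA variables** (five tag dosages, two class-II
  haplotype-pair indicators, one class-I carrier indicator) are a synthetic
  stand-in for published tag-SNP haplotype codings, whose exact derivation
  lives outside this package; weights are learned in-study.

## The synthetic data generator

The generator is first-class, tested code that produces every input the
pipeline needs under a single seed (all randomness flows through fixed
`numpy.random.SeedSequence` spawn streams, so identical configurations are
bit-identical).

**Genotypes.** Variants sit in unlinked LD blocks. Within a block, haplotype
alleles are Bernoulli draws obtained by thresholding equicorrelated latent
Gaussians; the latent correlation is calibrated with the bivariate normal
CDF so the realized dosage correlation equals `block_correlation` (default
0.5) despite the attenuation that thresholding causes. Dosages are the sum
of two independent haplotypes, giving Hardy–Weinberg classes. One MAF,
drawn uniformly from `maf_range` (default 0.1–0.5), is shared by a block's
SNPs so that a single latent correlation per block is exactly calibratable.
Blocks are laid out on named chromosomes so all three distance classes
occur: each gene's cis block at 100 Mb on its own chromosome with the
transcription site just downstream, cis-x blocks 2.5 Mb from the first two
gene sites, trans blocks round-robin beyond 140 Mb, and two "HLA" blocks
inside chr6:25–34 Mb.

**Architecture.** Of `n_genes` = 14 targets, 4 are core genes, 8 are
bystanders and 2 are HLA-driven. Core and bystander genes draw
`trans_eqtls_per_gene` = 12 trans blocks from a shared pleiotropic pool of
90, so bystanders receive trans effects from the same blocks as core genes;
HLA-driven genes draw from a disease-irrelevant null pool instead. Every
gene also receives a coherent-sign trans effect from each HLA block (the
HLA region as a trans hotspot). One SNP per block is causal. Trans effects
are ±0.1 per allele; each gene's cis effect is solved so that trans variants
carry exactly `trans_heritability_fraction` = 0.7 of its generating genetic
variance. Expression is the genetic value plus Gaussian noise scaled to a
total heritability of 0.3.

**Disease.** Liability is logistic: a baseline of −2.2 log-odds, plus
±1.9 × the centered genetic expression value of each core gene, plus a
direct effect of 0.8 per centered HLA risk allele, plus N(0, 0.5²) noise.
Cases and controls are ascertained by batch rejection sampling until the
quotas (2,000 + 2,000 by default) are exactly filled. Covariates (three
genotypic PCs computed from the study dosages, sex, age, and the true HLA
liability contribution as an HLA risk covariate) are attached. The direct
HLA effect plus the HLA→expression hotspot reproduces the confounding that
motivates excluding the HLA region from trans aggregation.

**Summary statistics.** A disjoint expression-GWAS cohort of 10,000 is
simulated and each gene's expression regressed on each SNP singly; beta, SE
and p are emitted in a flat eQTLGen-style table. Records beyond 5 Mb from
the target's site (the trans range) are restricted to a "tested" subset of
SNPs (default 90%, HLA SNPs always included), emulating a meta-analysis
that tested only trait-associated SNPs for trans-association.

**Effect-size calibration.** The per-block magnitudes were fixed once by a
power calculation at the simulated sample sizes. In z-score units, a core
gene's trans-score association is ≈ √K·ζ where ζ is the single-block
association z and K = 12; with n_gwas = 10,000 the per-SNP expression z is
≈ 13, so clump retention is near-certain, and with 2,000 + 2,000 study
individuals the targeted core-gene z is ≈ 9 (comfortably past the z ≈ 6.1
that p < 1e-9 demands). A bystander's score z is approximately N(0, m·ζ²)
with m ≈ n_core·K/pool ≈ 0.5 the block-sharing density, giving a false-call
rate well under 5%. Shrinking the pool (raising m) degrades the
core/bystander separation — the pilot behind the default pool size showed
exactly that.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: realistic human LD maps (blocks are
equicorrelated and unlinked; real LD decays and leaks across clump
boundaries), imputation error, genotyping artifacts, population structure
(the PC covariates are noise here, so adjustment is exercised but not
stressed), assay-level issues such as unmodelled splicing variation, winner's
curse in the summary statistics of a finite discovery study, and any overlap
between the expression-GWAS cohort and the case-control study (the
two-sample structure is assumed; the real-world overlap is unknown).

Known limitation observed in simulation: when several core genes share many
pleiotropic blocks with opposite-signed liability coefficients, a core
gene's marginal trans-score association can be cancelled almost to zero —
its true genetic expression is then genuinely unassociated with disease in
the marginal sense that the method (and any marginal TWAS-style test)
measures. This accounts for the residual sensitivity loss in the recovery
tests.

## Numerical notes

- Sample statistics use ddof = 1; the aggregate score's SD is checked to be
  1 within 1e-9 after standardization.
- The Hill number treats 0·log 0 as 0; all-zero variance vectors are a
  domain error.
- The latent-correlation calibration solves a 1-D root with Brent's method
  to 1e-10 on the bivariate normal CDF.
- Logistic fits use statsmodels' Newton MLE with 200 iterations;
  rank-deficient designs, non-convergence, separation, or SE > 1e3 flag the
  result, which is then excluded from selection.
- Monomorphic variants are skipped at every stage (summary statistics, LD,
  per-SNP GWAS) with a log entry; missing dosages are mean-imputed per
  variant before correlation or scoring.
- p-values are floored at the smallest positive double to keep them in
  (0, 1].

## Problem sizes used in the test suite

Unit tests run a scaled-down study (800-individual panel, 4,000-individual
expression GWAS, 400 + 400 cases/controls, 40 blocks, 6 genes) chosen so
the whole pipeline exercises every stage in about a second. The recovery
suite runs 20 replicates of the full default configuration above; the
type-I-error suite runs 1,000 null logistic fits at n = 2,000; the
LD-adjustment oracle uses a 5,000-individual reference panel against a
20,000-individual GWAS, with clumps of 2–10 SNPs and within-block
correlation up to 0.9.
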