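# Methods

This note documents the statistical models, the synthetic-data design and
the numerical choices behind `isopqtl`, in the spirit of the methods
documentation of packages like msprime or statsmodels: what is assumed,
what is tunable, and what a green test does and does not establish.

## Phenotype model

Olink NPX values are natural-log-scale relative abundances. QC follows the
standard practice for isolate-cohort proteomics:

1. values strictly below the per-protein limit of detection (LOD) are set
   missing (a value exactly at the LOD is kept);
2. proteins with combined missing/below-LOD proportion **> 40 %** are
   excluded (boundary exclusive), and samples with missing covariates are
   dropped;
3. each protein is regressed on intercept, age, age², sex, plate
   indicators (first plate as reference), season (binary), and the
   per-sample mean NPX across all assays, in one joint ordinary
   least-squares fit on that protein's non-missing samples;
4. residuals are mapped to standard-normal quantiles by rank:
   Φ⁻¹((rank − 0.5)/n), average ranks for ties.

Choices worth noting: the per-sample mean is computed on the censored but
*unfiltered* matrix (all assays that passed vendor QC), so later protein
exclusions do not change it; the INT offset 0.5 is the symmetric standard;
sample plating in collection order makes plate and season heavily
correlated, and an exactly aliased column is dropped from the design with
a log entry rather than failing.

After INT the phenotype is in SD units. Downstream effect sizes
(association betas, COJO joint betas, MR exposure effects) are therefore
*per-allele effects in phenotype SDs*, not raw NPX. Tests that compare
against planted NPX-scale truth either rescale by the realized phenotype
SD or run on raw values.

## Mixed model

Association uses `y = μ + u + ε` with `u ~ N(0, λσ²K)` and K the
standardized GRM from LD-pruned common variants (MAF > 1 %, HWE pass,
VIF ≤ 2 in 50-variant windows stepped by 5). K is eigendecomposed once;
the restricted likelihood is maximized over log λ ∈ [−10, 10] (bounded
Brent, |Δ| < 1e-6); per-variant Wald tests run in the rotated model with
λ held at the null fit, mean-imputing missing dosages and skipping
monomorphic variants. P-values use the t distribution with n − 2 df; with
K = I the test reduces exactly to OLS (a frozen oracle test).

Two desk-scale artefacts are documented rather than patched, because both
vanish at real panel sizes (~15 M variants) and "fixing" them would
misrepresent the method:

* **Proximal contamination.** The tested variant is included in the GRM
  (as in GEMMA). With M panel variants and polygenic heritability h²,
  this deflates tests by roughly n·h²/M — ≈ 5 % at the desk-scale
  default M = 4000, negligible in a real study. Null-calibration checks
  therefore use h² = 0, which is also the spec of the null world.
* **Kinship alignment.** With related samples and a phenotype that does
  not share the family covariance, all variants' statistics share one
  random factor — the alignment of y with the off-diagonal kinship —
  giving λ_GC an irreducible run-to-run scatter of ~√(2·ΣK²ᵢⱼ)/n (±0.04
  for sibship blocks of 4 at n = 800) *independent of the number of
  variants*. Consequently the λ_GC ∈ [0.97, 1.05] protein-exclusion
  filter, meaningful at 15 M variants, is pure noise on a 4000-variant
  synthetic panel. The filter is implemented with that default band; the
  desk-scale end-to-end runs pass an explicitly widened band (0.8, 1.2),
  and calibration itself is asserted on a 20 000-variant, unrelated,
  LD-free null design where the band's premises hold (observed pooled
  λ = 0.998).

## Meta-analysis and signal extraction

Cohorts are combined with METAL-style fixed-effect inverse-variance
weighting after allele harmonization: labels first, frequency matching
only where labels are ambiguous (single-character truncation), the
smallest |MAF difference| rule at multiallelic sites, and exact frequency
ties dropped rather than guessed (the rule has no tie-break). Sign flips
orient everything to cohort A's alternate allele. Variants present in one
cohort pass through flagged.

Peaks: variants with P < 1e-6 are sorted by increasing P; each selected
variant removes neighbours in LD r² > 0.2; survivors within 2 Mb group
into one peak whose index is the lowest-P member; index candidates must
have MAC ≥ 10 and pass HWE. This is frozen against a literal O(n²)
re-implementation on 1000 random instances. Adjacent peaks whose indices
are within 1 Mb or in LD r² > 0.1 merge (an automated surrogate for the
manual review such studies apply to long-LD isolates; both knobs are
config-exposed).

Conditional/joint analysis reconstructs the multiple-regression normal
equations from summary statistics: X'X from reference-panel LD
correlations scaled by realized dosage variances (correlations beyond a
10 Mb window set to zero), X'y from marginal betas, and the phenotypic
sum of squares as the median over variants of the value implied by each
marginal fit. Forward selection starts at the lowest-P variant, admits
the best candidate with conditional P below the study-wide threshold and
max r² with the selected set < 0.9, then backward-eliminates on the joint
fit. Candidates are pre-thinned by clumping (r² 0.1, 1 Mb) to avoid
overfitting. Joint betas are verified against individual-level OLS on the
simulated genotypes (3 SE agreement).

The study-wide threshold is α/(N_eff · M_eff): N_eff from VIF pruning of
the MAC-filtered panel of the first cohort, M_eff = Σλᵢ/λ_max of the
phenotype correlation matrix (pairwise-complete correlations are
eigenvalue-clipped to the nearest PSD correlation matrix first). M_eff is
reported rounded to the nearest integer and the *reported* integer is used
in the division, matching how such thresholds are quoted; with
N_eff = 5 078 182 and M_eff = 132 this reproduces 7.45e-11.

## Annotation

Cis means |variant − gene start| ≤ 1 Mb on the same chromosome, boundary
inclusive, anchored at the gene start (both window and anchor are
config-exposed). Drift folds are cohort MAF / reference MAF on the
discovery minor allele, with an ∞ sentinel when the reference MAF is zero
(excluded from "minimum finite fold" summaries); variants absent from the
reference are dropped, never silently flipped. Novelty: a signal with no
catalogued variant within ±1 Mb is novel outright; otherwise the index
variant is re-tested with the catalogued variants' dosages as mixed-model
covariates and stays novel only if still study-wide significant.
Replication requires P < α/(number sought) *and* direction agreement
(through the signed LD correlation when an r² > 0.8 proxy stands in),
which makes the status invariant to global allele flips.

## Colocalization and MR

Per variant, log ABF = ½log(1−r) + ½z²r with r = W²/(W² + se²); W = 1 for
both traits on the standardized analysis scale (config-exposed, since the
prior could also be set per trait). Priors: p1 = p2 = 1e-4, p12 = 1e-5;
hypotheses combine by log-sum-exp; PP4 > 0.8 declares colocalization.
With one variant PP3 ≡ 0. When a peak holds several independent variants,
each signal's input is first conditioned on the others.

MR uses the COJO-independent variants as instruments, excluding those
without an rsid and palindromic variants with allele frequency in
[0.42, 0.58]; outcome lookups fall back to r² > 0.8 proxies, re-orienting
the exposure effect by the sign of the LD correlation. One instrument →
Wald ratio (by/bx, SE |se_y/bx| to first order); two or more →
fixed-effect IVW; Egger/heterogeneity methods are deliberately out of
scope at ≤ 10 instruments. BH adjustment runs across all protein–trait
pairs jointly.

## Synthetic-study design

The generator emulates the two-isolate design rather than any particular
dataset:

* ancestral frequencies ~ Beta(0.5, 0.5) clipped to [0.005, 0.995] (a
  U-shaped spectrum with usable rare tails); the reference AF table keeps
  these ancestral values;
* per-cohort frequencies via one Balding–Nichols step,
  p_c ~ Beta(p(1−F)/F, (1−p)(1−F)/F), default F_st = 0.02 — typical
  divergence of Mediterranean/European isolates from a cosmopolitan
  reference, and enough to produce ≥ 2.25-fold drifted rare variants;
* haplotypes from a latent Gaussian AR(1) chain (ρ = 0.8) within blocks
  of 20 variants, thresholded at each variant's frequency: marginals are
  exact and neighbours show dosage r² ≈ 0.3–0.6, enough to exercise all
  r²-based logic (no attempt at human LD maps);
* relatedness by sibships of 4 sharing two parental diplotypes, giving
  GRM entries near 0.5 within blocks;
* protein = planted allelic effects + polygenic term u = Zw (covariance
  proportional to the realized GRM; default h² = 0.2) + fixed effects of
  age, age², sex, plate, season and a per-sample mean shift + Gaussian
  noise; the LOD is the 5 % quantile of each protein's distribution;
* outcome GWAS from an independent unrelated sample at ancestral
  frequencies in which trait = Σ causal-protein levels × planted beta +
  noise; a configurable fraction of panel variants appears in the output
  to exercise proxy lookup.

Defaults (1000 samples/cohort, 4000 variants, 10 proteins, effect sd 0.8
NPX/allele) are a desk-scale rendition of a ~1400-per-cohort, ~250-protein
study. What a green test establishes: the algorithms implement their
stated rules and recover planted truth at these scales. What it does not:
behaviour under real human LD, assay artefacts beyond LOD censoring, or
population structure richer than one drift step plus sibships.

All randomness flows through NumPy's PCG64 (`default_rng`); a fixed seed
reproduces every output byte for byte, including the pipeline manifest.

## Degenerate inputs and tie-breaks

Monomorphic variants: HWE P = 1, skipped in association, excluded from
LD. LD with < 2 complete pairs: NaN sentinel. VIF pruning removes the
highest-VIF variant first, ties broken by lower MAF then position, which
makes the kept set invariant to input order; exact collinearity is kept
finite by a 1e-8 ridge so duplicated variants are removed first.
Conditioning a variant on itself (or an exact linear combination of the
conditioning set) reports a fully absorbed signal (beta 0, P 1) instead
of a singular solve. Empty significant sets, empty instrument sets and
single-variant coloc regions all return well-defined empty/degenerate
results rather than raising.
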