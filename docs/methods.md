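# Methods

## Trait derivation

Lesion grades form an ordinal scale NONE < MILD_SH < SEVERE_SH < ULCER; a
claw is *affected* iff its grade is at least SEVERE_SH (mild sole
hemorrhage is treated as unaffected throughout). Up to 8 claws (fore/hind ×
left/right × medial/lateral) are graded per animal at each of four
timepoints T1–T4.

**SL-Susceptibility** is 1 if any claw is affected at any timepoint,
regardless of how many claws or assessments. It is 0 only when the animal
is unaffected at every claw in a *complete* four-timepoint record set;
otherwise the animal is unclassified. Completeness means all 8 claws graded
at each timepoint; by default a hind-feet-only assessment (all 4 hind claws
graded, no fore-claw record at all — as happens when only hind feet are
examined at calving) also counts as complete, and `strict_completeness=True`
disables that allowance. The strict flag exists because either reading of
"complete records" is defensible; the lenient default keeps otherwise fully
observed animals classifiable.

**SL-Recovery** is defined only for animals affected at T3 with all 8
claws graded at both T3 and T4. Claw identity between T3 and T4 is matched
by position (limb, side, claw). The animal is 1 ("recovered") iff every
claw affected at T3 has grade < SEVERE_SH at T4; one persistent claw makes
the animal 0 ("chronic") — in particular an ulcer followed by severe
hemorrhage on the same claw has *not* recovered. Any missing claw grade at
T3 or T4 excludes the animal entirely, even when the affected claw itself
is observed twice. The T3→T4 interval in days is attached for use as a
model covariate.

Lameness is mobility score 2 or 3 on the 0–3 scale. Point prevalence is
computed per timepoint over animals scored at that timepoint; period
prevalence is the fraction of scored animals lame at any timepoint.

## Cohort statistics

2×2 comparisons use the Pearson χ² without continuity correction (the
uncorrected statistic reproduces the reference contingency results used
in the acceptance checks from their counts; the Yates-corrected one does
not). The
interval comparison is a pooled-variance two-sample t-test (df = n₁+n₂−2,
consistent with the reference degrees of freedom). The correlation interval is the Fisher
z-transform CI, tanh(atanh r ± z/√(n−3)); Fisher-z is adopted
because it reproduces the reference interval bounds used in the acceptance
checks; treat the choice as an inference rather than a documented fact.

## Genotype quality control

SNP filters run in a fixed order: call rate < 0.90, then minor allele
frequency < 0.05 (monomorphic SNPs are passed through to the next stage so
that per-category counts stay meaningful), then monomorphism, then
Hardy-Weinberg deviation, implemented as |observed heterozygote frequency −
2p(1−p)| > 0.15 with p the observed allele frequency. Sample filters remove
animals with call rate < 0.90 and then progeny whose opposing-homozygote
rate against a genotyped parent exceeds 2% (field reports typically give
only removal counts, not the rule; the threshold is configurable). Because the
categories overlap, per-category counts depend on stage order; the order
above is fixed and reported stage by stage. Filters are idempotent.

## Relationship matrices

Inbreeding coefficients use the Meuwissen–Luo recursion (exact, O(n·anc));
A uses the tabular method (dense, guarded by a size limit); A⁻¹ uses
Henderson's rules with the Mendelian-sampling variance d_i =
½ − ¼(F_s + F_d) (¾ − ¼F with one known parent, 1 with none). G is
VanRaden's first method: dosages centred by 2p with p observed in the
genotyped set (configurable), missing dosages imputed to the SNP mean,
denominator 2Σp(1−p). For H⁻¹, G is first *tuned* — a + b·G chosen so its
mean diagonal and mean off-diagonal equal those of A22 — then *blended*,
G\* = α·G_t + (1−α)·A22 with α = 0.95, and

    H⁻¹ = A⁻¹ + [0 0; 0 (G\*)⁻¹ − A22⁻¹].

Tuning and blending constants follow common single-step practice and are
exposed as options; no τ/ω scaling is applied. With no genotyped animals
H⁻¹ = A⁻¹ exactly. All sparse constructions are verified in the test suite
against dense linear algebra on small pedigrees to 1e-10.

## Threshold model and Gibbs sampler

The liability model is λ = Xb + Z_hys·hys + Z_a·a + e with y = 1 ⇔ λ > 0.
X holds an intercept, parity-class dummies (first class absorbed), and for
SL-Recovery the mean-centred T3→T4 interval. hys ~ N(0, Iσ²hys),
a ~ N(0, Hσ²a) over *all* pedigree animals (phenotyped or not), e ~ N(0,
Iσ²e). The threshold is fixed at 0 and σ²e = 1 by default; an
`estimate_residual` mode samples σ²e as well, which is only weakly
identified in a single-threshold binary model and is provided for
comparability with analyses that report a residual-variance HDI.

One iteration of the (numba-compiled) sampler:

1. each liability from its truncated normal full conditional (inverse-CDF
   draw using the AS241 probit approximation, tail-safe via erfc);
2. single-site Gauss–Seidel updates of every location effect from its
   scalar normal full conditional of the mixed-model equations; the animal
   effect update uses one sparse row product with H⁻¹;
3. σ²hys and σ²a from their scaled inverse-χ² full conditionals
   (df = levels + ν, scale = SS + νS);
4. an ancillarity-sufficiency interweaving (ASIS) move for the genetic
   scale: holding the whitened effects ã = a/σ_a fixed, σ_a is a regression
   coefficient of the liabilities on ã, and is redrawn from that normal
   conditional with an independence-Metropolis correction for the variance
   prior. Without this move the single-site sampler's σ²a chain has lag-1
   autocorrelation ≈ 0.99 and effective sample sizes in the tens.

**Variance priors.** The default is a proper, weakly informative scaled
inverse-χ² with ν = 4 and S = 0.5 (prior mean νS/(ν−2) = 1.0 on the
liability scale, infinite prior variance) for both σ²hys and σ²a. This is
deliberate: with the improper flat prior (ν = −2, S = 0) the joint
posterior of a binary threshold model is improper — two independent
implementations (this sampler and a dense blocked-Gibbs check written for
the purpose) both produce σ²a chains that drift without bound. Flat and
other (ν, S) settings remain available in `ChainConfig` for sensitivity
analysis, with that caveat.

Chain bookkeeping retains every thin-th draw after burn-in:
(length − burn_in)//thin samples, e.g. 500,000/50,000/100 → 4,500.
Heritability h² = σ²a/(σ²a + σ²hys + σ²e) is computed per retained sample
and summarised by the posterior mean and the shortest 95% interval
(arviz HDI). Diagnostics report arviz effective sample size, lag-1
autocorrelation, and a split-chain z-score per variance parameter.

## Breeding values and the adjusted correlation

GEBV_i is the posterior mean of a_i over retained samples; PEV_i is the
posterior variance (the squared standard error of the GEBV); REL_i =
1 − PEV_i/((1+F_i)σ²a) with σ²a the posterior-mean additive variance from
the same chain. Values outside [0, 1] (possible for ancestors with no
phenotype information when the variance chain wanders) are clipped with a
warning. Whether PEV should come from posterior variances or an
MME-inverse approximation is an open choice; posterior variance is used
and documented here.

The approximate genetic correlation between two traits is the Pearson
correlation of their GEBV in the subset of animals with both phenotypes,
multiplied by √(ΣREL₁·ΣREL₂)/Σ√(REL₁·REL₂) (≥ 1 by Cauchy–Schwarz; exactly
1 when all reliabilities are 1). A literal variant without the square
roots, (ΣREL₁)(ΣREL₂)/Σ(REL₁·REL₂), is available behind a flag for audit
only: it scales with n and is not a correlation-scale quantity. SE =
√((1−r̃²)/(n−2)) with a normal 95% CI. Note the adjustment corrects for
*heterogeneous* reliabilities but not for uniform attenuation: with all
reliabilities equal to ρ < 1 the adjusted value remains ≈ ρ·r_g, so low,
even reliabilities still shrink the estimate toward zero — one reason such
approximate correlations must be read cautiously.

## Synthetic cohort generator

The generator emulates a prospective multi-herd study: ~4 herds with sizes
proportional to a real cohort, herd-year-season (HYS) contemporary groups
(default 12 levels, seasons nested within herd), three parity classes, four
assessment timepoints with realistic day-relative-to-calving distributions,
and 8 claws per animal. The pedigree places founder dams in generation 0;
each later generation introduces fresh founder sires mated to a uniform
2–8 dams (mean 5 daughters per sire, mirroring the sire-usage pattern of
national dairy populations).

Breeding values are simulated *through the pedigree* — founders from
N(0, Σ_a), offspring as parent-average plus a Mendelian-sampling deviation
with covariance d_i·Σ_a — rather than from SNP effects, so the generating
h² is exact under the estimation model's own assumptions. The two traits'
breeding values are bivariate with genetic correlation −0.11 by default.
Genotypes are gene-dropped down the same pedigree from Hardy-Weinberg
founders (MAF ~ U(0.05, 0.5)) and serve only to estimate relationships. A
consequence worth knowing: the Mendelian sampling realised at the markers
is independent of the Mendelian sampling in the breeding values, so a
marker-based G (or H) is a noisy proxy for the generating covariance, and
variance components fitted with H on these data shrink somewhat relative
to a pedigree-A fit. Parameter-recovery checks therefore fit with A;
single-step H is validated algebraically and exercised in the GEBV
pipeline.

Default variance components are σ²a = 0.42, σ²hys = 0.25, σ²e = 1.04
(liability h² ≈ 0.246). Liability intercepts are calibrated by
inverse-normal transform so marginal prevalences hit 44% (susceptibility)
and 71% (recovery among affected), both overridable. Lesion records are
constructed so that, with no missingness, trait derivation returns the
generating phenotypes exactly: susceptible animals carry 1–4 affected claws
at T3 (severity drawn at the observed early-lactation severe-hemorrhage :
ulcer ratio of 457:131), recovered animals' claws all heal by T4, chronic
animals keep at least one affected claw. Missing-record and
missing-genotype rates are configurable and applied completely at random.

What the generator does **not** emulate: treatment effects (therapeutic
trimming, blocking), lactation-curve or culling dynamics, genotype
imputation, informative (non-random) missingness, selection, or
non-additive genetic variance. Passing tests on these data therefore show
correctness of the estimation machinery under the model's own assumptions,
not robustness to the field-data artefacts those processes create.

## Problem sizes and numerical choices

The test suite and acceptance script use cohorts of 150–2,000 phenotyped
animals (pedigrees up to ~4,400) and chains of 15,000–20,000 iterations
with 2,000–3,000 burn-in and thinning 10 — sizes chosen so a full run
completes in minutes on one CPU while leaving the heritability posterior
clearly data-dominated. The ten-replicate recovery check at n = 2,000
gives 95% HDIs of width ≈ 0.25–0.45 for h²; the real-data analogue with a
deeper national pedigree would be tighter. Degenerate inputs fail loudly:
single-class phenotypes, cyclic pedigrees, all-monomorphic SNP panels,
empty prevalence denominators and singular blended genomic blocks all
raise typed errors. Random streams are derived deterministically from a
single seed per component, and identical seeds give bit-identical
pedigrees, genotypes, records and chains on the same platform.
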