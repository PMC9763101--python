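# Methods

This note records the models, estimators and numerical choices behind each
`crdscan` module, what the synthetic generator does and does not emulate,
and the known limitations.

## Coordinates and containers

All feature coordinates are BED-convention (0-based, half-open) internally.
Variant positions are stored 1-based as in the VCF and converted where they
are compared against feature coordinates.  Phenotype matrices carry a
`kind` flag (`raw_count` / `quantified` / `normalized`) and modules enforce
the representation they need: correlation maps and QTL passes require
`normalized`; per-peak case/control tests refuse it (they are defined on
uncorrected quantifications); count models require `raw_count`.  Missing
phenotype values are sentinel-NA and all statistics use pairwise-complete
samples rather than imputation.

## Preprocessing

Confounders are removed by OLS: per feature, residuals of
`value ~ intercept + covariates`, where covariates are genotype PCs
(ancestry; default 2, computed on the centered dosage matrix), declared
biological/technical covariates, and top phenotype PCs (technical
variation).  Residuals are then mapped to Normal(0, 1) by the rank-based
transform Φ⁻¹((rank − 0.5)/m), ties broken by average rank and then
perturbed deterministically by input order (relative perturbation 1e-8) so
tied observations stay distinct.  The order — regress first, transform
second — is the convention of cis-QTL pipelines.  The number of phenotype
PCs can be fixed or chosen by `select_pc_count`, which reruns a
reduced-permutation QTL pass (default 100 permutations) per candidate k and
keeps the k with the most FDR-5% discoveries, ties to the smallest k.

## CRD calling

**Correlation map.**  Pearson correlation between all peak pairs on a
chromosome within a 250-peak index window, pairwise-complete, with pairs
under 10 complete samples set missing.  The chromosome **background** is
the mean banded off-diagonal correlation.

**Noise floor.**  On data with no shared structure the mean-correlation
background is ~0 and the "≥ 2× background" criteria degenerate: any
positively correlated pair of noise peaks would qualify.  The background is
therefore floored at a sampling-noise guard derived from the Fisher-z null:
with n samples and P candidate merges, the largest spurious correlation
expected is r* = tanh(z₁₋α/P / √(n−3)); the floor is r*/factor so that
`factor × background ≥ r*`.  Family-wise α defaults to 0.01, i.e. a pure
noise chromosome produces any call in ~1% of cohorts.  The floor only acts
when the estimated background falls below it; on data with genuine baseline
covariation (real cohorts) the chromosome estimate dominates.

**Tree.**  Agglomerative clustering constrained to genomically adjacent
clusters; merge score is the mean inter-cluster correlation (pairs outside
the 250 band contribute the background value), maximal score merges first,
ties to the leftmost pair.  Every node is a contiguous peak-index range, so
domains are genomic intervals by construction.

**Criteria and acceptance.**  A node qualifies iff
(i) mean pairwise member correlation ≥ factor × background,
(ii) edge correlation — the mean correlation between each of the two
boundary peaks and all other members, 2m−3 pairs — ≥ factor × background,
and (iii) ≥ 2 mutually non-overlapping member intervals (greedy
interval-scheduling count).  The tree is searched depth-first from the
root and qualifying nodes are accepted without descending, so accepted
domains are maximal and nested sub-domains are never emitted.  Signed
correlations are used throughout: anti-correlated peaks do not build
domains.  Edge correlation uses all boundary-to-member pairs rather than
the single boundary-boundary pair because it averages more terms at equal
meaning, reducing variance.

**Quantification.**  Domain activity per individual is the NA-aware mean
of member-peak normalized quantifications; for count-based differential
testing, member raw counts are summed per domain.

## Differential testing

The count model is an NB GLM with log link, per-sample offsets from
median-of-ratios size factors (normalized to geometric mean 1), and design
intercept + case indicator (+ covariates).  Per-feature dispersion is
estimated by Cox-Reid-adjusted profile maximum likelihood on a 40-point
log-spaced grid over [1e-4, 10] with one parabolic refinement, then shrunk
in log space toward a linear log-mean trend with prior weight 10 against an
observation weight of n/2.  The fit is IRLS, vectorized across features;
non-convergent features are reported with p = NA.  The Wald statistic is
β̂/SE on the status coefficient.  Divergences from the reference count
pipeline are deliberate and documented: no independent filtering, no
empirical-Bayes LFC shrinkage, no outlier replacement.  A known
consequence of median-of-ratios normalization is that a strongly one-sided
composition change is partially absorbed into the size factors, so planted
one-sided fold changes measure slightly below their nominal value.

Covariate selection for this module follows a two-way screen: a covariate
enters the design if it associates with disease status (Mann-Whitney U,
p < 0.05) or with many features (π₁ of its per-feature regression p-values
above 0.05).

**Storey q-values.**  π₀(λ) = #{p > λ}/(m(1−λ)) on λ ∈ {0.05, …, 0.95} is
smoothed by a cubic polynomial and evaluated at λ = 0.95, clipped to
(1/m, 1]; q-values are the step-down minima of π₀ m p₍ⱼ₎/j.  Inputs below
20 p-values fall back to π₀ = 1, which makes the estimator identical to
Benjamini-Hochberg; π₁ = 1 − π₀ is the replication/sharing statistic.

## Condition-specific structure

A domain of group A is condition-specific when none of its member peaks
belongs to any domain of group B.  Two probes of the mechanism: per-peak
two-sided Mann-Whitney U between groups on uncorrected quantifications
(exact U distribution whenever there are no ties and ≤ 500 samples, normal
approximation with tie correction otherwise), with Storey q-values and
median differences; and a per-domain correlation shift — mean pairwise
member correlation computed separately per group on corrected
quantifications, compared globally by an unpaired Mann-Whitney U over the
per-domain estimates.  Annotation enrichment is a two-sided Fisher exact
test on the 2×2 of (foreground vs background peak) × (≥ 1 bp annotation
overlap); zero-cell tables report the plain odds ratio as 0/∞ alongside the
Haldane-Anscombe (+0.5) corrected one.

## QTL mapping

Associations are correlation-based OLS on rank-normalized phenotypes:
r between phenotype and dosage, t = r√(df/(1−r²)), two-sided p.  The cis
window is ±1 Mb around the phenotype anchor — strand-aware TSS for genes,
domain start for CRDs, peak start for peaks — and variants under the MAF
threshold (default 0.05) are excluded.

**Permutation pass.**  Per phenotype, the best nominal p across the window
is compared to the minima of the identical scan on n_perm (default 1,000)
row-shuffles of the phenotype, genotypes fixed — the scheme that preserves
cis LD.  A Beta(a, b) is fitted to the permutation minima by Newton
iterations on the digamma score equations (method-of-moments start, damped
positivity guard); the adjusted p is the Beta CDF at the observed best p.
The degrees-of-freedom refinement of the original permutation-pass scheme
is omitted; the acceptance checks verify factor-2 agreement with direct
empirical permutation p-values over the range a 10⁵-permutation oracle can
measure (p ∈ [1e-4, 0.5]).

**Conditional pass.**  The significance bound on the adjusted-p scale is
the midpoint between the last significant and first non-significant
phenotype (or the FDR level itself when everything is significant); each
phenotype converts it to a nominal threshold through its own fitted Beta
quantile.  Forward: repeatedly add the best variant as a covariate while it
passes the threshold (collinear dosages are skipped).  Backward: retest
each selected variant conditioning on all others and drop failures.
Survivors are ranked by forward selection order, 0 = primary.

**Interaction QTLs.**  For QTLs discovered in the case subset, OLS of
phenotype ~ genotype + status + covariates + genotype×status with a
two-sided t test on the interaction coefficient and Storey q over the
tested pairs.  Flipping the status coding flips the interaction slope and
leaves p unchanged.

**RTC.**  For a QTL and GWAS variant inside one recombination-hotspot
interval with N variants: the phenotype is residualized on each interval
variant in turn and the QTL variant re-associated with each residual;
variants are ranked by how completely their removal destroys the QTL
association (rank 0 = residual p largest); RTC = (N − rank)/N, near 1 when
the GWAS variant tags the same functional effect and roughly uniform when
it does not.  The degenerate gwas = qtl case trivially ranks first and is
flagged.

## Gene-CRD pairs and triplets

Gene-CRD association reuses the permutation machinery with the gene's cis
CRDs (span overlapping TSS ± 1 Mb) as candidates.  Significant pairs are
collapsed onto PC1 of the standardized (gene, CRD) pair; for standardized
series PC1 explains exactly (1+|r|)/2 of the variance and the score vector
is (g̃ + sign(r)·c̃)/√2, sign-aligned to correlate positively with the gene.
Pairs with |r| < 0.05 are skipped — PC1 then no longer represents a shared
signal.  The pseudo-phenotype is QTL-mapped in the gene's cis window; a
significant variant (Storey q ≤ 0.05 across pairs) anchors a triplet.

**Network scoring.**  Each triplet (V, C, G) is scored under three
Gaussian linear networks — causal L(C|V)·L(G|C), reactive L(G|V)·L(C|G),
independent L(C|V)·L(G|V) — where each conditional is the OLS Gaussian
profile likelihood.  The marginal of V is identical across models and
omitted.  Scores carry a BIC penalty (6 parameters per model, so it
cancels in the normalization) and posteriors are the softmax under a
uniform model prior.  BIC-penalized likelihood approximates the marginal
likelihood while keeping the three models directly comparable; posteriors
are invariant to affine rescaling of C and G.  With equal chain
coefficients, causal and reactive differ only through the V→C vs V→G
correlations, so reactive recovery degrades as the two chain coefficients
approach symmetry — model recovery is asserted at asymmetric coefficients
for the reactive case.

**Bootstrap confidence.**  Accuracy is the fraction of B = 100
with-replacement resamples whose top model matches the full-data top
model; resamples with a constant dosage are redrawn up to 10 times and
then counted as mismatches.  Triplets below the 0.55 accuracy threshold
are filtered.  The threshold is configurable; the quantile-based
alternative (lower quartile of the case-group accuracies) can be applied
by the caller.  Mechanism comparison matches triplets on (variant, CRD,
gene), requires the filter passed in both groups, and collapses reactive
and independent into "different", yielding same / causal→different /
different→causal in the controls→cases direction.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the sequencing process.  Each planted domain k has a latent factor
f_k ~ Normal(μ_group, 1) per individual; member peaks load on it as
`loading · f_k + Normal(0, noise_sd)`, giving within-domain correlation
loading²/(loading² + noise_sd²) (0.5 at the defaults), while background
peaks are independent noise of matched marginal variance.  Peaks sit on
one synthetic chromosome at 2-kb spacing with 1-kb widths; domain members
are contiguous and separated by at least one background peak.  Case status
shifts the factor mean of a configurable fraction of domains by
`diff_effect` (default 0.5 — a subtle shift, as regulatory activity varies
narrowly).  Planted QTLs add β·(dosage − mean) to a factor or gene with
β ~ Normal(0, 0.5); interaction QTLs add the slope in cases only (default
0.6).  Triplets wire one variant, one domain factor and one gene under the
causal, reactive or independent model with coefficients (0.5, 0.7).
Counts are NB with mean exp(5 + 0.3·z) of the standardized activity and
gamma-Poisson dispersion 0.1.  Genotypes are independent binomial(2, MAF)
draws with MAF ~ U(0.05, 0.5); one variant per planted signal is placed
within ±0.5 Mb of its target, plus unlinked background variants.  The
default cohort is 98 cases / 174 controls, mirroring the case/control
proportions of the motivating cohort.

What it does **not** emulate — and hence what passing tests do not show
about real data: LD between variants, ancestry structure and admixture,
peak-width and coverage heterogeneity, group-specific correlation
structure beyond mean shifts (condition-specific domains in the pipeline
demo arise only from calling variability), GC/batch artifacts, and
read-level noise.

## Problem sizes and determinism

Simulation-based checks run at deliberately compact sizes chosen to keep
Monte-Carlo error small relative to the asserted margins: domain recovery
on 1,000 peaks × 200 individuals with ~100 planted domains; permutation
calibration on hundreds of null phenotypes with 50 cis variants each and a
10⁵-permutation oracle on planted effects sized to keep the true adjusted
p inside the oracle's measurable range; 2,000-simulation interaction
calibration; 200 seeds per generative model for network recovery; NB
calibration on 2,000 features at n = 60/60.  Every stochastic routine
takes an explicit seed; the pipeline derives per-stage child seeds from a
SHA-256 hash of the master seed and stage name, and reruns with the same
config produce byte-identical outputs and manifest checksums.

## Limitations

- The caller emits only maximal domains; nested sub-structure is
  invisible.  Bit-compatibility with the original external calling tool is
  not attempted (its exact linkage and background estimator are not
  restated in the sources this package follows).
- Whether the criteria should use signed or absolute correlation is an
  open choice; signed is implemented, so coordinated repression
  (anti-correlation) is not grouped.
- The Beta approximation is extrapolative below the permutation floor;
  adjusted p-values far beyond 1/n_perm inherit its tail behavior.
- Gaussian-likelihood network scores assume linear effects and
  homoscedastic noise; latent confounders of C and G bias the comparison
  toward the causal/reactive pair.
- Trans effects, mixed-model kinship correction, and genotype imputation
  are out of scope.
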