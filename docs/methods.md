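# Methods

## Setting and model

The package implements summary-data Mendelian randomization (MR): genetic
variants that robustly associate with an exposure (a lipid trait measured
per SD, or the lipid shift produced by a drug target) serve as instruments
for its causal effect on a binary outcome (sepsis, on the log-odds scale).
Validity rests on the three instrumental-variable assumptions — relevance
(strong variant–exposure association), exchangeability (no association
with confounders) and exclusion restriction (no effect on the outcome
except through the exposure). The selection chain operationalises the
first two (significance and F thresholds; confounder screening); the
Egger intercept, Cochran's Q and the bootstrap outlier test diagnose
violations of the third.

All estimators work on a *harmonized* instrument set: exposure and outcome
effects expressed per copy of the same allele. Matching is by rsid;
mismatched allele order negates the outcome beta, strand-complement
reporting is reconciled, and palindromic (A/T, C/G) variants are dropped by
default because their strand cannot be resolved from alleles alone. An
optional frequency-inference mode keeps palindromes when both effect-allele
frequencies lie outside [0.30, 0.70]; 0.30 is the conventional ambiguity
cutoff and the mode is off by default because it trades a small gain in
instrument count for a strand-error risk.

## Estimators and numerical choices

**IVW.** Weighted zero-intercept regression of outcome on exposure effects,
weights 1/SE²_Y. Exposure-side measurement error is ignored (standard
first-order practice; the F > 10 and conditional-F filters bound the
resulting weak-instrument bias). Random effects are *multiplicative*: the
fixed-effects SE is scaled by √(Q/(k−1)) floored at 1; additive random
effects are not implemented. `mode="auto"` applies the heterogeneity
switching rule (random effects iff the Q test has p < 0.05). IVW p-values
use the normal distribution.

**MR-Egger.** Weighted regression with a free intercept after orienting
every instrument to a non-negative exposure effect (the InSIDE
convention); the input set is not mutated. Both SEs carry the
multiplicative √(Q/(k−2)) scaling. Egger p-values use a t distribution
with k−2 degrees of freedom — small instrument counts are common in
drug-target MR and the t reference is better calibrated there; a
`pvalue_dist="normal"` switch restores the normal.

**Outlier detection.** A PRESSO-style parametric bootstrap: the observed
statistic is the leave-one-out weighted residual sum of squares; simulated
datasets redraw both effect vectors under the no-pleiotropy null (with
leave-one-out slopes recomputed per draw), giving a global p and
per-variant outlier p-values that are Bonferroni-corrected across
instruments. Flagged variants are removed and IVW re-fit once; the
distortion test (comparing pre/post estimates inferentially) is not
implemented — removal plus re-estimation stands in for it. At least 1,000
bootstrap draws are required for stable tail estimates, and all randomness
flows through an explicit seed.

**Multivariable MR.** Weighted multiple regression through the origin via
the normal equations; rank deficiency raises an error naming the collinear
exposures. Conditional instrument strength for exposure k is the weighted
residual Q of regressing its effects on the other exposures' effects,
divided by L−K+1 (equal to the unconditional mean F when K = 1). MR-Lasso
adds per-variant intercepts α_j with an L1 penalty; given the causal
coefficients each α_j has a closed-form soft-threshold update, so the fit
alternates θ and α updates to a 1e−8 relative tolerance (cap 10,000
iterations). λ is chosen as the largest value on a 50-point log grid
(spanning 0.01–100× the median weighted residual) whose post-selection Q
on the zero-intercept variants has p ≥ 0.05; if none qualifies the
largest-λ fit is returned with a warning flag. λ = 0 is rejected as
unidentifiable.

**Scale conversions and labels.** Odds-ratio inputs are converted at the
boundary: β = ln OR and SE = ln(CI_hi/CI_lo)/(2·1.959964). The normal
quantile is fixed at 1.959964 (not 1.96) so p-values recomputed from
printed 95% intervals reproduce printed p-values at three decimals.
Evidence labels follow a Bonferroni rule over x exposures and y outcomes:
strong for p < 0.05/x/y, suggestive for 0.05/x/y ≤ p < 0.05; x and y are
explicit parameters rather than inferred. For LDL-C-proxied drug targets
the pharmacological odds ratio is the reciprocal of the fitted per-SD-
increase OR; HDL-C-proxied CETP estimates pass through unchanged.

**Mediation.** All arithmetic is on the additive scale. The indirect
effect is the product of coefficients with the delta-method SE
√(β₁²SE₂² + β₂²SE₁² + SE₁²SE₂²) (the second-order SE₁SE₂ term included);
the direct effect is total − indirect, so the decomposition sums exactly
by construction. The proportion mediated is reported as a percentage and
flagged *inconsistent* when the indirect and total effects have opposite
signs. The mediator→outcome leg uses the mediator's own instruments with
the exposure's instruments excluded, so a shared locus (e.g. the drug
gene) cannot re-enter through the mediator. Note that recomputing the
proportion mediated from three-decimal printed inputs gives ≈50.5% where a
full-precision internal computation can give a slightly different figure;
the package always computes from full precision and exposes the
printed-input recomputation only in tests.

**Instrument selection.** Thresholds are strict inequalities throughout
(p < threshold, F > 10, r² < cutoff). Clumping is greedy in ascending p
with ties broken lexicographically by rsid, which makes the kept set
deterministic, order-invariant and a fixed point of re-clumping; the
window never spans chromosomes. The drug-target gene windows use GRCh37
transcription bounds with a ±100 kb flank; the cis clumping threshold
defaults to r² < 0.1 (configurable to 0.3 — published practice varies and
the stricter default is safer). HMGCR's end position is taken as
74,657,929. Confounder screening consumes a plain (rsid, trait, p)
annotation table — a desk stand-in for a PhenoScanner query — and removes
variants with any annotation below 5×10⁻⁸.

## Synthetic data

The generator draws per-variant true exposure effects γ_j ~ N(0, σ²_γ)
for a configurable fraction of variants, mediator effects α·γ_j plus an
independent mediator-specific component on its own variant set, and
outcome effects (θ + αβ_med)γ_j + β_med·γ_med,j + δ_j, where δ_j is the
pleiotropic direct effect (balanced when its mean is zero; directional
pleiotropy is oriented along the exposure-increasing allele, the
orientation Egger regression estimates). LD blocks impose compound-
symmetric correlation √r² within blocks, applied to both the marginal
true effects (marginal = Cγ) and the estimation noise; the exposure and
outcome samples draw independent noise, matching the two-sample design.
Observed SEs follow 1/√(2·MAF(1−MAF)·n) and p-values come from the normal
approximation.

Defaults describe a well-powered biobank-scale study: 200 variants, MAF
uniform on (0.05, 0.5), per-variant effect SD 0.03 per SD of exposure
(giving median F in the hundreds at the default n), exposure n = 500,000,
outcome n = 460,000, mediator n = 330,000, no pleiotropy and no mediation
unless switched on. Statistical checks use n = 300,000 per sample and
m = 20–50 variants so a full battery (500 null replicates, 200 recovery
replicates, 100 bootstrap runs) completes in seconds on one CPU.

What the generator does **not** emulate: realistic genome-wide LD maps
(blocks are compound-symmetric and independent), allele-frequency
differences between samples, sample overlap, case-control ascertainment
effects on log-odds SEs, winner's-curse from discovery-in-sample
selection, and population stratification. Passing tests therefore
demonstrate correctness of the estimators and pipeline under the stated
generative model, not robustness to those real-data complications.

## Known limitations

- Weighted-median/mode estimators and MVMR-Egger are out of scope; the
  primary analysis path is IVW (FE/RE switching) with Egger and the
  bootstrap outlier test as sensitivity analyses.
- Unmatched instruments are not rescued by LD proxies; allele-incompatible
  pairs are dropped and counted rather than frequency-resolved.
- Mediation reports no confidence interval for the proportion mediated.
- Genome build is a pass-through label; there is no liftover, and
  positions are 1-based inclusive.
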