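# Methods

This note records the statistical model behind `pqtlmr`, the generating
assumptions of its synthetic-data module, the numerical choices made where
the design was genuinely open, and what the validation studies do and do
not establish. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Two-sample cis-MR model

The pipeline estimates the causal effect θ of a circulating protein X on an
outcome Y from two non-overlapping GWAS samples, using cis-pQTLs as
instruments. The identifying assumptions are the usual instrumental-variable
triple: each instrument is (i) associated with the protein, (ii) independent
of confounders of the protein–outcome relation, and (iii) affects the
outcome only through the protein. Cis variants (within ±1 Mb of the coding
gene's start) are preferred because their effect on the protein is likely
direct, limiting horizontal pleiotropy.

Per variant, the Wald ratio β̂_Y/β̂_X estimates θ with first-order
delta-method SE se(β̂_Y)/|β̂_X|; the second-order term, which adds
β̂_Y²·se(β̂_X)²/β̂_X⁴ under the square root, is negligible when the
instrument F statistic is large (the pipeline requires F ≥ 10) and is not
used by default. IVW combines the ratios as a weighted regression through
the origin with outcome-variance weights; Cochran's Q is the weighted
residual sum of squares of that *fixed-effect* fit (the standard Cochran
definition), and the multiplicative random-effects SE multiplies the
fixed-effect SE by max(1, √(Q/(k−1))) — inflation only, never deflation,
the common regression-based implementation of a "random-effects IVW". A
consequence worth knowing: with few instruments the truncation at 1 makes
IVW (and Egger) p-values mildly conservative under homogeneity; the test
suite checks super-uniformity of null p-values rather than exact
uniformity.

MR-Egger adds a free intercept after orienting all pairs to β̂_X ≥ 0 (the
estimator is invariant to joint sign flips, so orientation is a
normalization, not a choice); the intercept estimates the average
directional pleiotropic effect, and inference uses t with k−2 df for
small-k correctness. Egger's slope is identified by the *dispersion* of
instrument strengths: with near-equal β̂_X the slope and intercept are
nearly collinear and the estimator is unstable. This is a property of the
method, not of the implementation, and drives one design choice in the
validation studies (below).

The weighted median sorts the ratios, forms normalized cumulative weights
s_i = (Σ_{j≤i} w_j − w_i/2)/Σw, and linearly interpolates the weighted
quantile function at 0.5. It is consistent while valid instruments carry
more than half the total weight. It has no closed-form SE; the package uses
a seeded parametric bootstrap (default 1000 draws; both β̂_X and β̂_Y are
perturbed by their SEs and the weights recomputed), and the two-sided
normal p-value. Note that the interpolated estimator returns the dominant
instrument's ratio only in the limit of extreme weight concentration; with,
say, 60% of the weight on one instrument the estimate still interpolates
toward its neighbours.

Steiger statistics use the exact univariate least-squares identity
r² = t²/(t² + n − 2), which needs no assumption about trait variance or
allele-frequency scaling. The per-SNP filter keeps a variant iff
r²_exposure > r²_outcome *and* the one-sided Fisher-z p-value is below 0.05;
the set-level direction call applies the same z statistic to √(Σr²) per
side, capped at 1, with the per-side median sample size.

## Instrument-selection cascade

Filter order: significance → cis → MAF → MHC → strength (F) → cross-protein
pleiotropy → harmonization → Steiger → LD clumping. The order applies cheap
marginal filters before panel-dependent ones and runs Steiger before
clumping; it is visible in the audit trail, where every dropped SNP carries
exactly the first filter it failed, so the audit plus the kept list
partition the candidates and re-running the cascade on survivors is a
no-op. Genomic coordinates are 1-based with inclusive interval endpoints
throughout (so the MHC default chr6:28477897–33448354 excludes both
endpoints' positions). The pleiotropy filter counts distinct protein
*targets* (an optional aptamer→protein map collapses multi-aptamer
proteins) with genome-wide significance as the association criterion, and
"more than five" is strict: a count of exactly five survives.

Harmonization resolves allele swaps (flip β and EAF), strand flips
(complement letters), and palindromic A/T and C/G variants, whose letters
carry no strand information: outside the exposure-EAF band 0.42–0.58 they
are aligned by allele frequency, inside it they are dropped. Variants
missing from the outcome GWAS or with irreconcilable allele sets are
dropped with their own audit reasons (no proxy-SNP lookup).

Clumping is greedy: repeatedly keep the smallest exposure p-value (ties
broken by chromosome, position, variant id) and discard all remaining
candidates with panel r² ≥ 0.1 against it. Because every kept pair may
still correlate at up to r ≈ √0.1 ≈ 0.32, IVW's independence assumption is
only approximate after clumping; under sustained moderate LD this inflates
the null tail of the screen (a property of r²-threshold clumping generally,
not of this implementation). The simulated screen conditions below are
chosen so that post-clump instruments are effectively independent; with
real, denser LD a stricter clumping threshold is the appropriate remedy.

## Synthetic-data generator

Each protein gets one cis region of `snps_per_region` biallelic SNPs.
Genotypes are built from latent-Gaussian haplotypes: haplotype j carries an
AR(1) latent variable thresholded at Φ⁻¹(MAF_j), and the dosage is the sum
of two independent haplotypes, giving Hardy–Weinberg margins. The latent
adjacent correlation is *calibrated* (bivariate-normal tail inversion per
adjacent pair) so the realized dosage correlation matches `ld_rho` exactly
wherever the two MAFs allow it — the Pearson correlation of two binary
variables is Fréchet-bounded, so for very dissimilar adjacent MAFs the
target is capped at the attainable maximum. Two further properties matter
for interpretation: (1) threshold attenuation is strongest for adjacent
pairs, so beyond distance one the realized LD decays *more slowly* than
`ld_rho^d`; (2) at `ld_rho = 0.5` this leaves many SNP pairs near the
clumping bound (see above).

The protein is X = Σ_j γ_j G_j + ε with γ drawn per region: half-normal
|N(0, gamma_sd²)| by default (a pQTL's effect-allele orientation is
arbitrary, so positive signs lose no generality, and they keep "directional"
pleiotropy directional on the ratio scale), `fixed` (all γ = gamma_sd) for
equal-strength designs, or `ladder` (γ_j = gamma_sd·j/k) when graded
strengths are needed. Causal SNPs sit at random positions or evenly spaced
(`causal_snp_placement="spaced"`, encoding a protein with conditionally
independent cis signals). The outcome is Y = θX + Σ_{j∈invalid} α_j G_j + ε′,
with invalid instruments a configurable fraction of the causal set and α
drawn N(0, s²) (balanced) or N(s, s²) (directional), s = `pleiotropy_sd`.
Both traits are standardized to unit population variance (the Gaussian
noise variances are solved from the exact dosage covariance of the causal
set; configurations whose genetic variance reaches 1 raise an error), so θ
is in outcome SD per protein SD — the same scale as the MR estimates.
Reverse-causation datasets put the SNP effects on Y and set
X = reverse_effect·Y + noise.

Exposure, outcome and panel cohorts are disjoint by construction (separate
random streams), giving the two-sample design exactly. Marginal summary
statistics are per-SNP simple least squares; p-values use the two-sided
normal approximation, as biobank-scale GWAS software reports them. The
outcome table randomly swaps effect/other allele labels and (for
non-palindromic SNPs) strand letters, so harmonization is exercised on
every simulated dataset. All randomness derives from one integer seed via
counter-based stream splitting: region i is byte-identical regardless of
how many other regions are generated.

What the generator does *not* emulate: realistic human LD maps and
haplotype blocks, imputation noise, sample overlap between cohorts,
winner's-curse from discovery-based instrument choice in an external study,
assay (aptamer) measurement artefacts, and case-control outcome scales.
Passing validation therefore shows the pipeline is correct under its own
assumptions at realistic sample sizes, not that those assumptions hold in
any particular real dataset.

## Validation studies (frozen in `pqtlmr.scenarios`)

Conditions were designed once, by analytic power calculation plus pilot
simulation, and then frozen; the same functions back the test suite and the
acceptance script. Estimator-level studies use LD-free regions and the
ground-truth instruments so they benchmark the estimators themselves; the
end-to-end study gives the pipeline no access to the truth until scoring.

- **Null calibration** — θ = 0, 3 instruments, n = 5,000/cohort; IVW
  rejection at α = 0.05 over 200 replicates (binomial 99% envelope) and
  mean Cochran Q within ±0.3 of k−1 = 2 over 500 replicates. A balanced-
  pleiotropy variant (40% invalid, α ~ N(0, 0.25²)) checks that
  heterogeneity without bias leaves the size intact.
- **Recovery** — θ = 0.3, ladder strengths γ = 0.1/0.2/0.3,
  n = 20,000/cohort, 100 replicates; median IVW, Egger and weighted-median
  estimates within ±0.03. Ladder strengths are used because Egger needs
  strength dispersion (see above); with three near-equal random strengths
  the Egger median is unstable by construction.
- **Robustness** — ten equal-strength instruments (γ = 0.25), 40% invalid
  with directional α ~ N(0.25, 0.25²), n = 5,000, 100 replicates: the
  weighted median's absolute bias stays below 25% of IVW's. Equal
  strengths are the standard design here; with dispersed random strengths
  the weakest instruments' noisy ratios dominate the weighted median's
  finite-sample bias and the comparison measures noise, not robustness.
- **Egger intercept power** — 30 instruments, all invalid with
  α ~ N(0.05, 0.05²), n = 20,000, 100 replicates: intercept rejection
  > 50%. Thirty instruments are needed because the intercept SE scales
  with the residual (pleiotropy) scale over √k.
- **Directionality** — forward (θ = 0.3) and reverse (reverse_effect = 0.5)
  regions with fixed-strength instruments, exposure n = 10,000, outcome
  n = 20,000: forward direction with p < 0.05 in ≥95% of replicates;
  Steiger filtering drops ≥80% of reverse candidates.
- **End-to-end screen** — 5 causal (θ = 0.3) + 20 null proteins, 30
  SNPs/region, five evenly spaced equal-strength causal SNPs (γ = 0.15),
  ld_rho = 0.4, n = 20,000/cohort, panel 2,000; full pipeline; sensitivity
  ≥ 0.8 with zero false discoveries at 0.05/25. ld_rho = 0.4 makes
  clumping non-trivial (distance-1 neighbours are clumped at r² ≈ 0.16)
  while post-clump instruments are effectively independent; note that with
  20 null proteins even perfectly calibrated p-values produce at least one
  false discovery in ≈4% of seeds — the irreducible Bonferroni noise floor
  at a single-seed reading.

Problem sizes throughout were chosen to keep the full validation battery
around one minute on a single CPU while leaving comfortable statistical
margins.

## Enrichment

Over-representation uses the exact hypergeometric tail P(X ≥ overlap) with
the universe fixed to the coding genes of all tested proteins (the assay
panel is the sampling frame; a whole-genome universe would mistake panel
ascertainment for biology — both options are exposed). Terms are
intersected with the universe first and tested only when their intersected
size lies in [min_term, max_term] = [3, 500] by default; BH adjustment runs
over the tested terms. Hypergeometric p-values are discrete and therefore
super-uniform under the null — conservative, never anti-conservative — which
is the property the test suite checks. Druggability annotation is a plain
left join against a user-supplied gene→tier table; genes absent from the
table are labelled "unclassified".

## Known limitations

- First-order Wald SEs and normal/t reference distributions: fine for
  F ≥ 10, increasingly optimistic below.
- Residual post-clump LD is ignored by all estimators (see above).
- No conditional/joint analysis, proxy-SNP lookup, MR-PRESSO, mode-based
  estimators, multivariable MR or colocalization; no VCF/BGEN parsing,
  liftover, or multi-allelic handling.
- The weighted-median bootstrap SE is simulation-based; with very few
  instruments its p-values inherit bootstrap noise (seeded and
  reproducible).
- The aptamer→protein collapse for discovery counting uses an any-aptamer
  rule via the optional mapping; no aptamer-specific error model exists.
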