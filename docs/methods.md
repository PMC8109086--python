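# Methods

## Model and assumptions

All estimators address the two-sample summary-data model

    γ̂ⱼ ~ N(γⱼ, σ²_γⱼ),   Γ̂ⱼ ~ N(Γⱼ, σ²_Γⱼ),   Γⱼ = β·γⱼ + αⱼ,

where γⱼ is variant *j*'s effect on the exposure, Γⱼ its effect on the
outcome (both log-odds per effect-allele copy), β the causal effect of
interest, and αⱼ the direct (horizontally pleiotropic) effect, zero for
a valid instrument. The two studies are assumed independent (no sample
overlap) and drawn from the same ancestry, so allele frequencies are
comparable across them. Instrument validity further requires relevance
(γⱼ ≠ 0, enforced upstream by the significance filter) and the
exclusion restriction (αⱼ = 0), which the sensitivity estimators relax
in different directions: Egger allows directional αⱼ under InSIDE
(Cov(α, γ) = 0), the medians allow up to half the weight to be invalid,
RAPS absorbs systematic and idiosyncratic pleiotropy into an
overdispersion parameter and a robust loss, and MR-PRESSO removes
resolvable outliers.

## Estimators: numerical choices

**IVW (multiplicative random effects).** β̂ = Σwⱼrⱼ/Σwⱼ with
rⱼ = Γ̂ⱼ/γ̂ⱼ and first-order weights wⱼ = (γ̂ⱼ/σ_Γⱼ)² (exposure-side
noise ignored in the weights, the convention for this estimator). The
fixed-effect SE (Σwⱼ)^(−1/2) is multiplied by max(1, √(Q/(n−1))):
heterogeneity can widen the interval but under-dispersion never narrows
it. Normal reference for p and CI.

**MR-Egger.** Weighted regression of Γ̂ on γ̂ with intercept, weights
1/σ²_Γⱼ, after orienting every instrument so γ̂ⱼ > 0 (the fit is not
orientation-invariant; exposure-increasing alleles are the conventional
frame). The same multiplicative scale floor applies; inference uses t
with n−2 df. The intercept estimates the mean directional pleiotropic
effect.

**Medians.** The weighted median interpolates the inverse-variance-
weighted cumulative distribution of ratios at 0.5 (breakpoints
pⱼ = Sⱼ − wⱼ/2 on sorted ratios); the simple median is the equal-weight
case. SEs come from a seeded parametric bootstrap (default 1000
replicates) resampling each (γ̂ⱼ, Γ̂ⱼ) from normals at the observed
values with the observed SEs. This bootstrap is known to be mildly
conservative for medians — resampling around noise-spread observed
ratios inflates order-statistic spacing — so its CIs over-cover by
roughly 2–3 % in our validation runs; see Limitations.

**RAPS.** β̂ maximizes −Σρ(tⱼ) with standardized residuals
tⱼ(β, τ²) = (Γ̂ⱼ − βγ̂ⱼ)/√(σ²_Γⱼ + β²σ²_γⱼ + τ²), ρ quadratic or Huber
(constant 1.345). τ² = 0 unless `overdispersed=True`, in which case
(β, τ²) jointly solve the profile-score equation and the centred
second-moment equation Σ(ρ′(tⱼ)tⱼ − δ)/vⱼ = 0 with δ = E[ρ′(Z)Z] under
Z ~ N(0,1). The score root is bracketed outward from the IVW estimate
(step 2× the fixed-effect SE, growth 1.6) and solved by Brent's method
to 10⁻¹³; expanding to ±∞ is deliberately avoided because the profile
score decays to zero far from the optimum and would admit spurious
roots. The SE is the M-estimation sandwich √B/|A| with per-variant
scores ψⱼ and A the numerical score derivative. Non-convergence raises
an error reporting the last iterate and score norm.

**MR-PRESSO.** For each variant the expected outcome effect is the
leave-one-out fixed-effect IVW prediction β̂₋ⱼγ̂ⱼ. The observed RSS
(unweighted, matching the method's simulation construction in which σ
enters the resampling, not the sum) is compared against parametric
replicates drawing γ*ⱼ ~ N(γ̂ⱼ, σ_γⱼ) and Γ*ⱼ ~ N(β̂₋ⱼγ̂ⱼ, σ_Γⱼ), with
the leave-one-out slopes recomputed per replicate. The global empirical
p carries the +1 continuity correction; per-variant outlier p-values do
not — with 1000 simulations and ~50 variants, a +1-corrected Bonferroni
p could never fall below 0.05 and no outlier would ever be flagged.
Outliers are variants with Bonferroni-adjusted empirical p below 0.05
(configurable); the corrected estimate is the multiplicative
random-effects IVW on the remainder, and the distortion test compares
the observed percent change against removals of random same-sized
subsets.

## Selection and harmonization

Significance filtering keeps p < threshold strictly (default 5×10⁻⁸).
Clumping is greedy: the smallest-p remaining variant becomes an index
(ties broken by chromosome, position, rsid for determinism) and removes
same-chromosome neighbours within the window (default 10 kb,
configurable — conventional pipelines often use windows up to 10 Mb)
whose r² with it is at or above the threshold (default 0.001). LD
unknown to the panel is treated as r² = 1 within the window
(conservative removal; a "keep" policy is available), so missing panel
coverage can never leave correlated instruments in place.

Harmonization resolves swapped allele labels (negate Γ̂, reflect the
frequency) and strand complements (A↔T, C↔G translation) for
non-palindromic variants. Palindromic variants carry no strand
information in their alleles; when the exposure MAF is below the
threshold (default 0.3) the outcome effect is oriented so both studies'
effect-allele frequencies fall on the same side of 0.5, otherwise the
variant is dropped as ambiguous. Dropping all palindromes is available
as a switch since the frequency-alignment convention, though standard,
is not the only defensible action. A palindrome with a missing
frequency on either side is dropped (it cannot be aligned);
non-palindromic variants do not require frequencies. Every input
variant ends either in the output or in the drop log with a reason.

## Power

For a binary outcome, power uses the non-centrality approximation
NCP = N·R²·(ln OR)²·K(1−K) and power = Φ(√NCP − z₁₋α/₂), with N the
sample size, R² the variance in exposure liability explained by the
instrument (default 0.090), K the case fraction and OR the alternative.
With N = 76,312, R² = 0.090, K = 38,565/76,312 and OR = 1.07 at
α = 0.05 this gives 0.80. The case fraction uses the exposure study's
composition; that interpretation is what reproduces the 80 %/OR 1.07
pairing and is recorded here as a choice, since power calculators can
equally be parameterised by the outcome study. `detectable_or` inverts
the formula analytically.

## What the synthetic generator emulates

`generate(ScenarioConfig(...))` draws true exposure effects as
half-normal magnitudes (scale 0.08) truncated below at `gamma_min`
(default 0.03), with the effect allele defined as the
exposure-increasing allele. Both choices are deliberate emulations of
*selected* instruments: reported instruments are oriented, and a
genome-wide-significant locus at N = 76,312 has a true effect bounded
away from zero (0.03 ≈ 5.45 × the median exposure SE, the
detectability boundary). Without the truncation, sub-threshold
"instruments" whose observed effects cross zero would be sign-flipped
by Egger's orientation step and bias the intercept — an artefact of
mis-emulated selection, not of the estimator. With ~80 such instruments
the instrument strength is consistent with a polygenic immune exposure
whose score explains roughly 9 % of liability variance.

Standard errors follow 1/√(2·N·p(1−p)) for allele frequency
p ~ U(0.1, 0.9) (a case-control-scaled variant with an extra K(1−K)
factor is available); doubling N shrinks SEs by √2. Default sample
sizes are 76,312 (exposure) and 1,030,836 (outcome). Pleiotropy models:
`balanced` (α ~ N(0, 0.001²) — the default SD reproduces moderate
heterogeneity, Q/df ≈ 1.5, I² ≈ ⅓, typical of real instrument sets),
`directional` (nonzero mean), `outliers` (a few variants with direct
effects of `outlier_size` outcome-SE units), plus an `inside_violation`
correlation between α and γ. LD blocks emit proxies with √r²-attenuated
effects placed within the clumping window and recorded in the pairwise
LD table; palindromic alleles and randomized outcome-side strand/label
presentation give harmonization true positives and negatives with
recorded truth.

What it does **not** emulate: realistic human LD maps, winner's-curse
bias in the exposure effects (effects are drawn, not selected on their
observed z-scores), sample overlap between studies, allele-frequency
mismatch between ancestries, or exact logistic-regression standard
errors. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated model, not robustness to those
real-data features.

## Validation protocol and problem sizes

The test suite validates the estimators at the study's scale: 500
replicates of 80 instruments for recovery of a planted β = 0.1 (each
estimator's mean within 0.005; 95 % CI coverage in [0.92, 0.97]), 1000
null replicates for IVW type-I error (within [0.03, 0.07] at α = 0.05),
200 replicates for Egger-intercept recovery of planted directional
pleiotropy, and 100 seeded runs for MR-PRESSO detection of a 10-SD
outlier (≥ 95 %). Closed-form weighted least squares, a loop-based
median interpolation, and pairwise brute-force enumeration serve as
independent oracles for IVW, the weighted median and clumping. All
stochastic outputs are reproducible byte-for-byte from the seed; the
median-estimator coverage sits at the conservative edge of its band for
the reason given above.

## Known limitations

- First-order IVW weights ignore exposure-side noise; with weak
  instruments the estimate attenuates slightly (visible as recovery
  means ~0.0995 for a true 0.1). RAPS corrects this and is the better
  choice when instrument strength is marginal.
- The median estimators' bootstrap SEs are mildly conservative (see
  above); their intervals err on the wide side.
- Cross-language RNG streams are not portable: seeded results are
  reproducible within this package, not bit-identical to analyses run
  with other implementations.
- The distortion test's null (random same-sized removals) is
  conventional but approximate when outliers are many.
- No proxy-SNP substitution for instruments absent from the outcome
  study, no liftover, and no reference-genome strand check.
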