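# Methods

## The causal model

Two-sample drug-target MR treats cis variants near a target gene as
instruments for pharmacological modulation of that target. For SNP *j* with
per-allele exposure effect β̂ₓⱼ (SE σₓⱼ) and outcome effect β̂ᵧⱼ (SE σᵧⱼ),
estimated in non-overlapping cohorts and expressed on one shared effect
allele, the per-SNP causal estimate is the Wald ratio θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with
first-order SE σᵧⱼ/|β̂ₓⱼ|. The identifying assumptions are the usual IV
triple (relevance, exchangeability, exclusion); the package quantifies
relevance with per-SNP F-statistics, probes exclusion with pleiotropy-robust
estimators and colocalization, and probes reverse causation with the
Steiger test.

All standard errors are first-order ("NOME"): exposure estimates enter the
weights as fixed quantities. This is the convention for summary-data MR and
is accurate when instruments are strong (F ≫ 10); with weak instruments it
understates uncertainty and biases IVW slightly toward the null.

## Instrument construction

1. **Window**: SNPs within ±`window_kb` (default 500 kb) of the gene body,
   1-based inclusive coordinates on GRCh37, closed on both ends.
2. **Threshold cascade**: the first threshold in `p_cascade`
   (default 5×10⁻⁸ then 5×10⁻⁶) that yields any SNP in the window is used
   and recorded; the relaxed fallback is applied per locus, reflecting
   practice at loci with no genome-wide significant biomarker signal. A
   locus empty at every level raises an instrumentation error naming it.
3. **Clumping**: greedy — rank by p ascending (ties: larger |z|, then
   lexicographic id), keep the best remaining SNP, discard everything with
   r² ≥ `ld_r2_max` (default 0.1) against it. The result provably equals
   the rank-lexicographic-minimal maximal independent set, which the test
   suite verifies by exhaustive enumeration on small instances.
4. **Dual targets** concatenate per-locus instruments (loci must be
   disjoint; no cross-locus LD check, matching the construction of combined
   two-receptor instruments from per-locus ones).
5. **Diagnostics**: Fⱼ = (β̂ₓⱼ/σₓⱼ)², r²ⱼ = Fⱼ/(Fⱼ + n − 2); set-level R²
   sums r²ⱼ, treating clumped SNPs as independent. Fⱼ < 10 triggers a
   weak-instrument warning.

### Harmonization

The outcome table is aligned to the exposure's effect alleles: swapped
alleles negate β̂ᵧ and reflect the EAF; complementary alleles are mapped to
the exposure strand first. Palindromic SNPs (A/T, C/G) cannot be resolved
from labels; by default they are aligned by allele frequency when
min(f, 1−f) < 0.42 for **both** traits and dropped otherwise (0.42 is the
conventional ambiguity bound; policies `drop` and `keep` are available).
SNPs with missing outcome EAF are kept unless palindromic. Harmonization is
idempotent and every row records the action taken.

### Orientation and the reporting scale

`orient_to_agonism` flips allele labels so each stored exposure effect is a
positive magnitude — after orientation the effect allele is the
biomarker-**raising** allele. Agonism *lowers* the biomarker, so the
pipeline's `direction: lowering` (default) negates reported causal
estimates, which then read as outcome change per 1 SD biomarker decrease
(ORs are exponentiated log-odds on the same scale). Carrier-prevalence
inputs should therefore be the frequencies of the *lowering* (activation)
alleles, i.e. 1 − EAF of an oriented instrument.

## Estimators

- **IVW**: weighted regression of β̂ᵧ on β̂ₓ through the origin, weights
  σᵧ⁻²; fixed-effect SE (Σβ̂ₓ²σᵧ⁻²)^(−1/2). The multiplicative
  random-effects variant scales the SE by max(1, √(Q/(k−1))). Default
  choice: fixed below 4 SNPs, random-multiplicative otherwise (a pragmatic
  convention — with 2–3 SNPs Q estimates dispersion too poorly to be
  useful).
- **MR-Egger**: weighted regression with intercept after sign-orienting
  each SNP to β̂ₓⱼ ≥ 0; intercept estimates directional pleiotropy. SEs are
  scaled by max(1, √(Q_resid/(k−2))); intervals and p-values use t
  quantiles at k−2 df.
- **Weighted median**: per-SNP ratios with normalized weights
  wⱼ = (β̂ₓⱼ/σᵧⱼ)²; the estimate interpolates the ratio at cumulative
  weight-midpoint 0.5. Consistent when valid instruments carry > 50% of
  weight.
- **Weighted mode**: argmax of a weighted Gaussian kernel density over the
  ratios on a 512-point grid; bandwidth h = factor · 1.4826·MAD · k^(−1/5)
  (SD fallback when MAD = 0; identical ratios return the common value).
  Consistent when the largest group of instruments sharing one causal
  effect is valid.
- **Median/mode SEs**: parametric bootstrap — resample (β̂ₓ, β̂ᵧ) from
  their normal sampling distributions, 1000 reps by default, seed recorded
  in the result's notes.
- **MR-LASSO**: β̂ᵧⱼ = αⱼ + θβ̂ₓⱼ with L1-penalized per-SNP intercepts,
  solved by alternating soft-thresholding (exact for this objective) on a
  50-point log grid from λ_max (all αⱼ = 0) down to 0.001·λ_max. λ is
  chosen by the heterogeneity stopping rule: the largest set of
  zero-intercept SNPs whose post-selection Q is below the χ²₀.₉₅ critical
  value at its df; θ̂ is fixed-effect IVW on that set. If no λ gives ≥ 2
  valid SNPs passing the rule, the method reports itself unavailable.
- **Cochran's Q**: Σwⱼ(θ̂ⱼ − θ̂_IVW)² with wⱼ = (β̂ₓⱼ/σᵧⱼ)², p from
  χ²(k−1). Exact χ² calibration holds when exposure-side noise is
  negligible; the test suite verifies it in that regime.
- **Steiger**: per-trait variance explained recovered from p and n via
  t² at n−2 df, r²ⱼ = t²/(t² + n − 2), summed over instrument SNPs;
  direction is "forward" when r²(exposure) > r²(outcome), with a Fisher-z
  two-correlation p-value. Quantitative traits only — liability-scale r²
  for binary outcomes is out of scope and such rows are flagged
  `not_computed` by the pipeline.

Wald ratio is the primary method for single-SNP instruments, IVW otherwise;
the sensitivity suite runs from 3 SNPs. CIs use 1.96·SE except Egger's
t-based intervals.

## Colocalization

Per SNP, log approximate Bayes factor ½(log(1−r) + r·z²) with z = β̂/σ̂,
V = σ̂², shrinkage r = W/(W+V). Prior effect SD √W defaults to 0.15·sdY for
quantitative traits and 0.2 (log-odds) for case-control — the cited
conventions; only the configuration priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ are
study-specified. Posteriors over H0–H4 are computed entirely in log space
(log-sum-exp; H3's off-diagonal sum via a guarded log-difference that
returns exactly zero probability for single-SNP loci) and equal naive
linear-space enumeration to 10⁻¹⁰ on small loci. When sdY is unknown it can
be estimated by regressing 2f(1−f)n on 1/σ̂² through the origin
(sdY² = slope); a user-supplied value always wins. PP.H4 > 0.60 labels a
shared variant but never filters output, and the conditional ratio
H4/(H3+H4) is always reported (missing when H3+H4 = 0). In the pipeline,
colocalization runs only for pairs with primary MR p < 0.05 (forceable).

## Mediation

Product of coefficients: indirect = β₁β₂, Sobel SE
√(β₁²se₂² + β₂²se₁²) under two-sample independence (first-order: the
second-order se₁²se₂² term is omitted, < 1% of the variance for moderate
effect/SE ratios, as the Monte-Carlo comparison in the tests shows).
Proportion mediated = indirect/total with first-order SE treating total as
independent. The proportion is suppressed (reported missing, with a reason)
when signs of indirect and total conflict or when |total| < 10·se_total,
because the ratio is numerically unstable near a null total; both
thresholds are configurable. Step 2 uses genome-wide instruments for the
mediator, univariable (no adjustment for the exposure).

## Carrier prevalence

P_carrier = 1 − (1−f)² per SNP under Hardy–Weinberg;
P_locus = 1 − Π(1−fᵢ)² across the independent SNPs of a clumped instrument;
ancestry-level prevalence is the arithmetic mean of P_locus across
instrument sets. Residual LD below the clumping threshold is ignored (a
warning is emitted when a supplied LD matrix exceeds it). Values are stored
at full precision and rounded to two decimals for presentation. Note one
quirk of the source material this model reproduces: a single-SNP instrument
with f = 0.46 has P_locus = 0.71, which is *not* the same as the fraction
of allele carriers sometimes quoted as 46% — under Hardy–Weinberg the
carrier fraction of such a SNP is exactly 0.71, not 0.46.

## Synthetic data

The generator emulates two-sample summary statistics on one imputation
panel: EAFs uniform on [0.05, 0.95]; LD correlation R block-constant
(5-SNP blocks, ρ = 0.5; positive definite by construction) or AR(1);
marginal true effects R·β_causal; sampling SE 1/√(2nf(1−f)) for a
unit-variance trait and 1/√(2ns(1−s)f(1−f)) on the log-odds scale for
case-control outcomes (an approximation adequate for method testing, not a
likelihood-exact binary-trait model). Exposure and outcome estimates are
drawn from independent multivariate normals with correlation R; outcome
true effects are θ·(marginal exposure effects) plus per-SNP pleiotropy on a
configurable invalid fraction (balanced or directional). Defaults — 60
SNPs, exposure n = 350k, outcome n = 150k, 5 causal SNPs with per-allele
effects 0.01–0.05 SD (instrument F in the tens to hundreds), no invalid
instruments — represent a well-powered biomarker GWAS against a moderately
powered outcome GWAS. Noise scales of 0 give the noise-free diagnostic mode
in which every estimator must return θ exactly.

What the generator does **not** emulate: realistic human LD maps,
individual-level ascertainment, sample overlap between the two cohorts,
allele-frequency differences between cohorts, and genuine binary-trait
likelihoods. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated sampling model, not robustness to those
real-data complications.

The study corpus (`make_study_corpus`) materializes two targets (GLP1R-like
on chr6, GIPR-like on chr19; 40 SNPs per locus), two biomarkers with
primary/replication sources (n = 700k/650k for the BMI analog,
350k/320k for HbA1c, echoing large-consortium scales), and three outcomes
(two quantitative, one case-control with s = 0.3) at n = 150k. The
GLP1R×BMI locus is generated with peak true |z| = 5.2 — below genome-wide
significance — so the threshold cascade's relaxed level is exercised when
the sampled peak lands below 5×10⁻⁸; which level a given seed lands on is
recorded in the run metadata. Outcome true effects are θ-weighted sums of
both biomarkers' marginal effects, so each biomarker's MR approximately
recovers its own θ.

## Numerical and design notes

- Bootstrap draws hitting β̂ₓ = 0 exactly are nudged to the smallest
  positive float before forming ratios (probability-zero event, guards the
  division).
- LD matrices failing Cholesky are eigenvalue-clipped at 10⁻⁸ and rescaled
  to unit diagonal, with a warning.
- Tie-breaking everywhere is deterministic (stable sorts, lexicographic
  ids); re-running any seeded computation reproduces results bit-for-bit,
  and the pipeline's report files are byte-identical across reruns.
- p-value/z consistency on read is a warning, not an error (published
  tables round); relative tolerance 10⁻³ on −log₁₀ p.
- The problem sizes used by the heavier test-suite checks — 2000 replicates
  for IVW coverage, 5000 for Q calibration, 200 per colocalization
  scenario, 10⁵ Monte-Carlo draws for the Sobel comparison — were chosen so
  Monte-Carlo error is comfortably below each assertion's tolerance.

## Known limitations

- No multivariable MR, MR-PRESSO/CAUSE, SuSiE-style multi-causal-variant
  colocalization, fine-mapping, liftover, VCF parsing, or LD estimation
  from genotypes (LD matrices are inputs or simulated).
- Binary outcomes are analysed on the log-odds scale throughout and
  exponentiated only for reporting.
- Set-level R² assumes post-clumping independence; with residual r² up to
  the clumping threshold it slightly overstates variance explained.
- The weighted-mode estimate depends smoothly on its bandwidth factor;
  results at alternative bandwidths are worth reporting alongside the
  default.
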