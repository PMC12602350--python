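# targetmr

Drug-target Mendelian randomization (MR) on GWAS summary statistics.

`targetmr` is for epidemiologists and statistical geneticists who want to
anticipate the effects of pharmacologically modulating a drug target — an
incretin receptor such as GLP1R or GIPR, say — using only published GWAS
summary statistics. Genetic variants in a window around the target gene
(*cis* instruments) that alter a biomarker the drug changes (HbA1c, BMI)
act as lifelong, randomized proxies for taking the drug; two-sample MR then
estimates the downstream effect on outcomes such as alcohol use, liver
health, or disease risk.

The package implements the full analysis surface of such a study:

- **Summary-statistics I/O and harmonization** — validated per-SNP tables
  (β̂, SE, EAF, p, n), cis-window slicing, allele alignment across the two
  samples with strand-flip and palindromic-SNP handling.
- **Instrument construction** — p-value threshold cascade (5×10⁻⁸, falling
  back to 5×10⁻⁶ at under-powered loci), greedy LD clumping at r² < 0.1,
  dual-target instruments concatenating two loci, per-SNP F-statistics
  F = (β̂/σ̂)² and variance explained r² = F/(F + n − 2).
- **Estimators** — Wald ratio (1 SNP) and inverse-variance weighted (IVW,
  θ̂ = Σβ̂ₓβ̂ᵧσᵧ⁻² / Σβ̂ₓ²σᵧ⁻²) as primaries; MR-Egger, weighted median,
  weighted mode and MR-LASSO as pleiotropy-robust complements; Cochran's Q
  and the Steiger directionality test as diagnostics.
- **Colocalization** — single-causal-variant approximate-Bayes-factor
  posteriors PP.H0–PP.H4 with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, plus the
  conditional ratio H4/(H3 + H4) for weak outcome signals.
- **Two-step MR mediation** — product-of-coefficients decomposition with
  Sobel standard errors.
- **Carrier prevalence** — Hardy–Weinberg carrier probabilities
  P = 1 − (1 − f)² per SNP and P_locus = 1 − Π(1 − fᵢ)² per instrument,
  summarizing how common "agonist-like" alleles are per ancestry.
- **Synthetic-data generator** — two-sample summary statistics with block
  or AR(1) LD, configurable causal effects, pleiotropy and colocalization
  scenarios H0–H4, with ground truth for every recovery test.
- **Pipeline** — a YAML-configured study runner (targets × biomarkers ×
  primary/replication sources × outcomes) with Bonferroni and
  replication-consistency flags, exposed as the `targetmr` CLI.

## Worked example

Generate a synthetic study and run it end to end:

```bash
targetmr simulate --outdir corpus --seed 7
targetmr run --config corpus/study.yaml --outdir corpus/out
```

`corpus/out/report.tsv` holds one row per target × biomarker × source ×
outcome × method. The GIPR target's primary rows (seed 7) look like:

```
target biomarker      source      outcome    method n_snp    beta     se    pval bonferroni_pass replication_consistent
  GIPR     HbA1c     primary alcohol_freq ivw_fixed     2 -0.2287 0.0948 0.01585           False                   True
  GIPR     HbA1c replication alcohol_freq ivw_fixed     2 -0.3053 0.0987 0.00198            True                   True
```

Estimates are on the per-1-SD-biomarker-*decrease* scale: here, genetically
lowering HbA1c through GIPR variants reduces drinking frequency by ~0.23 SD
(primary) and ~0.31 SD (replication). Both sources are significant at 0.05
with concordant signs, so the replication-consistency flag is set; only the
replication row clears the Bonferroni threshold 0.05/20 = 0.0025. The true
simulated effect behind these data is 0.20 SD. Case-control outcomes carry
odds-ratio columns instead; `format_or_percent(0.62)` renders an OR as
"38% lower odds".

Colocalization runs for pairs whose primary MR p < 0.05
(`corpus/out/coloc.tsv`). With a modest outcome GWAS most posterior mass
sits on H1 (exposure-only signal); the conditional ratio H4/(H3 + H4) then
distinguishes shared from distinct causal variants:

```
target biomarker      outcome locus n_snp  pp_h1   pp_h3  pp_h4 conditional_h4
 GLP1R     HbA1c alcohol_freq GLP1R    40 0.9821 0.00046 0.0174         0.9742
```

Carrier prevalence from the library:

```python
>>> from targetmr import snp_carrier_prob, locus_carrier_prob
>>> round(snp_carrier_prob(0.46), 2)   # single-SNP instrument, EAF 0.46
0.71
>>> round(locus_carrier_prob([0.25]), 2)
0.44
```

i.e. 71% of individuals carry at least one activating allele of a
single-SNP instrument whose effect-allele frequency is 0.46.

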