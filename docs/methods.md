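# Methods

## Scope and data model

The package implements a complete case-control genetic-association
meta-analysis for a biallelic polymorphism. A `StudyRecord` carries one
study's genotype counts (Val/Val, Val/Leu, Leu/Leu) for cases and
controls, or — for publications that only report allele carriage —
Leu-carrier counts; group sizes must equal the genotype sums, and exactly
one of the two count kinds may be present. The packaged IS (6 studies) and
MI (13 studies) tables are transcribed per-study from the source
literature; printed column totals are never used as data. One MI study
(Butt2003) is carrier-only; one control group (Siegerink2009) is recorded
with the size implied by its genotype counts (747) because the published
group size (767) is inconsistent with its own genotype sum — no pooled
quantity depends on the group-size column for full-genotype studies.

## Genetic models and 2×2 derivation

Each of the five contrasts (dominant, recessive, additive, heterozygous,
allelic) selects exposed/unexposed columns from the genotype counts; the
additive and heterozygous contrasts drop the non-contrasted genotype's
individuals entirely rather than recoding them, because each names exactly
two genotype classes. The allelic model counts alleles (2 per person).
Carrier-only studies are usable only under the dominant model, the single
contrast computable from carriage.

Zero cells follow the Cochrane/RevMan convention: a study with zero
exposed (or zero unexposed) in both arms carries no odds-ratio information
and is excluded from that model with a logged reason; a single-arm zero
adds 0.5 to all four cells and flags the table as corrected. The published
analyses this package reproduces were run in software using the same
convention, and the pooled values match only under it.

## Pooling

Per-study effects are log odds ratios with Woolf variances, computed on
corrected cells where correction was applied. Fixed-effect pooling is
Mantel–Haenszel with the Robins–Breslow–Greenland variance for the log
pooled OR; the MH sums use each table's stored cells (corrected only where
a zero forced it). Random-effects pooling is DerSimonian–Laird: Cochran's
Q around the inverse-variance fixed estimate, the moment τ², and
re-weighting by 1/(v&#7522;+τ²). Heterogeneity (Q, I², τ²) is always
computed from inverse-variance log-OR weights, including when the fixed
pool is MH — the RevMan convention, required to match the published
random-effects results. Confidence intervals use the normal 1.96
multiplier, not t; p values are two-sided normal. "Significant" means the
95% CI excludes OR = 1.

Method selection (`select_method`) defaults to random effects when
I² ≥ 50% (boundary inclusive; threshold configurable). The publication
reproduced here did not state its exact fixed-vs-random trigger, so the
pipeline records the method used with every result, and `run_meta` accepts
`force_fixed`/`force_random` to pin it; reproduction of the published MI
results uses `force_random`, matching the published choice for those
models even where the recomputed I² sits just below 50%.

## Quality and bias diagnostics

Control-group genotypes are tested against Hardy–Weinberg proportions at
the sample's own allele frequency with a 1-df χ² (three classes, minus
one, minus one estimated frequency) and no Yates correction; the published
per-study statistics recompute exactly under these choices. Monomorphic
samples return χ² = 0, p = 1 with a flag. Out-of-HWE studies are flagged,
not excluded.

Egger's test is the classic unweighted OLS of the standardized effect
y&#7522;/se&#7522; on precision 1/se&#7522;, intercept CI and p from the t
distribution on k−2 df. Begg's test rank-correlates variance-stabilised
deviations from the inverse-variance fixed pool with the study variances
using Kendall's τ-b; because small study counts make the p value sensitive
to the continuity correction of the normal approximation, both the
uncorrected (primary) and corrected p are reported. Both tests require
k ≥ 3. Funnel output is plot-ready coordinates (per-study log-OR and se,
plus the ±1.96·se pseudo-confidence fan around the fixed pool), not
rendered images.

Known limitation: a handful of published Egger intercepts (and all
published Begg p values) deviate slightly from these variants — by
≲0.09 on the intercepts — reflecting undocumented internals of the
original analysis software; the package documents its variants and the
tests treat those entries as approximate.

## Sensitivity

Leave-one-out re-pools every k−1 subset under the same method. Stability
is defined on significance flips — the criterion used in the published
analyses — with per-row ORs and CIs reported so magnitude drift can also
be inspected. Each row is verified (by test) to equal an independent
pooling of the explicit subset.

## Synthetic data

The generator emulates the structure of the packaged study sets: control
genotypes are multinomial draws from Hardy–Weinberg proportions at a
configurable Leu frequency (default 0.25, typical of European-ancestry
samples); each study's dominant-contrast log odds ratio is drawn from
Normal(ln OR, τ²) and the case genotype distribution is tilted so the
carrier-vs-noncarrier odds ratio equals that draw, preserving the HWE
Val/Leu : Leu/Leu ratio within carriers. Truth is therefore injected on
the dominant contrast (the headline model); the other models' true effects
are emergent. Defaults: 13 studies, case groups 30–400, control groups
50–800, dominant OR 0.8, τ = 0. A single integer seed drives one
`numpy` Generator; no global state. When HWE in controls is disabled, a
fixation-index-style heterozygote deficit (f = 0.3) is applied.

What the simulator does not emulate: confounding, genotyping error,
selective publication, covariate adjustment, or ethnic stratification —
passing recovery/type-I tests shows the statistical chain is correctly
implemented and calibrated under clean sampling, not that real studies are
free of those problems.

Monte-Carlo checks in the test suite use 500 replicates (≈1 s each on one
CPU): the pooled z-test's null rejection rate is checked within 3.5
binomial standard errors of 5%, the HWE test within 3–7%, and the mean DL
estimate over 13-study replicates (sizes spanning the packaged MI range)
against its simulation CI around the true OR 0.8.

## Numerical choices

- CI multiplier 1.959963984540054 (normal 97.5th percentile) throughout.
- I² floored at 0 when Q < df; τ² floored at 0.
- DL with k = 1 degenerates to the single study (Q = 0, τ² = 0).
- Begg p values capped at 1; continuity correction clamps |S|−1 at 0.
- Exported CSV floats use `%.6g` so re-exports are byte-identical.
- `select_method` ties (I² exactly 50) go to random effects, documented
  boundary-inclusive.
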