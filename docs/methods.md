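# Methods

This note documents the statistical models implemented in `candgene`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Study design being replicated

The package replicates the analysis chain of a candidate-gene resequencing
case-control study of NAFLD: ~218 ultrasound-defined cases and ~227 healthy
controls, genotyped at four index SNPs (PNPLA3 rs738409-G, TM6SF2
rs58542926-T, GCKR rs1260326-T, MBOAT7 rs641738-T) and resequenced across
five candidate genes (GCKR, LYPLAL1, NCAN, PPP1R3B, TM6SF2). Risk-allele
orientation is fixed per SNP as listed; dominant/recessive collapses are
defined with respect to the risk allele. Case severity uses the
semi-quantitative ultrasound steatosis scale 0–6 (0 absent, 1–2 mild, 3–4
moderate, 5–6 severe), with "severe" defined as grades 5–6.

## Variant QC

A call is high-confidence iff DP ≥ 30, GQ ≥ 30, the alternate-allele
fraction (percent scale) lies in [33, 50] (heterozygous window) or
[70, 100] (homozygous window), and alternate observations are balanced
across strands. All thresholds are inclusive. "Balanced" strand support is
not quantified in the source protocol; the default here requires each
strand to carry at least 20% of the alternate observations
(`strand_balance_min = 0.2`, configurable). A record claiming alternate
support (AF > 0) but with no strand-resolved alternate reads fails the
STRAND rule. Filtering is idempotent and every rejected record carries its
failed rules in a fixed order (DP, GQ, AF, STRAND). MAF classes partition
[0, 0.5]: rare < 0.01 ≤ low-frequency < 0.05 ≤ common. Functional
annotations are nonsense, frameshift, splice-region and missense; the
annotation is taken from the input VCF, never recomputed from gene models.

A secondary Sanger-retest rule (drop calls with AF < 33 and DP < 20 among
moderate-quality variants) is reported in the source protocol but its
relation to the primary filter is unclear; only the primary filter is
implemented.

## In-silico consensus

Each of five predictor roles contributes 0 (neutral/benign/polymorphism),
1 (possibly damaging — a PolyPhen-2-specific grade) or 2 (deleterious /
probably damaging / disease causing) to a collective 0–10 score. The binary
"damaging" call requires a full deleterious verdict from at least 3 of the
5 tools; the intermediate grade deliberately does not count, because the
scoring map assigns it its own code. Consequently `is_damaging` implies a
collective score ≥ 6. Tool vocabularies are normalized through a
configurable mapping shipped with sensible defaults. The aggregator is not
wired into the burden test by default: qualifying "functional" status rests
on annotation class alone, mirroring the source analysis.

## Contingency statistics

No Yates continuity correction is applied anywhere — the uncorrected
Pearson statistic is what reproduces the published χ² values (14.66→"14.6",
6.39, 11.76→"11.7", 11.2, 4.693, 3.487) from the printed genotype counts.
(The genotypic values appear truncated, not rounded, in print; the published
p-value 0.014 attached to the dominant χ² 6.39 corresponds to the
continuity-corrected statistic and is inconsistent with its own χ² — the
package reports the p implied by the uncorrected statistic, 0.0114.)
Odds-ratio intervals use the Woolf log interval with z = 1.96, which
reproduces the printed CIs to within one unit in the last digit. Zero cells
get the Haldane–Anscombe 0.5 correction and a flag; a genotype row with no
carriers in a group is reported non-estimable (the published table prints
"—" for the TM6SF2 TT row). The published TM6SF2 table itself is internally
inconsistent (CC = 161 in the table vs 193 wild-type cases in the text);
only 193 reproduces the printed dominant χ²/OR, so worked examples use 193.

Hardy–Weinberg χ² uses the sample allele frequency, 1 df; monomorphic
samples return (0, 1). Missing genotypes are handled complete-case per SNP.

Carrier-burden tests compare subjects carrying ≥ 1 functional variant per
gene between groups (Pearson χ² + Woolf OR). Family-wise correction across
genes defaults to Bonferroni — the source reports losing significance
"after correction" without naming a method, so this is an interpretation,
configurable and documented as such.

## Logistic layer

Maximum-likelihood logistic fits are delegated to statsmodels (Newton
iterations, log-likelihood tolerance 1e-8, max 100 iterations); separation
or divergence (|β| > 30) is flagged as non-convergent rather than silently
reported. Forward stepwise selection enters the candidate with the smallest
Rao score-test p-value below `entry_p` (default 0.05) and removes included
terms with Wald p above `removal_p` (default 0.10) — the convention of the
commercial package used in the source analysis; both are configurable, and
the full entry/removal trace is returned. Skewed covariates (TG, HOMA-IR)
are log-transformed before entering regressions.

Hosmer–Lemeshow uses deciles of risk (default 10 groups), df =
groups − 2, merging tied-probability groups and flagging fewer than three
surviving groups as non-informative. Nagelkerke R² is the Cox–Snell
pseudo-R² `1 − exp(2(ll₀ − ll₁)/n)` rescaled by its maximum
`1 − exp(2·ll₀/n)`.

The bootstrap adjustment resamples subjects with replacement (B ≥ 100,
default 1000), refits, and computes each term's adjusted two-sided p as the
add-one fraction of replicates whose coefficient deviates from the observed
estimate by at least the observed magnitude (a shift/percentile scheme;
the source does not state which bootstrap p-value variant it used), with
2.5/97.5 percentile intervals. More than 10% non-convergent replicates
aborts with a diagnostic. Interaction tests keep both main effects, Wald-
test the product term, and reject aliased products by a rank check.

## Genetic risk score

Weighted GRS = Σ βᵢ·dᵢ with external per-allele weights (0.2653, 0.2711,
0.0649, 0.0575); unweighted GRS is the plain allele count (theoretical
range 0–8; the source cohort observed a maximum of 7 because risk-allele
homozygotes at TM6SF2 were nearly absent — the type admits 8 and tests
assert the observed maximum separately). Fixed tertile cuts are
T1 ≤ 0.1775 < T2 ≤ 0.3877 < T3; the source legend prints both 0.3877 and
0.3887 for the upper cut (an internal inconsistency) and 0.3877 — the value
used in the interval definition — is the default, with any pair settable
via configuration. Whether the original cuts were computed on the whole
cohort or controls only is unstated; empirical cuts are recomputed from
whatever score set is supplied. Subjects missing any panel genotype are
excluded, never imputed. The trend test is the Pearson χ² over the
2×3 tertile × status table plus per-tertile ORs against T1.

## Power model

Penetrances are solved from prevalence K under HWE with genotype relative
risks (1, r, 2r−1) for the additive model — risk-scale additivity, the
convention of the genetic-association power-calculator family, with
"OR ≈ 2.0" treated as r = 2.0 — or (1, r, r²) for multiplicative.
Case/control genotype distributions follow by Bayes ascertainment, and
power is the two-proportion normal approximation on the 2N-allele
comparison: pooled variance under H0, unpooled under H1, two-sided α.
This reproduces 87% for the low-frequency design (p = 0.03, r = 2.0,
218/227, K = 0.30, α = 0.05) and >99.9% ("100%") for the common design
(p = 0.30). A Cochran–Armitage trend variant is available. At the stated
detectable effect sizes the design's power is ≥ 0.80 for r = 1.9
(low-frequency) and 0.795 — i.e. 0.80 within rounding — for r = 1.35
(common); the inverse solver confirms the minimum detectable r at 80%
power. Monte-Carlo validation draws case/control genotype counts directly
from the ascertained distributions — exactly equivalent in distribution to
per-subject penetrance rejection sampling — and applies the allelic Pearson
χ²; monomorphic replicates are counted as non-rejections.

## Synthetic cohort generator

The generator defines the study conditions used throughout the tests:

* Genotypes: HWE in the source population; defaults
  rs738409 (freq 0.30, per-allele OR 2.0), rs58542926 (0.07, 2.5),
  rs1260326 (0.42, 1.5), rs641738 (0.41, 1.4) — control-population
  frequencies taken from the published genotype tables and ORs in the
  moderate band reported for these loci. SNPs are independent by default;
  an optional Gaussian-copula `ld_r` induces pairwise haplotype LD (the
  source reports a cross-carrier overlap but the joint distribution is not
  recoverable, so correlation strength is a free knob, off by default).
* Disease: additive-on-the-log-odds logistic model,
  `logit P(D) = logit(K) + Σ d·ln(OR) + Σ β_c (x_c − x̄_c)`, with
  K = 0.30 and covariate terms centred at their generative means so the
  stated baseline prevalence is the prevalence of an average subject. The
  source never states its generative model; additive log-odds coding is the
  conventional choice matching its logistic analyses.
* Covariates: age ~ N(50, 11²) years, BMI ~ N(26, 3.5²) kg/m², sex 66%
  male; glucose, insulin and TG log-normal with parameters matched to the
  published control medians and interquartile ranges; HOMA-IR derived as
  glucose·insulin/405 (mg/dL × U/L). Covariate log-odds defaults: age 0.02,
  male 0.20, BMI 0.19, log HOMA-IR 0.80, log TG 0.60 — moderate effects
  that reproduce the direction and rough size of the published case-control
  covariate contrasts.
* Ascertainment: retrospective rejection sampling from the population model
  until both quotas fill, capped at 1000 × (n_cases + n_controls) draws
  with an explicit error beyond the cap.
* Severity: case steatosis grades drawn as ~23.7% mild (1–2), ~43.7%
  moderate (3–4), ~32.6% severe (5–6), i.e. ~76% moderate-to-severe;
  controls are grade 0.
* Seeding: a single integer seed drives one named generator; identical
  specs and seeds give byte-identical subject tables.

What the generator does **not** emulate: sequencing reads and error
profiles (QC metrics in VCF fixtures are drawn directly), linkage beyond
the optional pairwise knob, covariate-covariate correlation beyond what the
disease model induces, population stratification, and genotyping error.
Tests passing on these cohorts therefore demonstrate the correctness and
calibration of the statistical machinery under the assumed model, not
robustness to real-data artefacts.

## Problem sizes used in tests

Simulation-based checks use sizes chosen to keep Monte-Carlo error well
below the asserted tolerances while remaining quick: 1,000 null cohorts at
the study's 218/227 for the type-I calibration of the collapse→χ² pipeline;
3,000/3,000 subjects for coefficient-recovery and stepwise-ranking checks;
1,000 replicates for Monte-Carlo power agreement (2-SE criterion); 300–600
replicates for permutation and calibration oracles; bootstrap determinism
at B = 300 and null calibration at B = 100 across 60 datasets.

## Known limitations

* Covariate-adjusted published results (adjusted ORs, the stepwise model's
  exact coefficients, the GRS cohort medians) depend on unreleased
  individual-level data and are validated structurally on synthetic
  cohorts, not numerically.
* The bootstrap p-value variant and the burden-test multiplicity correction
  are documented interpretations of underspecified source procedures.
* The logistic layer assumes complete covariate data; no missing-data
  machinery beyond complete-case genotype handling is provided.
* The power model uses the normal approximation; exact small-sample power
  is out of scope.
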