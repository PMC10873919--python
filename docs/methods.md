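# Methods

`felhcm` evaluates candidate disease variants in breed-structured cat
populations, end to end: breed-stratified allele frequencies, case-control
odds ratios under three inheritance codings, design-phase sample-size
calculations, and an ACMG-style classification engine that contrasts the
fixed 5% allele-frequency cutoff with a disease-prevalence-aware
alternative threshold (Tv). This note records the model, its assumptions,
the numerical choices, and what the synthetic-data tests do and do not
show.

## Cohort filtering

The association phase works on animals with an echocardiographic phenotype
label. Three exclusion families apply before any statistic is computed:

* **Phenotypic.** Equivocal animals (left-ventricular diastolic wall
  thickness strictly between 5 and 6 mm), restrictive-cardiomyopathy
  diagnoses, and phenotype-unknown animals are dropped. Healthy controls
  younger than `control_min_age_years` (default 6.0, roughly the median age
  of diagnosis for feline HCM) are dropped so that young not-yet-converted
  animals do not dilute the control arm; the boundary is strict (`< 6`
  excluded, exactly 6.0 retained). Controls with unknown age are excluded
  for the same reason — the cutoff cannot be verified. Affected animals are
  retained at any age, including unknown age: disease can present from a
  few months of age and a positive diagnosis is not age-confounded the way
  a negative one is.
* **Breed.** Each variant is assessed within the breed where it was first
  described; the caller subsets the cohort by breed (breed names are
  compared case-insensitively after whitespace normalization, since they
  are owner-reported). A cross-breed analysis is the same machinery without
  subsetting.
* **Genotypic.** Animals carrying any non-reference allele at any *other*
  catalogued variant are excluded, so each variant is evaluated on an
  otherwise wild-type background; animals with a missing genotype at the
  target variant are excluded from that variant's analysis only.

Every exclusion is recorded with a reason code
(`EQUIVOCAL`, `RCM`, `UNKNOWN_PHENO`, `CONTROL_UNDER_AGE`,
`NON_WT_OTHER_VARIANT`, `MISSING_DOSAGE`) in a `FilterTrace` serialized
next to every report. The chain is idempotent, and phenotype and genotype
filters commute (both are per-record predicates), which the property suite
checks.

The wall-thickness labeling helper implements only the generic cutoffs
(≤ 5 mm normal, ≥ 6 mm hypertrophic, between equivocal), valid for
average-sized euthyroid, normotensive cats; body-weight-specific prediction
intervals must be applied upstream where they matter.

## Odds ratios

Genotype triples (Wt/Wt, Wt/Vt, Vt/Vt) collapse to 2×2 tables under three
codings:

* allelic — variant alleles vs wild alleles (two per animal);
* dominant — carriers vs non-carriers;
* recessive — homozygous variant vs the rest.

The estimator is the sample (unconditional maximum-likelihood) odds ratio
OR = ad/bc with the Wald interval exp(ln OR ± z·SE),
SE = √(1/a + 1/b + 1/c + 1/d). When any cell is zero the
Haldane–Anscombe correction adds 0.5 to **all four** cells (policy
`auto`; `always`/`never` are available). A table with an entire zero
margin under policy `never` raises rather than reporting 0 or ∞.

Two conventions are deliberate:

* **Critical value.** At the 95% level the conventional z = 1.96 is used
  rather than the exact quantile 1.959964. The difference is invisible at
  two printed decimals except for heavily corrected small tables, where
  1.96 is what standard epidemiological practice (and the published feline
  HCM association tables) produce. Other confidence levels use the exact
  normal quantile.
* **Significance** is interval-based: a coding is flagged significant iff
  the CI excludes 1. No p-values are computed and no multiple-testing
  correction is applied across the three codings — running all three is a
  deliberate sensitivity analysis when the inheritance mode is disputed,
  and penalizing it would trade false positives for missed true
  associations. A Bonferroni flag exists as a clearly-labelled extension
  and defaults off.

A homozygote-contrast estimate (Vt/Vt vs Wt/Wt, heterozygotes dropped) is
provided for comparability with earlier cardiomyopathy studies that
reported that contrast.

The case-control classification criterion (PS4) is fulfilled when any
coding yields a significant OR above `ps4_or_threshold` (default 5.0); the
witness is the first qualifying coding in the fixed reporting order
(allelic, recessive, dominant).

Report rendering rounds ORs and CI bounds to the configured decimals
(default 2), with bounds ≥ 500 rendered as integers; underlying values are
kept at full precision and JSON output is unrounded.

## Sample size and power

For an unmatched case-control design targeting an allelic odds ratio OR
with reference-group event probability p₀, the exposed-group probability is
p₁ = OR·p₀ / (1 + p₀(OR − 1)). Power refers to the two-sided
continuity-corrected chi-square test (Yates). Because the design sizes of
interest are small (totals in the tens), `achieved_power` computes the
rejection probability **exactly** by enumerating the two binomial count
distributions (vectorized; used up to a few thousand animals per design),
rather than relying on the Fleiss normal approximation, which misses the
exact rejection probability by up to ~0.04 at these sizes. The Fleiss
closed form with continuity correction serves as the search starting point
and as the large-sample fallback. `min_total_n` returns the smallest even
total (balanced arms) from which exact power stays at or above the target —
a sustained crossing, so isolated sawtooth spikes of the discrete power
curve do not shrink the answer. Exact power is conservative at very small
n (a 2×2 with one animal per arm can never reject), which is the correct
account of what the test can actually do.

At the higher reported feline HCM prevalence (15%) and the first-report
effect sizes of the catalogued variants (allelic ORs roughly 13–62), the
computed totals are 32, 20, and 16 — single-to-low-double digits, matching
the scale of the original design phase.

## Classification engine

The evidence vocabulary is the standard coded set (PVS1; PS1–PS4; PM1–PM6;
PP1–PP5; BA1; BS1–BS4; BP1–BP7), with default weights implied by the code
prefix (very strong / strong / moderate / supporting; BA1 stand-alone).
Weights are overridable per criterion instance (e.g. a case-count
criterion downgraded to supporting), but defaults follow the prefix.
The combining rules are the standard ones; `combine()` is verified against
an independent rule-by-rule oracle over all 2,160 bounded evidence
profiles.

Frequency criteria come in two mutually exclusive families:

* **Fixed cutoff** (`acmg_ba1_cutoff`, default 5%): frequency above the
  cutoff is stand-alone benign (BA1), below is moderate pathogenic support
  (PM2); exactly at the cutoff neither strict inequality holds and no
  criterion fires.
* **Tv-based** (starred): frequency at or below the per-variant maximum
  credible allele frequency is PM2*, above is BS1*, with the same weights
  as their unstarred counterparts. BA1* exists in the vocabulary for
  manual curation but is never auto-assigned: no principled trigger for a
  stand-alone benign call at the Tv threshold has been operationalized, so
  the engine defaults to the strong-benign reading.

Tv values are normally supplied per variant in the configuration (the
packaged catalogue carries 17/40/11/27/15/2% for the six variants). A
generic maximum-credible-frequency calculation is also provided: under
Hardy–Weinberg with disease prevalence *P*, maximum allelic contribution
*c* and penetrance *f*, q_max = √(P·c/f) for a recessive architecture and
q_max = P·c/(2f) for a dominant one (carriers ≈ 2q), clipped to 1.

Classification runs in three passes per variant: from the non-frequency
evidence alone (INITIAL), with the fixed-cutoff criterion added (ACMG_AF),
and with the Tv criterion added (TV_AF), so the marginal effect of each
frequency rule is visible. Two behaviors are deliberate:

* **BA1 is literal.** A stand-alone benign criterion classifies benign
  regardless of pathogenic evidence. This is mechanical application of the
  rule as written; the human-curation nuance (documented exceptions to
  BA1) is out of scope. It is exactly this literalness that the two-stage
  comparison is designed to expose: on the packaged catalogue the fixed
  cutoff flips four of six variants to benign against all other evidence,
  while the Tv stage changes nothing.
* **Conflicts yield VUS.** Any simultaneous firing of a pathogenic-side
  rule and a strong-benign rule returns unknown significance.

Known divergences from the published veterinary tables, followed
deliberately: the published summary lists one variant (MYH7 E1883K, base
evidence PS3 + PP3 + PP2) as "pathogenic" under PM2*, but one strong + one
moderate + two supporting satisfies only a likely-pathogenic rule, and the
engine says so; the same table's "(PP3 + PS3 + PP3)" is read as a
transcription slip for PP3 + PS3 + PP2, and its "with BA1" row label under
a PM2 criterion as a slip for "with PM2". One published count table also
prints a total (14,025) that disagrees with its own genotype counts
(14,027); the genotype counts are authoritative here. Two Devon Rex rows
print frequencies (4.69%, 32.81%) inconsistent with their own counts
(4.55%, 33.33%) and are therefore not asserted. The Sphynx ALMS1 allelic
CI upper bound prints as "2" where the computation gives 1.92.

## Synthetic cohorts

`generate_cohort` draws genotypes per variant under Hardy–Weinberg
proportions (independently across variants), assigns disease by genotype
through a target odds ratio (baseline odds o₀ = r/(1−r); exposed class
odds OR·o₀; ALLELIC applies the per-allele factor multiplicatively by
dosage; NULL means no effect), draws ages i.i.d. uniform over a configured
range, perturbs a configured fraction of labels to equivocal/restrictive,
and masks dosages at a configured missingness rate. A fixed seed gives
byte-identical output.

What it emulates: breed-stratified HWE genotype structure, genotype-
dependent risk under the three inheritance architectures, the age
structure the control filter acts on, co-segregating secondary variants,
and missingness. What it does not: linkage disequilibrium between
variants, admixture or pedigree/litter structure, age-dependent
penetrance, and genotyping error. Passing calibration tests therefore
demonstrates correctness of the statistical machinery under the stated
sampling model, not robustness to those real-data features.

Calibration results the test suite computes (seeded, deterministic): the
allelic significance flag fires at the nominal 5% rate under a null
variant (2,000 replicates, n = 300, within two Monte-Carlo standard
errors); recessive-coding estimates recover a simulated OR of 13 (median
within [10, 17] over 500 replicates at n = 5,000); allelic-coding
estimates recover a simulated per-allele OR of 5 to within 0.15 on the log
scale at baseline risk 2% (within the 0.5–3% population-prevalence range
reported for the disease) with ≥ 200 animals per arm. The allelic
generative model is an approximation at high baseline risk — with common
disease the allele-counting estimand is attenuated (e.g. ≈ 4.1 for a
target of 5 at baseline 15%) — which is why the recovery check is run at a
realistic population baseline.

## Problem sizes and determinism

All randomized tests are seeded (hypothesis profiles use fixed examples;
simulation tests use explicit integer seeds). The test suite's simulation
scale — 2,000 null replicates at n = 300 and 500 recovery replicates at
n = 5,000–6,000 — was chosen to keep Monte-Carlo error well below the
asserted tolerances; the acceptance script reports the same calibrations
at 1,000/300 replicates. Exact-power enumeration is used up to four
million table cells per design, beyond which the normal approximation is
indistinguishable at the asserted tolerances.

## Limitations

Evidence curation (functional studies, computational predictor consensus,
cross-species precedent) is input, not computation: the engine classifies
whatever the evidence sheet asserts. Logistic regression with covariates,
exact conditional inference, Hardy–Weinberg testing, and family-based
designs are out of scope. Duplicate animals pooled across count sources
cannot be detected from aggregate counts. The per-variant retained sample
sizes of the original cohort cannot be reproduced without the unpublished
per-animal records; the filter arithmetic is instead validated
exhaustively on synthetic cohorts.
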