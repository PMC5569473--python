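# Methods

## Coordinates and data model

All intervals are 0-based half-open internally; published tables print
1-based inclusive positions, and converters preserve the span
(`b − a + 1 = end − start`).  Call files list only non-reference segments
(CN ≠ 2), mirroring segment callers, so cohort denominators always come
from the sample sheet: any individual without a call or genotype entry is
reference (CN 2).  Deletion loci admit CN {0, 1, 2} and duplication loci
CN {2, 3, 4}; duplications are capped at CN 4 (two duplication alleles), a
biallelic-allele model under which the allelic dosage is 2 − CN for
deletions and min(CN − 2, 2) for duplications.  Strand is ignored; CNVs
are unstranded intervals.

## Association statistics

The 2×2 allele table (risk/non-risk × case/control) yields:

* **Odds ratio and Woolf CI.**  θ̂ = ad/bc; 95% CI
  exp(ln θ̂ ± z·√(1/a + 1/b + 1/c + 1/d)) with z = 1.959964.  A zero cell
  leaves the estimate undefined; the optional Haldane–Anscombe +0.5
  correction applies to the estimate and CI only, never to tests.
* **Pearson allelic χ².**  χ² = N(ad − bc)²/((a+b)(c+d)(a+c)(b+d)), 1 df.
  The default is uncorrected: on the bundled discovery rows it reproduces
  the printed p = 2.84 × 10⁻¹⁵ and 1.22 × 10⁻¹³, which the Yates variant
  does not.  The bundled *UXS1* unfiltered (printed p 0.44) and
  replication (printed p 0.94) rows are closer to the continuity-corrected
  variant (0.436, 0.907) than to the uncorrected one (0.415, 0.860); the
  variant that actually produced those two printed values is not
  identifiable from them, so both variants are exposed (`yates=` flag) and
  the discrepancy is documented here rather than resolved.
* **Fisher exact test.**  Two-sided by full enumeration of the
  hypergeometric support with fixed margins, summing all tables whose
  probability is at most that of the observed table (minimum-likelihood
  convention) with 1 × 10⁻⁷ relative slack for floating-point ties.  A
  zero margin admits a single table and gives p = 1.  The implementation
  is enumeration by construction; `scipy.stats.fisher_exact` serves only
  as an independent cross-check in the test suite.

## Filtering and locus genotyping

The inclusion policy keeps calls with marker count ≥ 5 and span ≥ 5000 bp;
both thresholds are inclusive and configurable, and disabling the policy
is exactly equivalent to unit thresholds (the *unfiltered* re-analysis
mode).  Call-to-locus assignment uses ≥ 50% reciprocal overlap — the
overlap must cover at least half of the locus *and* half of the call.
This rule (and its 50% fraction) is a design choice of this package; no
standard exists for matching fragmentary calls to a canonical locus, and
the fraction is a keyword argument.  Conflicting copy numbers from two
overlapping calls of one individual raise an ambiguity error rather than
being silently merged.

The batch screen is a plain Pearson χ² heterogeneity test of
carrier/non-carrier counts across batches with a configurable flag
threshold (default 0.05).  It deliberately replaces mixed-model batch
correction with a transparent screen: it detects batch-confounded loci but
does not correct them, and a single batch or a degenerate table yields
"not applicable" instead of a p-value.

## Concordance

The match score extends "same type and copy number" to the reference
state: (2, 2) scores 2, which is the only completion consistent with
counting confirmed wild-type individuals as concordant.  A locus is
*validated* when MLPA shows at least one non-reference copy number of the
locus's own type (threshold configurable); variability of the opposite
type does not validate.

The deletion-vs-duplication comparison applies a two-sided Mann-Whitney
rank-sum test to per-locus mean match scores (the default; a
pooled-by-individual mode weights loci by assay count).  Small samples
(≤ ~200 000 group assignments) use exact permutation enumeration, which
remains exact under the heavy ties that 0/1/2 scores guarantee; larger
samples use the tie-corrected normal approximation without continuity
correction.  The study's printed rank-sum p (3.01 × 10⁻³) and per-type
mean scores (1.32/0.24) are not reproduction targets because the
underlying per-locus score vectors were never published; the package's
checks of this component are property-based instead (ordering under
configured error intercepts, exact-enumeration oracles).

## Reliability curve

Each locus contributes its median called-segment size and median marker
count (average-of-middle-two on even counts — the convention is stated
because sources are typically silent).  The cumulative curve value of a
locus is the mean of the mean match scores of that locus **and** all loci
with an equal or larger key; the inclusive reading is adopted because the
index CNV is explicitly part of its own average, and key ties share one
curve value.  The curve at the smallest key is therefore the grand mean.
Spearman ρ (average ranks on ties) between key and curve summarises how
reliability grows with segment support; a constant vector leaves ρ
undefined ("not applicable") rather than 0.

## LD screening

r² between unphased dosage vectors is computed by EM: the marginal allele
frequencies are fixed by the observed allele counts, leaving the
AB-haplotype frequency as the single free parameter, updated over the
double-heterozygote phase ambiguity until the change is < 1 × 10⁻¹⁰ or
1000 iterations.  Missing genotypes are dropped pairwise before EM;
monomorphic SNPs make r² undefined.  An LD region is the half-open
bounding interval of all panel SNPs with r² strictly above the threshold
(default 0.1), the lead always included.  Overlap screening lists
(CNV locus, region) pairs sharing ≥ 1 base and flags CNVs with overall
allele frequency below 5% as rare.

## Synthetic cohorts

The generator emulates the call level of an array CNV study, not raw
intensities or segmentation:

* **Genotypes.**  Hardy-Weinberg proportions (q², 2q(1−q), (1−q)²) — the
  minimal neutral choice, made explicitly since no generating model is
  implied by count tables.  Case allele frequency derives from the control
  frequency and a configured allelic odds ratio by inverting the odds
  definition, so the configured θ is exactly the population OR.
* **Array miscalls.**  P(miscall) = logistic(α_type − β·ln(markers) +
  batch shift).  The logistic form is an assumption: real studies report
  outcome rates (deletions validating far more often than duplications;
  reliability rising with marker count), not a mechanism, and this is the
  simplest monotone model reproducing both.  Replacement is uniform over
  the admissible wrong states, which keeps the discordance-rate oracle
  analytic.  Defaults (α_del = −1.5, α_dup = 0.5, β = 1) place deletion
  reliability well above duplication reliability at realistic marker
  counts of 5–40.
* **Marker counts and spans.**  Per-call marker count is 2 + Poisson
  (optionally gamma-overdispersed); span = markers × spacing.  Setting the
  mean to 2 makes the count deterministic, which the tests use to pin the
  miscall probability.
* **MLPA.**  Truth with probability 1 − ε (default ε = 0, i.e. MLPA as
  ground truth; the pipeline default uses ε = 0.02).
* **Determinism.**  Every stage/locus pair draws from its own named
  RNG substream (master seed + CRC32 of the stream name), so identical
  configuration and seed give byte-identical outputs and adding a locus
  never perturbs existing draws.

What passing simulated tests do **not** show: the generator has no allelic
intensity noise, no segmentation fragmentation (one call per individual
per locus), no LD between CNVs and flanking SNPs, and uniform miscall
destinations; conclusions about real arrays rest on the bundled study
tables, not the simulator.

## Problem sizes and defaults in checks

The package's statistical checks use: 10 000–20 000 individuals for
rate-recovery assertions (3 binomial SEs), 100 seeded replicates of
5000 + 5000 individuals for Woolf-CI coverage (expected ≈ 95%, asserted
≥ 90%), 100 replicates of 20 loci × 200 individuals for the positive
reliability-correlation property, and exhaustive or brute-force oracles
for the discrete primitives (match-score truth table over CN 0–4,
hypergeometric enumeration for small-margin Fisher tables, a 1 × 10⁻⁵
grid-likelihood search for EM r²).  These sizes keep every check both
statistically decisive and fast.

## Known limitations

* No genotypic (2×3) or trend tests, no covariate adjustment, no
  genome-wide multiple-testing machinery beyond a Bonferroni helper.
* No CNV calling from intensities, no VCF/SVTYPE input, no call merging
  across adjacent segments.
* The batch screen detects but does not correct batch confounding.
* The recombination-map-based alternative definition of LD regions is out
  of scope; only the r² threshold definition is implemented.
* Rendered reports follow fixed precision rules (OR/CI 2 d.p.,
  frequencies 1 d.p., p to 2 significant figures, 1 d.p. in the rare-CNV
  Fisher table), chosen so golden-file comparisons are string-exact.
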