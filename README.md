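# cnvconcord

Case-control association and array-vs-MLPA concordance analysis for
SNP-array copy-number variant (CNV) calls.

## The problem

SNP-array CNV calling (Birdseye-style segmenters) is noisy: calls supported
by few array markers or spanning little sequence are unreliable, batches of
conjointly processed arrays shift apparent CNV frequencies, and — as
orthogonal re-measurement by MLPA (multiplex ligation-dependent probe
amplification) repeatedly shows — duplications are far harder to genotype
correctly than deletions.  A case-control association signal at a CNV can
therefore be a genotyping artefact rather than biology.

`cnvconcord` packages the downstream analysis such a study needs:

* **filtering** — keep calls with ≥ 5 array markers spanning ≥ 5000 bp
  (configurable, inclusive thresholds), with an *unfiltered* re-analysis
  mode that re-admits sub-threshold calls, and a Pearson χ² batch-frequency
  screen;
* **association** — per-locus allelic dosages (deletion: 2 − CN;
  duplication: min(CN − 2, 2)) summed into a 2×2 allele table
  (a, b; c, d) on which it computes the odds ratio θ̂ = ad/bc with the
  Woolf 95% CI exp(ln θ̂ ± 1.96·√(1/a + 1/b + 1/c + 1/d)), the Pearson
  allelic χ² (Yates optional), and a two-sided Fisher exact test by full
  hypergeometric enumeration (minimum-likelihood convention);
* **concordance** — the 0/1/2 match score between array and MLPA copy
  numbers (2 = same CN, 1 = same non-reference type only, 0 = otherwise),
  per-locus mean scores, discordance rates, MLPA validation calls, and a
  deletion-vs-duplication Mann-Whitney rank-sum comparison;
* **reliability** — per-CNV median segment size and marker count, the
  cumulative mean-of-mean-match-scores curve (each locus averaged with all
  loci of equal or larger key), and Spearman ρ between the key and the
  curve;
* **LD screening** — r² between unphased SNP dosages by EM over the
  double-heterozygote phase ambiguity, LD regions around lead SNPs
  (r² > 0.1), and CNV-interval overlap screening with rare-CNV flags;
* **simulation** — a synthetic cohort generator (Hardy-Weinberg genotypes,
  odds-ratio-parameterised case frequencies, a logistic marker-count- and
  type-dependent miscall process, batch shifts, near-truth MLPA) so the
  whole pipeline is testable end to end.

A reference dataset from a published CNV genome-wide association study of
psoriatic arthritis (478 patients / 3798 controls; frequent deletions near
*UXS1* and at the *TRB* locus; rare CNVs at psoriasis susceptibility loci)
is bundled as count tables and reanalysed at run time.

## Worked example

Recompute the bundled study's statistics from its raw counts:

```bash
$ cnvconcord run --fixture study --out out/
UXS1|discovery        OR 2.36 [1.90-2.94]   chi2 p 2.84e-15
UXS1|unfiltered discovery  OR 0.94 [0.82-1.09]  chi2 p 0.41
UXS1|replication      OR 1.02 [0.81-1.29]   chi2 p 0.86
TRB|discovery         OR 1.88 [1.59-2.23]   chi2 p 1.22e-13
TRB|replication       OR 0.94 [0.82-1.07]   chi2 p 0.34
CSMD1   Fisher p 1.0
IL12B   Fisher p 0.1
RYR2    Fisher p 0.7
```

The discovery rows show the strong array-based associations (OR 2.36 and
1.88); the unfiltered and replication rows show both signals vanishing once
sub-threshold calls are re-admitted or the CNV is re-genotyped by MLPA —
the study's central cautionary result.  The Fisher rows screen the three
MLPA-validated rare CNVs at susceptibility loci (none associated).

The same attenuation is visible in simulation: with the default error
model, a deletion generated at OR 2.36 is recovered from the corrupted
array calls at only

```bash
$ cnvconcord run --simulate --seed 7 --out sim/
$ python -c "import json; print(json.load(open('sim/report.json'))['loci']['del-frequent']['rendered'])"
1.46 [1.26-1.69]
```

because miscalls drag both group frequencies toward each other.

Library use mirrors the CLI:

```python
from cnvconcord import AlleleTable, odds_ratio_ci, fisher_exact

t = AlleleTable(861, 95, 6026, 1570)
odds_ratio_ci(t)        # (2.361, 1.897, 2.940)
fisher_exact(AlleleTable(2, 954, 12, 7584))   # 0.665
```

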