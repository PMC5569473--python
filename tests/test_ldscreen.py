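"""EM-based r-squared, LD-region construction and CNV-overlap screening."""

import numpy as np
import pytest

from cnvconcord.core import CnvLocus, Individual, SnpGenotypes
from cnvconcord.ldscreen import (
    haplotype_freqs_em,
    ld_region,
    overlap_screen,
    r2_unphased,
)


def _genotypes_from_haplotypes(h1, h2):
    """Unphased dosages from two phased haplotype matrices (n x 2 SNPs)."""
    g = h1 + h2
    return g[:, 0].astype(float), g[:, 1].astype(float)


def _grid_oracle_r2(ga, gb, step=1e-5):
    """Likelihood-maximisation oracle over the single free haplotype
    frequency (margins are fixed by the observed allele counts)."""
    ga, gb = np.asarray(ga, float), np.asarray(gb, float)
    n = len(ga)
    pa = ga.sum() / (2 * n)
    pb = gb.sum() / (2 * n)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    pab = np.arange(lo, hi + step, step)
    pAb = pa - pab
    paB = pb - pab
    pO = 1 - pa - pb + pab
    probs = {
        (2, 2): pab**2, (2, 1): 2 * pab * pAb, (2, 0): pAb**2,
        (1, 2): 2 * pab * paB, (1, 1): 2 * pab * pO + 2 * pAb * paB,
        (1, 0): 2 * pAb * pO,
        (0, 2): paB**2, (0, 1): 2 * paB * pO, (0, 0): pO**2,
    }
    ll = np.zeros_like(pab)
    for key, pr in probs.items():
        if counts[key] > 0:
            with np.errstate(divide="ignore"):
                ll += counts[key] * np.log(np.clip(pr, 1e-300, None))
    best = pab[np.argmax(ll)]
    d = best - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def test_r2_of_snp_with_itself_is_one(rng):
    g = rng.integers(0, 3, 50).astype(float)
    if len(set(g)) == 1:
        g[0] = (g[0] + 1) % 3
    assert r2_unphased(g, g) == pytest.approx(1.0, abs=1e-6)


def test_r2_of_independent_snps_is_near_zero(rng):
    n = 10_000
    ga = rng.binomial(2, 0.4, n).astype(float)
    gb = rng.binomial(2, 0.3, n).astype(float)
    assert r2_unphased(ga, gb) < 0.01


def test_r2_monomorphic_is_not_applicable():
    assert r2_unphased(np.zeros(10), np.ones(10)) is None


def test_r2_em_matches_grid_likelihood_oracle_on_random_panels():
    """EM r2 equals an independent grid-search likelihood maximisation
    within 1e-4 on random 20-individual genotype panels."""
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 10:
        ga = rng.binomial(2, rng.uniform(0.2, 0.8), 20).astype(float)
        gb = rng.binomial(2, rng.uniform(0.2, 0.8), 20).astype(float)
        r2 = r2_unphased(ga, gb)
        if r2 is None:
            continue
        assert r2 == pytest.approx(_grid_oracle_r2(ga, gb), abs=1e-4)
        checked += 1


def test_r2_symmetric_and_allele_label_invariant(rng):
    ga = rng.binomial(2, 0.4, 200).astype(float)
    gb = rng.binomial(2, 0.6, 200).astype(float)
    r2 = r2_unphased(ga, gb)
    assert r2 == pytest.approx(r2_unphased(gb, ga), abs=1e-9)
    assert r2 == pytest.approx(r2_unphased(2 - ga, gb), abs=1e-6)
    assert r2 == pytest.approx(r2_unphased(ga, 2 - gb), abs=1e-6)


def test_r2_unphased_recovers_phased_haplotype_r2(rng):
    """On genotypes built from known haplotypes, the EM estimate agrees with
    the direct haplotype-count r2 within 3 SEs."""
    n = 10_000
    # haplotype pool with strong LD: AB 0.45, Ab 0.05, aB 0.05, ab 0.45
    haps = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    probs = [0.45, 0.05, 0.05, 0.45]
    h1 = haps[rng.choice(4, n, p=probs)]
    h2 = haps[rng.choice(4, n, p=probs)]
    ga, gb = _genotypes_from_haplotypes(h1, h2)
    counts = np.zeros(4)
    for h in (h1, h2):
        for k in range(4):
            counts[k] += np.sum((h == haps[k]).all(axis=1))
    f = counts / counts.sum()
    pa, pb = f[0] + f[1], f[0] + f[2]
    d = f[0] - pa * pb
    direct = d * d / (pa * (1 - pa) * pb * (1 - pb))
    assert r2_unphased(ga, gb) == pytest.approx(direct, abs=0.02)


def test_missing_genotypes_dropped_pairwise(rng):
    ga = rng.binomial(2, 0.5, 100).astype(float)
    gb = ga.copy()
    ga_m = ga.copy()
    ga_m[:10] = np.nan
    assert r2_unphased(ga_m, gb) == pytest.approx(1.0, abs=1e-6)


def _panel_from_block(rng, n=300):
    """5 SNPs in perfect LD flanked by independent SNPs on each side."""
    block = rng.binomial(2, 0.5, n).astype(float)
    rows = [rng.binomial(2, 0.4, n).astype(float) for _ in range(2)]
    rows += [block] * 5
    rows += [rng.binomial(2, 0.4, n).astype(float) for _ in range(2)]
    return SnpGenotypes(
        snp_ids=[f"rs{i}" for i in range(9)],
        positions=np.arange(9) * 1000 + 100,
        individual_ids=[f"I{i}" for i in range(n)],
        dosages=np.vstack(rows),
    )


def test_ld_region_spans_exactly_the_perfect_ld_block(rng):
    panel = _panel_from_block(rng)
    region = ld_region("rs4", panel, threshold=0.1)
    assert set(region.members) == {"rs2", "rs3", "rs4", "rs5", "rs6"}
    assert (region.start, region.end) == (2100, 6101)
    assert all(r2 > 0.1 for r2 in region.members.values())


def test_ld_region_lead_only_when_no_neighbors(rng):
    n = 2000
    rows = [rng.binomial(2, 0.5, n).astype(float) for _ in range(3)]
    panel = SnpGenotypes(
        snp_ids=["a", "b", "c"], positions=[10, 20, 30],
        individual_ids=[f"I{i}" for i in range(n)], dosages=np.vstack(rows),
    )
    region = ld_region("b", panel, threshold=0.1)
    assert set(region.members) == {"b"}
    assert (region.start, region.end) == (20, 21)


def test_ld_region_threshold_is_strict(rng):
    panel = _panel_from_block(rng)
    # at threshold 1.0 only perfect proxies survive; empirical r2 of the
    # block with itself is exactly 1, but finite-sample copies may dip below
    region = ld_region("rs4", panel, threshold=1.0 - 1e-9)
    assert {"rs4"} <= set(region.members) <= {"rs2", "rs3", "rs4", "rs5", "rs6"}


def test_ld_region_monomorphic_lead_is_error():
    panel = SnpGenotypes(
        snp_ids=["a", "b"], positions=[1, 2],
        individual_ids=["I1", "I2", "I3"],
        dosages=np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 2.0]]),
    )
    with pytest.raises(ValueError, match="monomorphic"):
        ld_region("a", panel)


def _region(chrom, start, end):
    from cnvconcord.ldscreen import LdRegion

    return LdRegion("lead", chrom, start, end, {"lead": 1.0})


def test_overlap_screen_half_open_boundaries(small_cohort):
    adjacent = CnvLocus("A", "chr1", 0, 10, "deletion")
    touching = CnvLocus("B", "chr1", 9, 20, "deletion")
    hits = overlap_screen([adjacent, touching], [_region("chr1", 10, 20)], small_cohort)
    assert [h.locus_id for h in hits] == ["B"]


def test_overlap_screen_chromosome_mismatch(small_cohort):
    locus = CnvLocus("A", "chr2", 0, 100, "deletion")
    assert overlap_screen([locus], [_region("chr1", 0, 100)], small_cohort) == []


def test_overlap_screen_flags_rare_cnvs_and_type_counts():
    """12 susceptibility loci carrying only low-frequency CNVs with a 16:4
    duplication:deletion split are all reported and flagged rare."""
    cohort = [Individual(f"P{i}", "case") for i in range(100)]
    cohort += [Individual(f"C{i}", "control") for i in range(100)]
    loci = []
    for k in range(16):
        loci.append(CnvLocus(f"dup{k}", "chr1", k * 100, k * 100 + 50, "duplication",
                             genotypes={"P0": 3}))
    for k in range(4):
        loci.append(CnvLocus(f"del{k}", "chr1", 1600 + k * 100, 1650 + k * 100, "deletion",
                             genotypes={"C0": 1}))
    hits = overlap_screen(loci, [_region("chr1", 0, 3000)], cohort)
    assert len(hits) == 20
    assert sum(h.cnv_type == "duplication" for h in hits) == 16
    assert sum(h.cnv_type == "deletion" for h in hits) == 4
    assert all(h.rare for h in hits)
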