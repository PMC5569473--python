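"""LD-region construction around lead SNPs and CNV-overlap screening.

Squared correlation r² between two SNPs is estimated from unphased
diploid dosages by maximum likelihood: the marginal allele frequencies are
fixed by the observed allele counts, and the only free quantity is the
AB-haplotype frequency, resolved over the double-heterozygote phase
ambiguity by expectation-maximization.  An LD region around a lead SNP is
the bounding interval of all panel SNPs with r² to the lead above a
threshold (strict >, default 0.1), the lead always included.  CNV loci are
then screened for interval overlap with those regions; overlapping CNVs
with minor allele frequency below 5% are flagged as rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CnvLocus, Individual, SnpGenotypes
from .association import allele_dosage

__all__ = [
    "LdRegion",
    "OverlapHit",
    "r2_unphased",
    "haplotype_freqs_em",
    "ld_region",
    "overlap_screen",
]


def haplotype_freqs_em(
    ga: np.ndarray,
    gb: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[float, float, float] | None:
    """(p_AB, p_A, p_B) by EM over the double-heterozygote ambiguity.

    ``ga``/``gb`` are dosage vectors in {0,1,2} with NaN for missing;
    missing entries are dropped pairwise.  Returns None when either SNP is
    monomorphic in the complete-pairs subset (LD undefined).
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    ok = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[ok], gb[ok]
    if ga.size < 2:
        raise ValueError("need >= 2 individuals with both genotypes observed")
    n = ga.size
    p_a = ga.sum() / (2 * n)
    p_b = gb.sum() / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None

    # genotype-pair counts; only (1,1) is phase-ambiguous
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    n_dh = counts[1, 1]

    # unambiguous AB-haplotype contributions:
    #   dosage ga=i, gb=j outside (1,1) contributes min-known AB copies
    known_ab = (
        2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    )
    p_ab = p_a * p_b  # start at linkage equilibrium
    for _ in range(max_iter):
        # P(AB/ab | double het) vs P(Ab/aB | double het)
        p_aB = p_b - p_ab
        p_Ab = p_a - p_ab
        p_ab_hap = 1 - p_a - p_b + p_ab
        num = p_ab * p_ab_hap
        den = num + p_Ab * p_aB
        frac = num / den if den > 0 else 0.5
        new = (known_ab + frac * n_dh) / (2 * n)
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    return float(p_ab), float(p_a), float(p_b)


def r2_unphased(ga: np.ndarray, gb: np.ndarray) -> float | None:
    """Squared LD correlation from unphased dosages; None when monomorphic."""
    res = haplotype_freqs_em(ga, gb)
    if res is None:
        return None
    p_ab, p_a, p_b = res
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return float(min(1.0, d * d / denom))


@dataclass(frozen=True)
class LdRegion:
    lead_snp_id: str
    chrom: str
    start: int  # 0-based half-open bounding interval of member SNPs
    end: int
    members: dict[str, float]  # snp_id -> r^2 with the lead


def ld_region(
    lead_snp_id: str, panel: SnpGenotypes, threshold: float = 0.1
) -> LdRegion:
    """All panel SNPs with r² to the lead strictly above the threshold.

    The lead is always a member (r² = 1 with itself); the region interval
    is the half-open bounding box of member positions.
    """
    lead = panel.row(lead_snp_id)
    members: dict[str, float] = {}
    for sid in panel.snp_ids:
        if sid == lead_snp_id:
            members[sid] = 1.0
            continue
        r2 = r2_unphased(lead, panel.row(sid))
        if r2 is not None and r2 > threshold:
            members[sid] = r2
    if r2_unphased(lead, lead) is None:
        raise ValueError(f"lead SNP {lead_snp_id} is monomorphic")
    positions = [panel.position_of(s) for s in members]
    return LdRegion(
        lead_snp_id=lead_snp_id,
        chrom=panel.chrom,
        start=min(positions),
        end=max(positions) + 1,
        members=members,
    )


@dataclass(frozen=True)
class OverlapHit:
    locus_id: str
    lead_snp_id: str
    cnv_type: str
    case_allele_freq: float
    control_allele_freq: float
    rare: bool  # overall CNV allele frequency < rare_threshold


def overlap_screen(
    cnv_loci: Sequence[CnvLocus],
    regions: Sequence[LdRegion],
    cohort: Sequence[Individual],
    rare_threshold: float = 0.05,
) -> list[OverlapHit]:
    """List (locus, region) pairs whose half-open intervals share >= 1 base.

    Each hit carries the CNV allele frequency per cohort group and a rare
    flag (overall frequency below ``rare_threshold``).
    """
    cases = [p for p in cohort if p.is_case]
    controls = [p for p in cohort if not p.is_case]
    hits: list[OverlapHit] = []
    for locus in cnv_loci:
        for region in regions:
            if locus.chrom != region.chrom:
                continue
            if locus.start >= region.end or region.start >= locus.end:
                continue
            fa = (
                sum(allele_dosage(locus.cn_of(p.id), locus.cnv_type) for p in cases)
                / (2 * len(cases))
                if cases
                else float("nan")
            )
            fc = (
                sum(allele_dosage(locus.cn_of(p.id), locus.cnv_type) for p in controls)
                / (2 * len(controls))
                if controls
                else float("nan")
            )
            total = sum(
                allele_dosage(locus.cn_of(p.id), locus.cnv_type) for p in cohort
            ) / (2 * len(cohort))
            hits.append(
                OverlapHit(
                    locus_id=locus.locus_id,
                    lead_snp_id=region.lead_snp_id,
                    cnv_type=locus.cnv_type,
                    case_allele_freq=fa,
                    control_allele_freq=fc,
                    rare=total < rare_threshold,
                )
            )
    return hits
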