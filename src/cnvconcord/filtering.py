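"""CNV call inclusion filters, locus genotyping and the batch-frequency screen.

Array CNV call sets are conventionally screened by segment support before
association analysis; the default policy keeps calls covered by >= 5 array
markers spanning >= 5000 bp (both thresholds inclusive).  Disabling the
policy re-admits sub-threshold calls — the "unfiltered" re-analysis mode
used to test whether short fragmentary calls at a locus change its allele
frequencies.

Batches of conjointly processed arrays are a known confounder of CNV
frequencies; :func:`batch_heterogeneity` is a transparent Pearson
chi-square screen of carrier frequency across batches (a deliberately
simple alternative to mixed-model batch correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .core import CnvCall, CnvLocus, Individual

__all__ = [
    "FilterPolicy",
    "BatchScreenResult",
    "filter_calls",
    "genotype_locus",
    "batch_heterogeneity",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion thresholds for array CNV calls (inclusive >=)."""

    min_markers: int = 5
    min_span_bp: int = 5000
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.min_markers < 1 or self.min_span_bp < 1:
            raise ValueError("thresholds must be >= 1")

    def keeps(self, call: CnvCall) -> bool:
        if not self.enabled:
            return True
        return call.marker_count >= self.min_markers and call.span >= self.min_span_bp


def filter_calls(
    calls: Sequence[CnvCall], policy: FilterPolicy
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Partition calls into (kept, dropped) under the policy; exact partition."""
    kept = [c for c in calls if policy.keeps(c)]
    dropped = [c for c in calls if not policy.keeps(c)]
    return kept, dropped


def _reciprocal_overlap(call: CnvCall, locus: CnvLocus, fraction: float) -> bool:
    if call.chrom != locus.chrom:
        return False
    ov = min(call.end, locus.end) - max(call.start, locus.start)
    if ov <= 0:
        return False
    return ov >= fraction * locus.span and ov >= fraction * call.span


def genotype_locus(
    calls: Sequence[CnvCall],
    locus_id: str,
    chrom: str,
    start: int,
    end: int,
    cnv_type: str,
    policy: FilterPolicy = FilterPolicy(),
    overlap_fraction: float = 0.5,
) -> CnvLocus:
    """Assign per-individual CN at a canonical locus from filtered calls.

    A call contributes when it passes the policy and reciprocally overlaps
    the locus interval by at least ``overlap_fraction`` of both lengths.
    Individuals with no contributing call are reference (CN 2).  Two
    contributing calls of one individual with conflicting CN are an
    ambiguity error.
    """
    kept, _ = filter_calls(calls, policy)
    locus = CnvLocus(locus_id=locus_id, chrom=chrom, start=start, end=end, cnv_type=cnv_type)
    genos: dict[str, int] = {}
    for call in kept:
        if not _reciprocal_overlap(call, locus, overlap_fraction):
            continue
        prev = genos.get(call.individual_id)
        if prev is not None and prev != call.cn_state:
            raise ValueError(
                f"ambiguous genotype at {locus_id}: individual "
                f"{call.individual_id} has conflicting overlapping calls "
                f"(CN {prev} vs {call.cn_state})"
            )
        genos[call.individual_id] = call.cn_state
    locus.genotypes = genos
    for iid, cn in genos.items():
        locus._check_cn(iid, cn)
    return locus


@dataclass(frozen=True)
class BatchScreenResult:
    locus_id: str
    p_value: float | None  # None when the test is not applicable
    batch_carrier_freq: dict[str, float]
    flagged: bool


def batch_heterogeneity(
    locus: CnvLocus,
    cohort: Sequence[Individual],
    flag_threshold: float = 0.05,
) -> BatchScreenResult:
    """Pearson chi-square screen of carrier frequency across batches.

    Carriers are individuals with CN != 2 at the locus.  A single batch
    (or a degenerate table) yields no p-value; loci with p below
    ``flag_threshold`` are flagged as batch-confounded.
    """
    batches = sorted({p.batch for p in cohort})
    freqs: dict[str, float] = {}
    carriers = np.zeros(len(batches), dtype=int)
    totals = np.zeros(len(batches), dtype=int)
    for p in cohort:
        j = batches.index(p.batch)
        totals[j] += 1
        if locus.cn_of(p.id) != 2:
            carriers[j] += 1
    for j, b in enumerate(batches):
        freqs[b] = carriers[j] / totals[j] if totals[j] else float("nan")
    if len(batches) < 2:
        return BatchScreenResult(locus.locus_id, None, freqs, False)
    table = np.array([carriers, totals - carriers])
    # degenerate margins (all carriers or none) make the test undefined
    if table.sum(axis=1).min() == 0:
        return BatchScreenResult(locus.locus_id, None, freqs, False)
    _, p, _, _ = chi2_contingency(table, correction=False)
    return BatchScreenResult(locus.locus_id, float(p), freqs, bool(p < flag_threshold))
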