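"""Call-reliability versus CNV size and marker count.

For each CNV locus the median called segment size and median marker count
are computed over its per-individual array calls.  Loci are then ranked by
one of those keys, and a cumulative curve is built where each locus's value
is the mean of the mean match scores of that locus *and all loci with an
equal or larger key* — so the curve at the smallest key is the grand mean
and the curve is monotone in rank only if reliability genuinely rises with
the key.  Spearman's rank correlation between the key and the curve then
quantifies how strongly call reliability grows with segment support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .core import CnvCall

__all__ = [
    "ReliabilityPoint",
    "locus_call_medians",
    "cumulative_mean_curve",
    "spearman_rho",
    "reliability_table",
]


@dataclass(frozen=True)
class ReliabilityPoint:
    locus_id: str
    median_size_bp: float
    median_marker_count: float
    mean_score: float
    cumulative_mean: float


def locus_call_medians(calls: Sequence[CnvCall]) -> tuple[float, float]:
    """(median segment size in bp, median marker count) over a locus's calls.

    Medians use the average-of-middle-two convention for even counts.
    """
    if not calls:
        raise ValueError("no calls for locus")
    sizes = [c.span for c in calls]
    markers = [c.marker_count for c in calls]
    return float(np.median(sizes)), float(np.median(markers))


def cumulative_mean_curve(
    keys: Sequence[float], mean_scores: Sequence[float]
) -> np.ndarray:
    """c_i = mean of mean_scores over loci with key >= key_i (self-inclusive).

    Key ties share an identical curve value; the locus with the smallest
    key carries the grand mean.  Order of input does not matter.
    """
    keys = np.asarray(keys, dtype=float)
    m = np.asarray(mean_scores, dtype=float)
    if keys.size == 0:
        raise ValueError("need at least one point")
    if keys.shape != m.shape:
        raise ValueError("keys and mean_scores must align")
    return np.array([m[keys >= k].mean() for k in keys])


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation (average ranks on ties); None when either
    vector is constant (the coefficient is undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = spearmanr(x, y).statistic
    return float(rho)


def reliability_table(
    locus_ids: Sequence[str],
    calls_by_locus: dict[str, Sequence[CnvCall]],
    mean_scores: dict[str, float],
    key: str = "markers",
) -> tuple[list[ReliabilityPoint], float | None]:
    """Build the ranked reliability curve and its Spearman correlation.

    ``key`` selects the ranking axis: ``"size"`` (median bp) or
    ``"markers"`` (median marker count).  Returns points sorted ascending
    by key, plus rho between the key and the cumulative curve.
    """
    if key not in ("size", "markers"):
        raise ValueError("key must be 'size' or 'markers'")
    med_size: dict[str, float] = {}
    med_markers: dict[str, float] = {}
    for lid in locus_ids:
        med_size[lid], med_markers[lid] = locus_call_medians(calls_by_locus[lid])
    keyvals = med_size if key == "size" else med_markers
    ids = sorted(locus_ids, key=lambda l: keyvals[l])
    ks = [keyvals[l] for l in ids]
    ms = [mean_scores[l] for l in ids]
    curve = cumulative_mean_curve(ks, ms)
    points = [
        ReliabilityPoint(
            locus_id=l,
            median_size_bp=med_size[l],
            median_marker_count=med_markers[l],
            mean_score=mean_scores[l],
            cumulative_mean=float(c),
        )
        for l, c in zip(ids, curve)
    ]
    rho = spearman_rho(ks, curve) if len(ids) >= 3 else None
    return points, rho
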