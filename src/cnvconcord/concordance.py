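"""Array-vs-MLPA concordance: match scores, per-locus summaries, and the
deletion-vs-duplication validation comparison.

The per-individual match score compares the array-derived and MLPA-derived
integer copy numbers at one locus:

* 2 — identical copy number (including reference 2 vs 2);
* 1 — same non-reference type (both deletions, CN < 2, or both
  duplications, CN > 2) but different copy number;
* 0 — otherwise (any mismatch involving the reference state, or
  opposite types).

A locus is "validated" when at least one MLPA measurement shows a
non-reference copy number of the locus's type — i.e. the orthogonal assay
independently confirms that copy-number variability exists there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .core import DELETION, DUPLICATION, MlpaResult

__all__ = [
    "MatchRecord",
    "LocusConcordance",
    "TypeComparison",
    "match_score",
    "cn_type",
    "build_match_records",
    "locus_concordance",
    "mann_whitney",
    "type_validation_summary",
]


def cn_type(cn: int) -> str:
    """deletion (< 2), reference (= 2) or duplication (> 2)."""
    if cn < 2:
        return DELETION
    if cn > 2:
        return DUPLICATION
    return "reference"


def match_score(array_cn: int, mlpa_cn: int) -> int:
    """0/1/2 agreement between array and MLPA copy numbers (symmetric)."""
    if array_cn < 0 or mlpa_cn < 0:
        raise ValueError("copy numbers must be >= 0")
    if array_cn == mlpa_cn:
        return 2
    ta, tm = cn_type(array_cn), cn_type(mlpa_cn)
    if ta == tm and ta != "reference":
        return 1
    return 0


@dataclass(frozen=True)
class MatchRecord:
    """Paired array/MLPA copy numbers for one individual at one locus."""

    individual_id: str
    locus_id: str
    array_cn: int
    mlpa_cn: int

    @property
    def score(self) -> int:
        return match_score(self.array_cn, self.mlpa_cn)


@dataclass(frozen=True)
class LocusConcordance:
    locus_id: str
    cnv_type: str
    mean_score: float
    n_assayed: int
    discordance_rate: float  # fraction with score < 2
    validated: bool


def build_match_records(
    array_genotypes: dict[str, int], mlpa: Iterable[MlpaResult], locus_id: str
) -> list[MatchRecord]:
    """Pair MLPA measurements of one locus with array genotypes.

    Individuals missing from the array genotype map are reference (CN 2).
    """
    return [
        MatchRecord(r.individual_id, locus_id, array_genotypes.get(r.individual_id, 2), r.cn)
        for r in mlpa
        if r.locus_id == locus_id
    ]


def locus_concordance(
    records: Sequence[MatchRecord], cnv_type: str, min_validated: int = 1
) -> LocusConcordance:
    """Per-locus concordance summary over all assayed individuals."""
    if not records:
        raise ValueError("no match records for locus")
    locus_id = records[0].locus_id
    scores = [r.score for r in records]
    n_confirmed = sum(
        1 for r in records if r.mlpa_cn != 2 and cn_type(r.mlpa_cn) == cnv_type
    )
    return LocusConcordance(
        locus_id=locus_id,
        cnv_type=cnv_type,
        mean_score=sum(scores) / len(scores),
        n_assayed=len(records),
        discordance_rate=sum(s < 2 for s in scores) / len(scores),
        validated=n_confirmed >= min_validated,
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y via midranks (handles ties)."""
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], max_exact_tables: int = 200_000
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns (U, p).

    Small samples (C(n1+n2, n1) <= ``max_exact_tables``) use an exact
    permutation enumeration of group assignments, which remains exact
    under ties; larger samples use the tie-corrected normal approximation
    (no continuity correction).  When every pooled value is identical the
    statistic carries no information and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    if comb(n1 + n2, n1) <= max_exact_tables:
        # pooled midranks are invariant under group assignment, so U of any
        # arrangement is a rank-subset sum
        ranks = rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for pick in combinations(range(n1 + n2), n1):
            u = sum(ranks[i] for i in pick) - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(var)
    return u_obs, float(2 * norm.sf(abs(z)))


@dataclass(frozen=True)
class TypeComparison:
    """Deletion-vs-duplication validation table and rank-sum test."""

    n_del: int
    n_dup: int
    validated_del: int
    validated_dup: int
    mean_of_means_del: float | None
    mean_of_means_dup: float | None
    u_statistic: float | None
    p_value: float | None  # None when one type is absent

    @property
    def validation_rate_del(self) -> float | None:
        return self.validated_del / self.n_del if self.n_del else None

    @property
    def validation_rate_dup(self) -> float | None:
        return self.validated_dup / self.n_dup if self.n_dup else None


def type_validation_summary(
    loci: Sequence[LocusConcordance], pooled_scores: bool = False
) -> TypeComparison:
    """Compare MLPA validation between deletion and duplication loci.

    The rank-sum test compares per-locus mean match scores by default; with
    ``pooled_scores`` it would require raw records and is therefore applied
    to the per-locus means repeated by ``n_assayed`` (a pooled-individual
    approximation).
    """
    dels = [l for l in loci if l.cnv_type == DELETION]
    dups = [l for l in loci if l.cnv_type == DUPLICATION]
    mm_del = float(np.mean([l.mean_score for l in dels])) if dels else None
    mm_dup = float(np.mean([l.mean_score for l in dups])) if dups else None
    u = p = None
    if dels and dups:
        if pooled_scores:
            xs = np.repeat([l.mean_score for l in dels], [l.n_assayed for l in dels])
            ys = np.repeat([l.mean_score for l in dups], [l.n_assayed for l in dups])
        else:
            xs = [l.mean_score for l in dels]
            ys = [l.mean_score for l in dups]
        u, p = mann_whitney(xs, ys)
    return TypeComparison(
        n_del=len(dels),
        n_dup=len(dups),
        validated_del=sum(l.validated for l in dels),
        validated_dup=sum(l.validated for l in dups),
        mean_of_means_del=mm_del,
        mean_of_means_dup=mm_dup,
        u_statistic=u,
        p_value=p,
    )
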