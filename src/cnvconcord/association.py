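"""Allelic case-control association statistics for CNV loci.

A diploid individual carries 0-2 copies of a CNV allele: for a deletion
locus the allelic dosage is ``2 - CN``; for a duplication locus it is
``CN - 2`` capped at 2 (a biallelic duplication-allele model, CN 4 = two
duplication alleles).  Summing dosages over cases and controls yields a
2x2 allele table

    a = risk alleles in cases      b = non-risk alleles in cases
    c = risk alleles in controls   d = non-risk alleles in controls

on which three statistics are computed:

* allelic odds ratio ``(a*d)/(b*c)`` with the Woolf (log-scale normal)
  95% confidence interval ``exp(ln OR +/- z*sqrt(1/a+1/b+1/c+1/d))``;
* Pearson chi-square test on 1 df (Yates continuity correction optional,
  off by default);
* two-sided Fisher exact test, computed by full enumeration of the
  hypergeometric support using the minimum-likelihood convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import hypergeom

from .core import DELETION, DUPLICATION, CnvLocus, Individual

__all__ = [
    "AlleleTable",
    "AssociationResult",
    "allele_dosage",
    "build_allele_table",
    "odds_ratio_ci",
    "chi2_allelic",
    "fisher_exact",
    "associate",
    "bonferroni",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AlleleTable:
    """2x2 case/control x risk/non-risk allele counts."""

    a: int  # risk alleles, cases
    b: int  # non-risk alleles, cases
    c: int  # risk alleles, controls
    d: int  # non-risk alleles, controls

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def case_freq(self) -> float:
        """Risk-allele frequency in cases."""
        return self.a / (self.a + self.b)

    @property
    def control_freq(self) -> float:
        return self.c / (self.c + self.d)

    def swapped_rows(self) -> "AlleleTable":
        return AlleleTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    locus_id: str
    table: AlleleTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2_p: float
    fisher_p: float


def allele_dosage(cn: int, cnv_type: str) -> int:
    """Number of CNV alleles (0-2) implied by an integer copy number.

    Deletion loci: dosage ``2 - cn`` (CN 0 = homozygous deletion = 2
    alleles).  Duplication loci: ``cn - 2`` capped at 2; CN > 4 is clamped
    with a warning.
    """
    if cn < 0:
        raise ValueError(f"negative copy number {cn}")
    if cnv_type == DELETION:
        if cn > 2:
            raise ValueError(f"CN {cn} impossible at a deletion locus")
        return 2 - cn
    if cnv_type == DUPLICATION:
        if cn < 2:
            raise ValueError(f"CN {cn} impossible at a duplication locus")
        if cn > 4:
            warnings.warn(f"CN {cn} clamped to dosage 2 (biallelic duplication model)")
        return min(cn - 2, 2)
    raise ValueError(f"unknown cnv_type {cnv_type!r}")


def build_allele_table(locus: CnvLocus, cohort: list[Individual]) -> AlleleTable:
    """Sum allelic dosages over cases and controls.

    Every cohort member contributes two alleles; individuals without a
    genotype entry are reference (CN 2, dosage 0).
    """
    cases = [p for p in cohort if p.is_case]
    controls = [p for p in cohort if not p.is_case]
    if not cases or not controls:
        raise ValueError("cohort must contain at least one case and one control")
    a = sum(allele_dosage(locus.cn_of(p.id), locus.cnv_type) for p in cases)
    c = sum(allele_dosage(locus.cn_of(p.id), locus.cnv_type) for p in controls)
    return AlleleTable(a, 2 * len(cases) - a, c, 2 * len(controls) - c)


def odds_ratio_ci(
    t: AlleleTable, z: float = Z_95, zero_cell_correction: bool = False
) -> tuple[float, float, float]:
    """Allelic odds ratio with the Woolf confidence interval.

    With ``zero_cell_correction`` the Haldane-Anscombe +0.5 is added to
    every cell (for the estimate and CI only — never for tests); without
    it a zero cell raises, as the estimate is undefined.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if not zero_cell_correction:
            raise ZeroDivisionError(
                "odds ratio undefined with a zero cell (enable zero_cell_correction)"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def chi2_allelic(t: AlleleTable, yates: bool = False) -> float:
    """Pearson chi-square p-value (1 df) on the allele table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the Yates variant
    subtracts N/2 from |ad - bc| (floored at 0) before squaring.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined with a zero margin")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2, 0.0)
    stat = n * num * num / margins
    return float(_chi2_dist.sf(stat, 1))


def fisher_exact(t: AlleleTable, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by enumeration of the hypergeometric support.

    With margins fixed, the first cell k ranges over
    ``max(0, r1 - c2) .. min(r1, c1)`` where r1 = a+b, c1 = a+c, c2 = b+d;
    the two-sided p sums the probabilities of all tables at most as likely
    as the observed one (minimum-likelihood convention), with relative
    slack ``rel_tol`` to absorb floating-point ties.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # a zero margin: only one table possible
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + rel_tol)].sum()))


def associate(
    locus: CnvLocus,
    cohort: list[Individual],
    yates: bool = False,
    zero_cell_correction: bool = True,
) -> AssociationResult:
    """All allelic association statistics for one locus in one call."""
    t = build_allele_table(locus, cohort)
    or_, lo, hi = odds_ratio_ci(t, zero_cell_correction=zero_cell_correction)
    return AssociationResult(
        locus_id=locus.locus_id,
        table=t,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        chi2_p=chi2_allelic(t, yates=yates),
        fisher_p=fisher_exact(t),
    )


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
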