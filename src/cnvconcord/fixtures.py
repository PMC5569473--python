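"""Bundled reference dataset: published count tables from a genome-wide
CNV association study of psoriatic arthritis (478 patients, 3798 controls).

The study reported two frequent CNVs — a deletion ~69 kb upstream of UXS1
and a deletion at the TRB T-cell-receptor locus — with allelic association
statistics in discovery, unfiltered-discovery and replication cohorts, plus
low-frequency CNVs at psoriasis susceptibility loci with MLPA validation
outcomes, and a 28-locus array-vs-MLPA validation ledger.  Every entry
carries a ``source`` label naming the table row it transcribes, so report
output can be traced back to the original counts.

These fixtures are inputs (printed contingency tables), not expected
outputs: all statistics on them are recomputed by the package at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import AlleleTable
from .core import DELETION, DUPLICATION, interval_from_one_based

__all__ = [
    "AssociationRow",
    "SusceptibilityRow",
    "LedgerEntry",
    "UXS1_ROWS",
    "TRB_ROWS",
    "SUSCEPTIBILITY_ROWS",
    "VALIDATION_LEDGER",
    "UXS1_INTERVAL",
    "UXS1_DISCORDANCE",
    "TRB_DISCORDANCE",
    "TRB_FULL_COHORT_DISCORDANCE",
]


@dataclass(frozen=True)
class AssociationRow:
    """One case/control allele-count row of a frequent-CNV association table."""

    locus_id: str
    cohort: str  # discovery | unfiltered discovery | replication
    table: AlleleTable
    source: str


@dataclass(frozen=True)
class SusceptibilityRow:
    """One low-frequency CNV at a psoriasis susceptibility locus.

    Allele counts are out of 956 case alleles (478 patients) and 7596
    control alleles (3798 controls); ``n_assayed`` is the number of
    patients re-measured by MLPA.  The Fisher test applies only to
    MLPA-validated CNVs.
    """

    gene: str
    cnv_type: str
    case_alleles: int
    control_alleles: int
    validated: bool
    n_assayed: int
    source: str

    def allele_table(self, n_cases: int = 478, n_controls: int = 3798) -> AlleleTable:
        return AlleleTable(
            self.case_alleles,
            2 * n_cases - self.case_alleles,
            self.control_alleles,
            2 * n_controls - self.control_alleles,
        )


@dataclass(frozen=True)
class LedgerEntry:
    """One CNV locus of the 28-locus MLPA validation ledger."""

    locus_id: str
    cnv_type: str
    frequent: bool  # frequent (GWAS) CNV vs low-frequency susceptibility-locus CNV
    validated: bool
    source: str


# frequent deletion upstream of UXS1, printed 1-based inclusive as
# chr2: 106,246,527-106,251,789 (span 5263 bp)
UXS1_INTERVAL = ("chr2", *interval_from_one_based(106_246_527, 106_251_789))

UXS1_ROWS: tuple[AssociationRow, ...] = (
    AssociationRow(
        "UXS1", "discovery", AlleleTable(861, 95, 6026, 1570),
        "UXS1 deletion, discovery cohort (478 cases / 3798 controls)",
    ),
    AssociationRow(
        "UXS1", "unfiltered discovery", AlleleTable(635, 321, 5145, 2451),
        "UXS1 deletion, discovery re-analysed without the 5-marker/5-kb filter",
    ),
    AssociationRow(
        "UXS1", "replication", AlleleTable(331, 167, 594, 306),
        "UXS1 deletion, MLPA-based replication (251 cases / 451 controls)",
    ),
)

TRB_ROWS: tuple[AssociationRow, ...] = (
    AssociationRow(
        "TRB", "discovery", AlleleTable(776, 180, 5288, 2308),
        "TRB deletion, discovery cohort (478 cases / 3798 controls)",
    ),
    AssociationRow(
        "TRB", "replication", AlleleTable(801, 765, 947, 847),
        "TRB deletion, extended cases / independent controls (782 / 897), MLPA-based",
    ),
)

ALL_ASSOCIATION_ROWS: tuple[AssociationRow, ...] = UXS1_ROWS + TRB_ROWS


def _sus(gene, cnv_type, ca, ctrl, validated, n_assayed):
    state = "validated" if validated else "not validated"
    return SusceptibilityRow(
        gene, cnv_type, ca, ctrl, validated, n_assayed,
        f"{gene} {cnv_type}, susceptibility-locus table ({state}, {n_assayed} assayed)",
    )


SUSCEPTIBILITY_ROWS: tuple[SusceptibilityRow, ...] = (
    _sus("CSMD1", DELETION, 1, 7, True, 7),
    _sus("IL12B", DUPLICATION, 2, 3, True, 14),
    _sus("RYR2", DELETION, 2, 12, True, 7),
    _sus("ERAP1", DELETION, 2, 1, False, 7),
    _sus("ERAP1-dup", DUPLICATION, 1, 4, False, 7),
    _sus("FBXL19", DELETION, 1, 0, False, 14),
    _sus("FBXL19-dup", DUPLICATION, 2, 22, False, 14),
    _sus("GJB2", DUPLICATION, 1, 1, False, 14),
    _sus("IFIH1", DUPLICATION, 3, 6, False, 14),
    _sus("IL23A", DUPLICATION, 4, 8, False, 7),
    _sus("NFKBIA", DUPLICATION, 2, 6, False, 14),
    _sus("RNF114", DUPLICATION, 2, 7, False, 12),
    _sus("TNIP1", DUPLICATION, 1, 0, False, 7),
    _sus("TRAF3IP2", DUPLICATION, 3, 7, False, 12),
)


def _ledger() -> tuple[LedgerEntry, ...]:
    """28 MLPA-assayed CNV loci: 11 deletions (8 validated) and 17
    duplications (2 validated).

    The 8 frequent CNVs split into 7 deletions and 1 duplication — forced
    arithmetically by the totals, since the 20 low-frequency CNVs comprise
    4 deletions and 16 duplications.  Per-type validated counts among the
    low-frequency set are 2 deletions (CSMD1, RYR2) and 2 duplications
    (both at IL12B), leaving 6 of 7 frequent deletions validated and the
    single frequent duplication not validated.
    """
    entries: list[LedgerEntry] = []
    # frequent CNVs (genome-wide set)
    for i in range(7):
        entries.append(
            LedgerEntry(
                f"frequent-del-{i + 1}", DELETION, True, i < 6,
                "frequent GWAS deletion, validation ledger",
            )
        )
    entries.append(
        LedgerEntry(
            "frequent-dup-1", DUPLICATION, True, False,
            "frequent GWAS duplication, validation ledger (none validated)",
        )
    )
    # low-frequency CNVs at susceptibility loci: 4 del + 16 dup
    low_del = [("CSMD1", True), ("RYR2", True), ("ERAP1", False), ("FBXL19", False)]
    for name, ok in low_del:
        entries.append(
            LedgerEntry(name, DELETION, False, ok, f"{name} low-frequency deletion")
        )
    low_dup_validated = ["IL12B", "IL12B-2"]
    low_dup_not = [
        "ERAP1-dup", "FBXL19-dup", "GJB2", "IFIH1", "IL23A", "NFKBIA",
        "RNF114", "TNIP1", "TRAF3IP2",
    ] + [f"sup-dup-{i + 1}" for i in range(5)]
    for name in low_dup_validated:
        entries.append(
            LedgerEntry(name, DUPLICATION, False, True, f"{name} low-frequency duplication")
        )
    for name in low_dup_not:
        entries.append(
            LedgerEntry(name, DUPLICATION, False, False, f"{name} low-frequency duplication")
        )
    return tuple(entries)


VALIDATION_LEDGER: tuple[LedgerEntry, ...] = _ledger()

# array-vs-MLPA discordant / assayed individuals at the two frequent loci
UXS1_DISCORDANCE = (50, 135)
TRB_DISCORDANCE = (48, 135)
TRB_FULL_COHORT_DISCORDANCE = (157, 446)
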