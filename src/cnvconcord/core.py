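"""Domain types and tabular readers/writers for CNV call sets.

All genomic intervals are stored 0-based half-open internally.  Published
copy-number tables and genome-browser coordinates are customarily printed
1-based inclusive; :func:`interval_from_one_based` / :func:`interval_to_one_based`
convert between the two conventions without changing the span.

File formats are headered TSV throughout:

* CNV calls: ``individual_id  chrom  start  end  cn_state  marker_count``
  (BED-derived dialect, 0-based half-open; one row per called non-reference
  segment per individual).
* Sample sheet: ``id  status  batch`` with status ``case``/``control``.
* MLPA table: ``individual_id  locus_id  cn``.
* SNP genotype matrix: SNPs as rows (``snp_id  position`` then one column per
  individual), minor-allele dosage 0/1/2, ``.`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "CnvCall",
    "CnvLocus",
    "MlpaResult",
    "SnpGenotypes",
    "FormatError",
    "ValidationError",
    "interval_from_one_based",
    "interval_to_one_based",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_mlpa_table",
    "write_mlpa_table",
    "read_snp_matrix",
    "write_snp_matrix",
]

DELETION = "deletion"
DUPLICATION = "duplication"


class FormatError(ValueError):
    """A file does not conform to the documented dialect (missing columns,
    unparseable fields, unknown tokens)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (bad coordinates,
    duplicate keys, impossible copy-number states)."""


def interval_from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open.

    ``(a, b)`` printed as e.g. ``chr2: 106,246,527-106,251,789`` maps to
    ``(a - 1, b)``; the span ``b - a + 1`` is preserved as ``end - start``.
    """
    if end < start:
        raise ValidationError(f"inclusive interval has end < start: ({start}, {end})")
    return start - 1, end


def interval_to_one_based(start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`interval_from_one_based`."""
    if end <= start:
        raise ValidationError(f"half-open interval has end <= start: ({start}, {end})")
    return start + 1, end


@dataclass(frozen=True)
class Individual:
    """One cohort member: opaque id, case/control status, processing batch."""

    id: str
    status: str  # "case" | "control"
    batch: str = "b0"

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"status must be case/control, got {self.status!r}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(frozen=True)
class CnvCall:
    """One called non-reference copy-number segment for one individual.

    ``cn_state`` is the integer copy number of the segment; the reference
    state 2 is never emitted by segment callers (only deviations are
    reported), so ``cn_state == 2`` is invalid here.
    """

    individual_id: str
    chrom: str
    start: int
    end: int
    cn_state: int
    marker_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"call for {self.individual_id}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.cn_state < 0:
            raise ValidationError(f"negative cn_state {self.cn_state}")
        if self.cn_state == 2:
            raise ValidationError(
                f"call for {self.individual_id}: cn_state 2 is the reference "
                "state and is never emitted as a segment"
            )
        if self.marker_count < 1:
            raise ValidationError(f"marker_count must be >= 1, got {self.marker_count}")

    @property
    def span(self) -> int:
        """Segment length in bp (end - start, half-open)."""
        return self.end - self.start


@dataclass
class CnvLocus:
    """A CNV region under analysis with per-individual integer CN genotypes.

    Individuals absent from ``genotypes`` are reference (CN 2) by convention:
    call files list only non-reference segments, so cohort denominators must
    come from the sample sheet, never from the call file.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str  # "deletion" | "duplication"
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cnv_type not in (DELETION, DUPLICATION):
            raise ValidationError(f"cnv_type must be deletion/duplication, got {self.cnv_type!r}")
        if self.end <= self.start:
            raise ValidationError(f"locus {self.locus_id}: end must exceed start")
        for iid, cn in self.genotypes.items():
            self._check_cn(iid, cn)

    def _check_cn(self, iid: str, cn: int) -> None:
        if not 0 <= cn <= 4:
            raise ValidationError(f"locus {self.locus_id}, {iid}: CN {cn} outside 0..4")
        if self.cnv_type == DELETION and cn > 2:
            raise ValidationError(
                f"locus {self.locus_id} is a deletion locus but {iid} has CN {cn} > 2"
            )
        if self.cnv_type == DUPLICATION and cn < 2:
            raise ValidationError(
                f"locus {self.locus_id} is a duplication locus but {iid} has CN {cn} < 2"
            )

    def cn_of(self, individual_id: str) -> int:
        """CN genotype of an individual; 2 (reference) when absent."""
        return self.genotypes.get(individual_id, 2)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MlpaResult:
    """MLPA-measured integer copy number for one individual at one locus."""

    individual_id: str
    locus_id: str
    cn: int

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValidationError(
                f"MLPA CN must be >= 0 ({self.individual_id} at {self.locus_id}: {self.cn})"
            )


@dataclass
class SnpGenotypes:
    """A panel of SNPs with per-individual minor-allele dosages.

    ``dosages`` is a (n_snps, n_individuals) float array with values in
    {0, 1, 2} and NaN for missing; rows are sorted by position.
    """

    snp_ids: list[str]
    positions: np.ndarray  # int, strictly increasing
    individual_ids: list[str]
    dosages: np.ndarray  # float, shape (n_snps, n_individuals), NaN = missing
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snp_ids), len(self.individual_ids)):
            raise ValidationError("dosage matrix shape does not match ids")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("SNP positions must be strictly increasing")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValidationError("dosages must lie in [0, 2] or be missing")

    def row(self, snp_id: str) -> np.ndarray:
        try:
            i = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None
        return self.dosages[i]

    def position_of(self, snp_id: str) -> int:
        return int(self.positions[self.snp_ids.index(snp_id)])


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (header line is mandatory)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read a CNV call file (headered 6-column TSV, 0-based half-open).

    Any malformed row fails the whole file with its line number; partial
    reads are never returned.
    """
    cols = ["individual_id", "chrom", "start", "end", "cn_state", "marker_count"]
    df = _read_tsv(path, cols)
    calls: list[CnvCall] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            calls.append(
                CnvCall(
                    individual_id=str(row["individual_id"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cn_state=int(row["cn_state"]),
                    marker_count=int(row["marker_count"]),
                )
            )
        except (TypeError, ValueError) as exc:
            kind = ValidationError if isinstance(exc, ValidationError) else FormatError
            raise kind(f"{path}, line {line}: {exc}") from None
    return calls


def write_cnv_calls(path: str | Path, calls: Iterable[CnvCall]) -> None:
    rows = [
        (c.individual_id, c.chrom, c.start, c.end, c.cn_state, c.marker_count)
        for c in calls
    ]
    df = pd.DataFrame(
        rows, columns=["individual_id", "chrom", "start", "end", "cn_state", "marker_count"]
    )
    with open(path, "w") as fh:
        fh.write("# CNV calls, coordinates 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False)


_STATUS_ALIASES = {
    "case": "case",
    "patient": "case",
    "affected": "case",
    "1": "case",
    "control": "control",
    "ctrl": "control",
    "unaffected": "control",
    "0": "control",
}


def read_sample_sheet(path: str | Path) -> list[Individual]:
    """Read the cohort sample sheet; statuses are normalized to case/control."""
    df = _read_tsv(path, ["id", "status", "batch"])
    seen: set[str] = set()
    people: list[Individual] = []
    for idx, row in df.iterrows():
        line = idx + 2
        iid = str(row["id"])
        token = str(row["status"]).strip().lower()
        if token not in _STATUS_ALIASES:
            raise FormatError(f"{path}, line {line}: unknown status token {token!r}")
        if iid in seen:
            raise ValidationError(f"{path}, line {line}: duplicate individual id {iid!r}")
        seen.add(iid)
        people.append(Individual(id=iid, status=_STATUS_ALIASES[token], batch=str(row["batch"])))
    return people


def write_sample_sheet(path: str | Path, cohort: Iterable[Individual]) -> None:
    df = pd.DataFrame(
        [(p.id, p.status, p.batch) for p in cohort], columns=["id", "status", "batch"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_mlpa_table(path: str | Path) -> list[MlpaResult]:
    """Read MLPA copy-number measurements; one record per (individual, locus)."""
    df = _read_tsv(path, ["individual_id", "locus_id", "cn"])
    seen: set[tuple[str, str]] = set()
    out: list[MlpaResult] = []
    for idx, row in df.iterrows():
        line = idx + 2
        key = (str(row["individual_id"]), str(row["locus_id"]))
        if key in seen:
            raise ValidationError(f"{path}, line {line}: duplicate (individual, locus) pair {key}")
        seen.add(key)
        try:
            out.append(MlpaResult(key[0], key[1], int(row["cn"])))
        except ValueError as exc:
            kind = ValidationError if isinstance(exc, ValidationError) else FormatError
            raise kind(f"{path}, line {line}: {exc}") from None
    return out


def write_mlpa_table(path: str | Path, results: Iterable[MlpaResult]) -> None:
    df = pd.DataFrame(
        [(r.individual_id, r.locus_id, r.cn) for r in results],
        columns=["individual_id", "locus_id", "cn"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_snp_matrix(path: str | Path, chrom: str = "chr1") -> SnpGenotypes:
    """Read a SNP dosage matrix (SNPs as rows, individuals as columns,
    ``.`` for missing)."""
    df = _read_tsv(path, ["snp_id", "position"])
    ind_cols = [c for c in df.columns if c not in ("snp_id", "position")]
    if not ind_cols:
        raise FormatError(f"{path}: no individual columns")
    dos = df[ind_cols].replace(".", np.nan).astype(float).to_numpy()
    return SnpGenotypes(
        snp_ids=[str(s) for s in df["snp_id"]],
        positions=df["position"].astype(int).to_numpy(),
        individual_ids=ind_cols,
        dosages=dos,
        chrom=chrom,
    )


def write_snp_matrix(path: str | Path, panel: SnpGenotypes) -> None:
    df = pd.DataFrame(panel.dosages, columns=panel.individual_ids)
    df = df.map(lambda v: "." if np.isnan(v) else str(int(v)))
    df.insert(0, "position", panel.positions)
    df.insert(0, "snp_id", panel.snp_ids)
    df.to_csv(path, sep="\t", index=False)


def cohort_split(cohort: Sequence[Individual]) -> tuple[list[Individual], list[Individual]]:
    """(cases, controls) partition of a cohort."""
    return [p for p in cohort if p.is_case], [p for p in cohort if not p.is_case]
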