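"""Synthetic case-control cohorts with array-style CNV calls and MLPA truth.

The generator produces, for each configured CNV locus:

* true diploid copy-number genotypes under Hardy-Weinberg proportions,
  with the case allele frequency derived from a control frequency and an
  allelic odds ratio;
* array-style segment calls obtained by corrupting the truth through a
  miscall process whose probability is logistic in the CNV type, the
  log marker count and an additive per-batch shift:

      P(miscall) = expit(alpha_type - beta * ln(markers) + batch_shift)

  A miscalled individual's CN is replaced by a uniformly chosen different
  admissible state (deletion loci: {0, 1, 2}; duplication loci: {2, 3, 4}).
  Only individuals whose (possibly corrupted) CN differs from 2 emit a
  segment call, mirroring real segment callers which report deviations
  only;
* MLPA observations equal to the truth except for an independent error
  rate ``mlpa_error`` (again uniform over admissible wrong states).

Randomness is organised as one independent substream per (stage, locus),
derived from a master seed by hashing stream names, so adding a locus or
stage never perturbs draws elsewhere and a fixed configuration + seed is
fully reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .core import DELETION, DUPLICATION, CnvCall, CnvLocus, Individual, MlpaResult

__all__ = [
    "LocusSpec",
    "ErrorModel",
    "CohortConfig",
    "SyntheticCohort",
    "case_allele_freq",
    "draw_genotypes",
    "corrupt_to_array_calls",
    "emit_mlpa",
    "generate_cohort",
    "substream",
]

ADMISSIBLE = {DELETION: (0, 1, 2), DUPLICATION: (2, 3, 4)}


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """A named, independent RNG substream derived from a master seed.

    Stream identity is the CRC32 of each name component, so streams are
    stable across runs and insensitive to the order in which other streams
    are created.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % 2**31, *keys]))


@dataclass(frozen=True)
class LocusSpec:
    """Simulation parameters for one CNV locus.

    ``control_allele_freq`` is the CNV-allele frequency in controls;
    ``odds_ratio`` the allelic case-vs-control odds ratio; marker counts
    per call are drawn as ``2 + Poisson(mean_markers - 2)`` overdispersed
    by ``marker_dispersion`` (gamma-mixed), and the called span is the
    marker count times ``marker_spacing_bp``.
    """

    locus_id: str
    cnv_type: str
    control_allele_freq: float
    odds_ratio: float
    chrom: str = "chr1"
    start: int = 1_000_000
    end: int = 1_010_000
    mean_markers: float = 10.0
    marker_dispersion: float = 0.0  # 0 = pure Poisson
    marker_spacing_bp: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.control_allele_freq < 1.0:
            raise ValueError("control_allele_freq must be strictly inside (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if self.cnv_type not in ADMISSIBLE:
            raise ValueError(f"cnv_type must be deletion/duplication, got {self.cnv_type!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Array miscall process and MLPA error rate.

    ``alpha_del`` / ``alpha_dup`` are per-type log-odds intercepts of the
    miscall probability; ``beta`` >= 0 is the reliability gain per unit
    ln(marker count); ``batch_effects`` maps batch labels to additive
    shifts on the miscall log-odds.
    """

    alpha_del: float = -1.5
    alpha_dup: float = 0.5
    beta: float = 1.0
    mlpa_error: float = 0.0
    batch_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.mlpa_error < 1.0:
            raise ValueError("mlpa_error must lie in [0, 1)")

    def alpha(self, cnv_type: str) -> float:
        return self.alpha_del if cnv_type == DELETION else self.alpha_dup

    def miscall_prob(self, cnv_type: str, markers: float | np.ndarray, batch_shift: float = 0.0):
        return expit(self.alpha(cnv_type) - self.beta * np.log(markers) + batch_shift)


def case_allele_freq(q_control: float, odds_ratio: float) -> float:
    """Case allele frequency implied by a control frequency and allelic OR.

    Inverts OR = [q_case/(1-q_case)] / [q_ctrl/(1-q_ctrl)]:
    q_case = OR*w / (1 + OR*w) with w = q_ctrl/(1-q_ctrl).
    """
    if not 0.0 < q_control < 1.0:
        raise ValueError("q_control must be strictly inside (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    w = odds_ratio * q_control / (1.0 - q_control)
    return w / (1.0 + w)


def draw_genotypes(
    q: float, n: int, cnv_type: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw n diploid CN genotypes under Hardy-Weinberg proportions.

    Each individual carries Binomial(2, q) CNV alleles; a deletion allele
    lowers CN by 1 from the reference 2, a duplication allele raises it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    alleles = rng.binomial(2, q, size=n)
    return 2 - alleles if cnv_type == DELETION else 2 + alleles


def _replace_uniform(
    cn: np.ndarray, flip: np.ndarray, states: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """Replace flipped entries by a uniformly chosen *different* admissible state."""
    out = cn.copy()
    idx = np.flatnonzero(flip)
    if idx.size == 0:
        return out
    states_arr = np.asarray(states)
    # draw an index among the k-1 wrong states by skipping the true one
    pick = rng.integers(0, len(states_arr) - 1, size=idx.size)
    for j, i in enumerate(idx):
        wrong = states_arr[states_arr != cn[i]]
        out[i] = wrong[pick[j]]
    return out


def corrupt_to_array_calls(
    truth: CnvLocus,
    spec: LocusSpec,
    model: ErrorModel,
    cohort: Sequence[Individual],
    rng: np.random.Generator,
) -> tuple[list[CnvCall], dict[str, int]]:
    """Corrupt true genotypes into array-style segment calls.

    Returns the emitted calls (CN != 2 only) and the full per-individual
    array genotype map (including reference states), which is the ground
    truth of what the array *reported*.
    """
    states = ADMISSIBLE[truth.cnv_type]
    ids = [p.id for p in cohort]
    cn_true = np.array([truth.cn_of(i) for i in ids])
    n = len(ids)

    mean_extra = max(spec.mean_markers - 2.0, 0.0)
    if spec.marker_dispersion > 0:
        lam = rng.gamma(
            shape=1.0 / spec.marker_dispersion,
            scale=mean_extra * spec.marker_dispersion,
            size=n,
        )
    else:
        lam = np.full(n, mean_extra)
    markers = 2 + rng.poisson(lam)

    shifts = np.array([model.batch_effects.get(p.batch, 0.0) for p in cohort])
    p_err = model.miscall_prob(truth.cnv_type, markers, shifts)
    flip = rng.random(n) < p_err
    cn_array = _replace_uniform(cn_true, flip, states, rng)

    calls: list[CnvCall] = []
    for i, iid in enumerate(ids):
        if cn_array[i] == 2:
            continue
        span = int(markers[i]) * spec.marker_spacing_bp
        start = spec.start
        calls.append(
            CnvCall(
                individual_id=iid,
                chrom=spec.chrom,
                start=start,
                end=start + span,
                cn_state=int(cn_array[i]),
                marker_count=int(markers[i]),
            )
        )
    return calls, {iid: int(cn_array[i]) for i, iid in enumerate(ids)}


def emit_mlpa(
    truth: CnvLocus,
    epsilon: float,
    rng: np.random.Generator,
    individual_ids: Sequence[str] | None = None,
) -> list[MlpaResult]:
    """MLPA observations: truth with probability 1 - epsilon, else a random
    different admissible state."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    states = ADMISSIBLE[truth.cnv_type]
    ids = list(individual_ids) if individual_ids is not None else sorted(truth.genotypes)
    cn = np.array([truth.cn_of(i) for i in ids])
    flip = rng.random(len(ids)) < epsilon
    observed = _replace_uniform(cn, flip, states, rng)
    return [MlpaResult(iid, truth.locus_id, int(c)) for iid, c in zip(ids, observed)]


@dataclass(frozen=True)
class CohortConfig:
    """Study-level simulation configuration."""

    n_cases: int = 478
    n_controls: int = 3798
    n_batches: int = 4
    loci: tuple[LocusSpec, ...] = ()
    error_model: ErrorModel = field(default_factory=ErrorModel)
    mlpa_subset: int | None = None  # individuals assayed per locus; None = all cases


@dataclass
class SyntheticCohort:
    """Everything one simulation run produces."""

    cohort: list[Individual]
    truth: dict[str, CnvLocus]  # locus_id -> true genotypes
    array: dict[str, CnvLocus]  # locus_id -> array-reported genotypes
    calls: list[CnvCall]
    mlpa: list[MlpaResult]


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Simulate a full study: cohort, truth, corrupted calls, MLPA."""
    rng_batch = substream(seed, "batches")
    cohort = [
        Individual(f"P{i:05d}", "case", batch=f"b{rng_batch.integers(config.n_batches)}")
        for i in range(config.n_cases)
    ] + [
        Individual(f"C{i:05d}", "control", batch=f"b{rng_batch.integers(config.n_batches)}")
        for i in range(config.n_controls)
    ]
    cases = [p for p in cohort if p.is_case]
    controls = [p for p in cohort if not p.is_case]

    truth: dict[str, CnvLocus] = {}
    array: dict[str, CnvLocus] = {}
    calls: list[CnvCall] = []
    mlpa: list[MlpaResult] = []

    for spec in config.loci:
        rng_g = substream(seed, "genotypes", spec.locus_id)
        q_case = case_allele_freq(spec.control_allele_freq, spec.odds_ratio)
        cn_cases = draw_genotypes(q_case, len(cases), spec.cnv_type, rng_g)
        cn_ctrls = draw_genotypes(
            spec.control_allele_freq, len(controls), spec.cnv_type, rng_g
        )
        genos = {p.id: int(c) for p, c in zip(cases, cn_cases)}
        genos.update({p.id: int(c) for p, c in zip(controls, cn_ctrls)})
        locus = CnvLocus(
            locus_id=spec.locus_id,
            chrom=spec.chrom,
            start=spec.start,
            end=spec.end,
            cnv_type=spec.cnv_type,
            genotypes={k: v for k, v in genos.items() if v != 2},
        )
        truth[spec.locus_id] = locus

        rng_a = substream(seed, "array", spec.locus_id)
        locus_calls, cn_map = corrupt_to_array_calls(
            locus, spec, config.error_model, cohort, rng_a
        )
        calls.extend(locus_calls)
        array[spec.locus_id] = CnvLocus(
            locus_id=spec.locus_id,
            chrom=spec.chrom,
            start=spec.start,
            end=spec.end,
            cnv_type=spec.cnv_type,
            genotypes={k: v for k, v in cn_map.items() if v != 2},
        )

        rng_m = substream(seed, "mlpa", spec.locus_id)
        assay_ids = [p.id for p in cases]
        if config.mlpa_subset is not None:
            assay_ids = assay_ids[: config.mlpa_subset]
        mlpa.extend(emit_mlpa(locus, config.error_model.mlpa_error, rng_m, assay_ids))

    return SyntheticCohort(cohort=cohort, truth=truth, array=array, calls=calls, mlpa=mlpa)
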