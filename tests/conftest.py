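import numpy as np
import pytest

from cnvconcord.core import Individual


@pytest.fixture
def rng():
    return np.random.default_rng(20170823)


@pytest.fixture
def small_cohort():
    """2 cases + 2 controls across two batches."""
    return [
        Individual("P1", "case", "b1"),
        Individual("P2", "case", "b2"),
        Individual("C1", "control", "b1"),
        Individual("C2", "control", "b2"),
    ]


def make_cohort(n_cases: int, n_controls: int, batch: str = "b0") -> list[Individual]:
    return [Individual(f"P{i}", "case", batch) for i in range(n_cases)] + [
        Individual(f"C{i}", "control", batch) for i in range(n_controls)
    ]


def positive_rho_count(n_reps: int = 100, n_loci: int = 20, n_ind: int = 200) -> int:
    """Seeded replicates of the marker-count reliability analysis: returns in
    how many the Spearman correlation between marker count and the cumulative
    validation curve comes out positive."""
    from cnvconcord.concordance import build_match_records, locus_concordance
    from cnvconcord.core import CnvLocus
    from cnvconcord.reliability import reliability_table
    from cnvconcord.simulate import (
        ErrorModel,
        LocusSpec,
        corrupt_to_array_calls,
        emit_mlpa,
        substream,
    )

    cohort = [Individual(f"I{i}", "case") for i in range(n_ind)]
    model = ErrorModel(alpha_del=1.5, beta=1.2)
    positive = 0
    for rep in range(n_reps):
        calls_by_locus, mean_scores, ids = {}, {}, []
        for j in range(n_loci):
            lid = f"L{j}"
            truth = CnvLocus(
                lid, "chr1", 0, 5000, "deletion",
                genotypes={f"I{i}": 1 for i in range(n_ind)},
            )
            spec = LocusSpec(
                lid, "deletion", 0.5, 1.0, start=0, end=5000,
                mean_markers=float(3 + 2 * j),
            )
            rng = substream(rep, "rho-replicate", j)
            locus_calls, cn_map = corrupt_to_array_calls(truth, spec, model, cohort, rng)
            if not locus_calls:
                continue
            mlpa = emit_mlpa(truth, 0.0, rng)
            recs = build_match_records(
                {k: v for k, v in cn_map.items() if v != 2}, mlpa, lid
            )
            ids.append(lid)
            calls_by_locus[lid] = locus_calls
            mean_scores[lid] = locus_concordance(recs, "deletion").mean_score
        _, rho = reliability_table(ids, calls_by_locus, mean_scores, key="markers")
        if rho is not None and rho > 0:
            positive += 1
    return positive
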