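"""Synthetic cohort generator: odds algebra, HWE draws, miscall process."""

import numpy as np
import pytest

from cnvconcord.association import build_allele_table, odds_ratio_ci
from cnvconcord.core import CnvLocus
from cnvconcord.simulate import (
    CohortConfig,
    ErrorModel,
    LocusSpec,
    case_allele_freq,
    corrupt_to_array_calls,
    draw_genotypes,
    emit_mlpa,
    generate_cohort,
    substream,
)

from conftest import make_cohort


def test_case_allele_freq_identity_and_inversion():
    assert case_allele_freq(0.5, 1.0) == pytest.approx(0.5)
    # frequency implied by a control frequency of 79.3% and allelic OR 2.36
    q_case = case_allele_freq(0.793, 2.36)
    assert q_case == pytest.approx(0.900, abs=5e-4)
    # the OR recomputed from the two frequencies round-trips exactly
    w_case = q_case / (1 - q_case)
    w_ctrl = 0.793 / (1 - 0.793)
    assert w_case / w_ctrl == pytest.approx(2.36, rel=1e-12)


def test_case_allele_freq_round_trip_generic():
    q_case = case_allele_freq(0.304, 1.88)
    assert q_case == pytest.approx(0.451, abs=5e-4)
    assert (q_case / (1 - q_case)) / (0.304 / 0.696) == pytest.approx(1.88, rel=1e-12)


@pytest.mark.parametrize("bad_q", [0.0, 1.0, -0.1])
def test_case_allele_freq_boundary_is_domain_error(bad_q):
    with pytest.raises(ValueError):
        case_allele_freq(bad_q, 2.0)


def test_draw_genotypes_degenerate_frequencies(rng):
    assert np.all(draw_genotypes(0.0, 50, "deletion", rng) == 2)
    assert np.all(draw_genotypes(1.0, 50, "deletion", rng) == 0)
    assert np.all(draw_genotypes(1.0, 50, "duplication", rng) == 4)


def test_draw_genotypes_recovers_allele_frequency(rng):
    n, q = 100_000, 0.2
    cn = draw_genotypes(q, n, "deletion", rng)
    q_hat = (2 - cn).sum() / (2 * n)
    se = np.sqrt(q * (1 - q) / (2 * n))
    assert abs(q_hat - q) < 3 * se


def test_draw_genotypes_hwe_proportions(rng):
    n, q = 100_000, 0.3
    cn = draw_genotypes(q, n, "duplication", rng)
    for state, prob in ((4, q**2), (3, 2 * q * (1 - q)), (2, (1 - q) ** 2)):
        frac = np.mean(cn == state)
        assert abs(frac - prob) < 3 * np.sqrt(prob * (1 - prob) / n)


def _carrier_locus(n, cnv_type="deletion"):
    """Everyone a heterozygous carrier, for clean miscall-rate estimation."""
    return CnvLocus(
        "L", "chr1", 1000, 6000, cnv_type,
        genotypes={f"P{i}": 1 if cnv_type == "deletion" else 3 for i in range(n)},
    )


def test_corrupt_with_vanishing_error_reproduces_truth(rng):
    n = 500
    cohort = make_cohort(n, 0)
    locus = _carrier_locus(n)
    spec = LocusSpec("L", "deletion", 0.5, 1.0, start=1000, end=6000, mean_markers=10)
    model = ErrorModel(alpha_del=-60.0, alpha_dup=-60.0, beta=0.0)
    calls, cn_map = corrupt_to_array_calls(locus, spec, model, cohort, rng)
    assert all(cn_map[p.id] == locus.cn_of(p.id) for p in cohort)
    assert len(calls) == n  # every carrier emits a call


def test_corrupt_reproduces_configured_discordance_rate(rng):
    """With alpha set so the miscall probability is 0.37 at the fixed marker
    count, the empirical discordance over 10000 carriers is 0.37 +/- 3 SE."""
    n, target = 10_000, 0.37
    cohort = make_cohort(n, 0)
    locus = _carrier_locus(n)
    # mean_markers=2 makes the per-call marker count deterministic (2),
    # and beta=0 removes the marker-count term
    spec = LocusSpec("L", "deletion", 0.5, 1.0, start=1000, end=6000, mean_markers=2.0)
    alpha = np.log(target / (1 - target))
    model = ErrorModel(alpha_del=float(alpha), beta=0.0)
    _, cn_map = corrupt_to_array_calls(locus, spec, model, cohort, rng)
    rate = np.mean([cn_map[p.id] != locus.cn_of(p.id) for p in cohort])
    assert abs(rate - target) < 3 * np.sqrt(target * (1 - target) / n)


def test_higher_marker_count_lowers_miscall_rate(rng):
    """beta > 0: a 40-marker locus miscalls strictly less than a 10-marker one."""
    n = 10_000
    cohort = make_cohort(n, 0)
    locus = _carrier_locus(n)
    model = ErrorModel(alpha_del=0.5, beta=1.0)
    rates = {}
    for markers in (10, 40):
        spec = LocusSpec(
            "L", "deletion", 0.5, 1.0, start=1000, end=6000, mean_markers=float(markers)
        )
        _, cn_map = corrupt_to_array_calls(locus, spec, model, cohort, rng)
        rates[markers] = np.mean([cn_map[p.id] != locus.cn_of(p.id) for p in cohort])
    p10 = float(model.miscall_prob("deletion", 10))
    p40 = float(model.miscall_prob("deletion", 40))
    margin = 3 * np.sqrt(p10 * (1 - p10) / n) + 3 * np.sqrt(p40 * (1 - p40) / n)
    assert rates[40] < rates[10] - (p10 - p40) + margin
    assert rates[40] < rates[10]  # realised ordering at this n


def test_batch_shift_raises_miscall_rate(rng):
    n = 4000
    cohort = [p for p in make_cohort(n, 0)]
    shifted = [type(p)(p.id, p.status, "bad") for p in cohort[: n // 2]] + cohort[n // 2 :]
    locus = _carrier_locus(n)
    spec = LocusSpec("L", "deletion", 0.5, 1.0, start=1000, end=6000, mean_markers=10.0)
    model = ErrorModel(alpha_del=-2.0, beta=0.0, batch_effects={"bad": 2.0})
    _, cn_map = corrupt_to_array_calls(locus, spec, model, shifted, rng)
    bad_rate = np.mean([cn_map[p.id] != locus.cn_of(p.id) for p in shifted[: n // 2]])
    good_rate = np.mean([cn_map[p.id] != locus.cn_of(p.id) for p in shifted[n // 2 :]])
    assert bad_rate > good_rate


def test_emit_mlpa_exact_at_zero_error(rng):
    locus = _carrier_locus(200)
    results = emit_mlpa(locus, 0.0, rng)
    assert all(r.cn == locus.cn_of(r.individual_id) for r in results)


def test_emit_mlpa_error_rate_recovered(rng):
    n, eps = 10_000, 0.05
    locus = _carrier_locus(n)
    results = emit_mlpa(locus, eps, rng)
    rate = np.mean([r.cn != locus.cn_of(r.individual_id) for r in results])
    assert abs(rate - eps) < 3 * np.sqrt(eps * (1 - eps) / n)


def test_miscalls_land_on_admissible_different_states(rng):
    locus = _carrier_locus(2000, "duplication")
    spec = LocusSpec("L", "duplication", 0.5, 1.0, start=1000, end=6000, mean_markers=5)
    model = ErrorModel(alpha_dup=3.0, beta=0.0)
    _, cn_map = corrupt_to_array_calls(locus, spec, model, make_cohort(2000, 0), rng)
    assert set(cn_map.values()) <= {2, 3, 4}


def test_generate_cohort_deterministic_and_substreams_independent():
    cfg = CohortConfig(
        n_cases=50, n_controls=100, n_batches=2,
        loci=(LocusSpec("L1", "deletion", 0.3, 1.5), LocusSpec("L2", "duplication", 0.1, 1.0)),
        error_model=ErrorModel(mlpa_error=0.02),
    )
    a = generate_cohort(cfg, seed=11)
    b = generate_cohort(cfg, seed=11)
    assert a.calls == b.calls and a.mlpa == b.mlpa
    assert a.truth["L1"].genotypes == b.truth["L1"].genotypes
    # adding a locus must not perturb the draws of existing loci
    cfg3 = CohortConfig(
        n_cases=50, n_controls=100, n_batches=2,
        loci=cfg.loci + (LocusSpec("L3", "deletion", 0.2, 1.0),),
        error_model=ErrorModel(mlpa_error=0.02),
    )
    c = generate_cohort(cfg3, seed=11)
    assert c.truth["L1"].genotypes == a.truth["L1"].genotypes
    assert [x for x in c.mlpa if x.locus_id == "L1"] == [x for x in a.mlpa if x.locus_id == "L1"]


def test_substream_names_give_distinct_streams():
    r1 = substream(5, "genotypes", "L1")
    r2 = substream(5, "genotypes", "L2")
    assert r1.integers(0, 2**31, 10).tolist() != r2.integers(0, 2**31, 10).tolist()


def test_simulated_or_is_recoverable_without_array_error():
    """Association on error-free simulated truth recovers the configured OR."""
    cfg = CohortConfig(
        n_cases=2000, n_controls=2000, n_batches=1,
        loci=(LocusSpec("L1", "deletion", 0.793, 2.36),),
        error_model=ErrorModel(alpha_del=-60, alpha_dup=-60, beta=0.0),
    )
    sim = generate_cohort(cfg, seed=99)
    t = build_allele_table(sim.truth["L1"], sim.cohort)
    or_, lo, hi = odds_ratio_ci(t)
    assert lo < 2.36 < hi or abs(or_ - 2.36) < 0.5
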