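"""Pipeline orchestration and report rendering.

Two entry points:

* :func:`run_fixture_analysis` recomputes every statistic of the bundled
  reference study (association tables, Fisher screens of low-frequency
  CNVs, the 28-locus validation ledger, discordance rates) from its raw
  counts;
* :func:`run_simulated_analysis` generates a synthetic cohort, writes all
  stage input/output TSVs, and runs filter -> genotype -> associate ->
  concord -> reliability end to end.

Report printing follows the conventions of published copy-number
association tables: odds ratios and CI bounds to 2 decimals, allele
frequencies to 1 decimal, p-values to 2 significant figures (1 decimal in
the rare-CNV Fisher table).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .association import associate, chi2_allelic, fisher_exact, odds_ratio_ci
from .concordance import (
    build_match_records,
    locus_concordance,
    type_validation_summary,
)
from .core import write_cnv_calls, write_mlpa_table, write_sample_sheet
from .filtering import FilterPolicy, batch_heterogeneity, filter_calls, genotype_locus
from .fixtures import (
    ALL_ASSOCIATION_ROWS,
    SUSCEPTIBILITY_ROWS,
    UXS1_DISCORDANCE,
    TRB_DISCORDANCE,
    TRB_FULL_COHORT_DISCORDANCE,
    VALIDATION_LEDGER,
)
from .reliability import reliability_table
from .simulate import CohortConfig, ErrorModel, LocusSpec, generate_cohort

__all__ = [
    "format_or_ci",
    "format_p",
    "format_freq",
    "run_fixture_analysis",
    "run_simulated_analysis",
    "config_from_yaml",
]


# --- printing conventions ---------------------------------------------------


def format_or_ci(or_: float, lo: float, hi: float) -> str:
    """e.g. ``2.36 [1.90-2.94]``."""
    return f"{or_:.2f} [{lo:.2f}-{hi:.2f}]"


def format_p(p: float, decimals: int | None = None) -> str:
    """p to 2 significant figures, scientific below 1e-3; or fixed decimals."""
    if decimals is not None:
        return f"{p:.{decimals}f}"
    if p < 1e-3:
        return f"{p:.2e}"
    return f"{p:.2g}"


def format_freq(fraction: float) -> str:
    """Allele frequency as a percentage with 1 decimal."""
    return f"{100 * fraction:.1f}"


# --- fixture-driven analysis ------------------------------------------------


def run_fixture_analysis(yates: bool = False) -> dict[str, Any]:
    """Recompute all statistics of the bundled reference study.

    Returns a nested dict: per association row OR/CI/chi2 p, per
    susceptibility CNV the Fisher p (validated loci only), the per-type
    validation rates of the 28-locus ledger, and the discordance rates.
    """
    assoc = {}
    for row in ALL_ASSOCIATION_ROWS:
        t = row.table
        or_, lo, hi = odds_ratio_ci(t)
        assoc[f"{row.locus_id}|{row.cohort}"] = {
            "table": (t.a, t.b, t.c, t.d),
            "case_freq_pct": 100 * t.case_freq,
            "control_freq_pct": 100 * t.control_freq,
            "odds_ratio": or_,
            "ci_low": lo,
            "ci_high": hi,
            "chi2_p": chi2_allelic(t, yates=yates),
            "rendered": format_or_ci(or_, lo, hi),
            "source": row.source,
        }

    fisher = {}
    for row in SUSCEPTIBILITY_ROWS:
        entry: dict[str, Any] = {
            "case_alleles": row.case_alleles,
            "control_alleles": row.control_alleles,
            "validated": row.validated,
            "source": row.source,
        }
        if row.validated:
            p = fisher_exact(row.allele_table())
            entry["fisher_p"] = p
            entry["rendered_p"] = format_p(p, decimals=1)
        fisher[row.gene] = entry

    dels = [e for e in VALIDATION_LEDGER if e.cnv_type == "deletion"]
    dups = [e for e in VALIDATION_LEDGER if e.cnv_type == "duplication"]
    ledger = {
        "n_deletion": len(dels),
        "n_duplication": len(dups),
        "validated_deletion": sum(e.validated for e in dels),
        "validated_duplication": sum(e.validated for e in dups),
        "deletion_rate_pct": 100 * sum(e.validated for e in dels) / len(dels),
        "duplication_rate_pct": 100 * sum(e.validated for e in dups) / len(dups),
    }

    def _rate(pair):
        return {"discordant": pair[0], "assayed": pair[1], "pct": 100 * pair[0] / pair[1]}

    return {
        "association": assoc,
        "susceptibility_fisher": fisher,
        "validation_ledger": ledger,
        "discordance": {
            "UXS1": _rate(UXS1_DISCORDANCE),
            "TRB": _rate(TRB_DISCORDANCE),
            "TRB_full_cohort": _rate(TRB_FULL_COHORT_DISCORDANCE),
        },
    }


# --- simulation-driven pipeline ---------------------------------------------


DEFAULT_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec(
        "del-frequent", "deletion", control_allele_freq=0.793, odds_ratio=2.36,
        chrom="chr2", start=106_246_526, end=106_251_789,
        mean_markers=10.0, marker_spacing_bp=700,
    ),
    LocusSpec(
        "dup-frequent", "duplication", control_allele_freq=0.30, odds_ratio=1.0,
        chrom="chr5", start=2_000_000, end=2_012_000,
        mean_markers=8.0, marker_spacing_bp=1500,
    ),
    LocusSpec(
        "del-rare", "deletion", control_allele_freq=0.01, odds_ratio=1.0,
        chrom="chr8", start=3_000_000, end=3_020_000,
        mean_markers=25.0, marker_spacing_bp=800,
    ),
)


def run_simulated_analysis(
    seed: int,
    out_dir: str | Path,
    config: CohortConfig | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> dict[str, Any]:
    """Simulate a cohort and run every analysis stage, writing TSVs.

    Stages run in order: simulate, filter, per-locus genotyping, batch
    screen, association, concordance, reliability.  All outputs land under
    ``out_dir``; the returned dict summarises each stage and is also
    written as ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or CohortConfig(loci=DEFAULT_LOCI, error_model=ErrorModel(mlpa_error=0.02))
    sim = generate_cohort(cfg, seed)

    write_sample_sheet(out / "samples.tsv", sim.cohort)
    write_cnv_calls(out / "calls.tsv", sim.calls)
    write_mlpa_table(out / "mlpa.tsv", sim.mlpa)

    kept, dropped = filter_calls(sim.calls, policy)
    write_cnv_calls(out / "calls.kept.tsv", kept)
    write_cnv_calls(out / "calls.dropped.tsv", dropped)

    report: dict[str, Any] = {
        "seed": seed,
        "version": __version__,
        "n_cases": cfg.n_cases,
        "n_controls": cfg.n_controls,
        "policy": {"min_markers": policy.min_markers, "min_span_bp": policy.min_span_bp,
                   "enabled": policy.enabled},
        "n_calls": len(sim.calls),
        "n_kept": len(kept),
        "loci": {},
    }

    calls_by_locus: dict[str, list] = {}
    mean_scores: dict[str, float] = {}
    concordances = []
    for spec in cfg.loci:
        locus = genotype_locus(
            sim.calls, spec.locus_id, spec.chrom, spec.start, spec.end,
            spec.cnv_type, policy=policy,
        )
        res = associate(locus, sim.cohort)
        screen = batch_heterogeneity(locus, sim.cohort)
        records = build_match_records(sim.array[spec.locus_id].genotypes, sim.mlpa, spec.locus_id)
        locus_calls = [c for c in sim.calls if c.chrom == spec.chrom]
        entry: dict[str, Any] = {
            "cnv_type": spec.cnv_type,
            "allele_table": (res.table.a, res.table.b, res.table.c, res.table.d),
            "odds_ratio": res.odds_ratio,
            "ci": (res.ci_low, res.ci_high),
            "chi2_p": res.chi2_p,
            "fisher_p": res.fisher_p,
            "rendered": format_or_ci(res.odds_ratio, res.ci_low, res.ci_high),
            "batch_p": screen.p_value,
            "batch_flagged": screen.flagged,
        }
        if records:
            conc = locus_concordance(records, spec.cnv_type)
            concordances.append(conc)
            mean_scores[spec.locus_id] = conc.mean_score
            calls_by_locus[spec.locus_id] = locus_calls
            entry["mean_match_score"] = conc.mean_score
            entry["discordance_rate"] = conc.discordance_rate
            entry["validated"] = conc.validated
        report["loci"][spec.locus_id] = entry

    if concordances:
        comp = type_validation_summary(concordances)
        report["type_comparison"] = {
            "n_del": comp.n_del, "n_dup": comp.n_dup,
            "validated_del": comp.validated_del, "validated_dup": comp.validated_dup,
            "mean_of_means_del": comp.mean_of_means_del,
            "mean_of_means_dup": comp.mean_of_means_dup,
            "mann_whitney_p": comp.p_value,
        }
    usable = [l for l in calls_by_locus if calls_by_locus[l]]
    if len(usable) >= 3:
        points, rho = reliability_table(
            usable, calls_by_locus, mean_scores, key="markers"
        )
        report["reliability"] = {
            "spearman_rho_markers": rho,
            "curve": [
                (p.locus_id, p.median_marker_count, p.cumulative_mean) for p in points
            ],
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def config_from_yaml(path: str | Path) -> tuple[CohortConfig, FilterPolicy]:
    """Load a simulation/analysis configuration from a YAML file.

    Schema (all keys optional, defaults in parentheses)::

        n_cases: 478        n_controls: 3798      n_batches: 4
        mlpa_subset: null
        error_model: {alpha_del: -1.5, alpha_dup: 0.5, beta: 1.0,
                      mlpa_error: 0.0, batch_effects: {b1: 0.5}}
        loci:
          - {locus_id: L1, cnv_type: deletion, control_allele_freq: 0.2,
             odds_ratio: 1.5, chrom: chr1, start: 0, end: 10000,
             mean_markers: 10, marker_spacing_bp: 500}
        filter: {min_markers: 5, min_span_bp: 5000, enabled: true}
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    loci = tuple(LocusSpec(**l) for l in raw.get("loci", []))
    em = ErrorModel(**raw.get("error_model", {}))
    cfg = CohortConfig(
        n_cases=raw.get("n_cases", 478),
        n_controls=raw.get("n_controls", 3798),
        n_batches=raw.get("n_batches", 4),
        loci=loci or DEFAULT_LOCI,
        error_model=em,
        mlpa_subset=raw.get("mlpa_subset"),
    )
    policy = FilterPolicy(**raw.get("filter", {}))
    return cfg, policy
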