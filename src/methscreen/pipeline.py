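"""End-to-end orchestration: simulate/ingest -> screen -> candidates ->
cross-validate -> enrichment -> signatures -> patterns -> report.

A single run seed fans out to per-stage child seeds through a fixed
name-hash derivation, so any stage can be re-run in isolation and still
reproduce its draws.  Every threshold, family size, transform and
orientation choice is echoed into the JSON summaries: the analysis has
several under-specified knobs and each run must be auditable.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import patterns as pat
from . import screen as scr
from . import signatures as sig
from .io import (
    Cohort,
    GeneCatalog,
    default_catalog,
    read_cohort,
    write_results,
    write_run_summary,
    _write_frame,
)
from .simulate import (
    DEFAULT_IMMUNE_GENES,
    SimulationConfig,
    generate_cohort,
    loading_for_target_rho,
    write_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "stage_seed",
           "study_like_configs", "tiny_config"]

logger = logging.getLogger(__name__)

MARKERS = ("CD274", "CTLA4")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (stable across runs)."""
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort_dirs: list[str] = field(default_factory=list)
    simulate: str | None = None           # None | "tiny" | "study-like"
    markers: tuple[str, str] = MARKERS
    cutoff: float | str = 0.3             # numeric or "calibrate:<fraction>"
    alpha: float = 0.05
    ifng_genes: tuple[str, ...] = sig.IFNG_SIGNATURE_GENES
    seed: int = 0
    output_dir: str | Path = "methscreen_run"
    min_candidates_for_enrichment: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if isinstance(self.cutoff, str):
            if not self.cutoff.startswith("calibrate:"):
                raise ValueError("cutoff must be numeric or 'calibrate:<fraction>'")
            frac = float(self.cutoff.split(":", 1)[1])
            if not 0.0 < frac < 1.0:
                raise ValueError("calibration fraction must lie in (0, 1)")
        elif not 0.0 < float(self.cutoff) < 1.0:
            raise ValueError("numeric cutoff must lie in (0, 1)")


# ---------------------------------------------------------------------------
# fixtures: seeded synthetic cohorts with the study's shape
# ---------------------------------------------------------------------------

#: candidate-like genes planted on the latent factor, per fixture cohort
PLANTED = {
    "HNSCC": ["XRCC1", "MLH3", "PMS1", "RAD51B", "XRCC3", "RAD54B", "BRCA1",
              "SHFM1", "GEN1", "FANCE", "FAAP20", "SPRTN", "SETMAR", "HUS1",
              "PER1"],
    "CESC": ["OGG1", "MSH5", "RAD51B"],
    "LUSC": ["RAD51B", "CHEK1"],
}

#: (n_samples, n genes with methylation data) per fixture cohort
COHORT_SHAPES = {"HNSCC": (278, 152), "CESC": (191, 153), "LUSC": (74, 158)}

#: population Spearman rho targeted for planted gene/checkpoint couplings
PLANTED_TARGET_RHO = 0.45


def _available_genes(catalog: GeneCatalog, n_available: int, keep: list[str],
                     seed: int) -> tuple[str, ...]:
    """Drop genes to emulate incomplete HM450 coverage, never dropping the
    homologous-recombination group or the planted genes."""
    hr = set(catalog.genes_in_group("homologous recombination"))
    protected = hr | set(keep)
    droppable = [g for g in catalog.genes if g not in protected]
    n_drop = len(catalog) - n_available
    if n_drop > len(droppable):
        raise ValueError("cannot drop that many genes")
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(droppable, size=n_drop, replace=False))
    return tuple(g for g in catalog.genes if g not in dropped)


def study_like_configs(seed: int, catalog: GeneCatalog | None = None) -> list[SimulationConfig]:
    """Three squamous-cohort configs mirroring the study's shapes: 278/191/74
    samples with 152/153/158 measured repair genes and 15/3/2 planted
    latent-linked genes; RAD51B is planted in all three."""
    catalog = catalog or default_catalog()
    loading = loading_for_target_rho(PLANTED_TARGET_RHO)
    configs = []
    for name, (n, avail) in COHORT_SHAPES.items():
        child = stage_seed(seed, f"simulate:{name}")
        configs.append(
            SimulationConfig(
                n_samples=n,
                repair_genes=catalog,
                latent_loading_meth={g: loading for g in PLANTED[name]},
                available_genes=_available_genes(
                    catalog, avail, PLANTED[name], stage_seed(seed, f"avail:{name}")
                ),
                name=name,
                seed=child,
            )
        )
    return configs


def tiny_config(seed: int, catalog: GeneCatalog | None = None) -> SimulationConfig:
    """One 20-gene x 40-sample cohort for smoke tests (runs in seconds)."""
    catalog = catalog or default_catalog()
    genes = catalog.genes_in_group("homologous recombination")[:8]
    non_hr = [g for g in catalog.genes
              if "homologous recombination" not in catalog.groups[g]]
    genes += non_hr[:12]
    small = catalog.subset(genes)
    loading = loading_for_target_rho(0.6)
    planted = genes[:4]
    return SimulationConfig(
        n_samples=40,
        repair_genes=small,
        latent_loading_meth={g: loading for g in planted},
        name="TINY",
        seed=stage_seed(seed, "simulate:TINY"),
    )


def make_fixture(scale: str, seed: int, outdir: str | Path | None = None,
                 catalog: GeneCatalog | None = None):
    """Generate fixture cohorts; optionally write them as TSV bundles.

    ``tiny``: one 20-gene x 40-sample cohort.  ``study-like``: three cohorts
    with the study's sample sizes and gene availability.
    Returns the list of (config, cohort) pairs.
    """
    if scale == "tiny":
        configs = [tiny_config(seed, catalog)]
    elif scale == "study-like":
        configs = study_like_configs(seed, catalog)
    else:
        raise ValueError("scale must be 'tiny' or 'study-like'")
    out = []
    for config in configs:
        cohort = generate_cohort(config)
        if outdir is not None:
            write_cohort(cohort, Path(outdir) / config.name, config)
        out.append((config, cohort))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _resolve_cutoff(config: RunConfig, screen_result: scr.ScreenResult) -> float:
    if isinstance(config.cutoff, str):
        fraction = float(config.cutoff.split(":", 1)[1])
        return scr.calibrate_cutoff(screen_result, fraction)
    return float(config.cutoff)


def run_pipeline(config: RunConfig, catalog: GeneCatalog | None = None) -> dict:
    """Execute every stage on every cohort and write the report bundle.

    Stage order per cohort: screen both markers -> cutoff (fixed or
    calibrated on the first cohort's first-marker screen) -> candidate
    intersection -> enrichment (union fallback when the candidate list is
    smaller than ``min_candidates_for_enrichment``) -> signature panel ->
    methylation patterns.  Candidate lists are then cross-validated in the
    other cohorts.  Returns the report dict, also written as JSON.
    """
    if config.simulate is None and not config.cohort_dirs:
        raise ValueError("no cohorts: provide cohort_dirs or a simulate scale")
    catalog = catalog or default_catalog()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohorts: list[Cohort] = []
    if config.simulate is not None:
        for cfg, cohort in make_fixture(config.simulate, config.seed,
                                        outdir / "cohorts", catalog):
            cohorts.append(cohort)
    for directory in config.cohort_dirs:
        cohorts.append(read_cohort(directory))
    if not cohorts:
        raise ValueError("no cohorts: provide cohort_dirs or a simulate scale")

    report: dict = {"seed": config.seed, "markers": list(config.markers),
                    "alpha": config.alpha, "cohorts": {}}
    candidates_by_cohort: dict[str, scr.CandidateList] = {}
    screens: dict[str, dict[str, scr.ScreenResult]] = {}

    for cohort in cohorts:
        cdir = outdir / cohort.name
        cdir.mkdir(parents=True, exist_ok=True)
        entry: dict = {}

        per_marker = {m: scr.run_screen(cohort, catalog, m) for m in config.markers}
        screens[cohort.name] = per_marker
        for marker, res in per_marker.items():
            write_results(res, cdir / f"screen_{marker}.tsv")
        cutoff = _resolve_cutoff(config, per_marker[config.markers[0]])
        entry["cutoff"] = cutoff
        entry["m_tests"] = {m: r.m_tests for m, r in per_marker.items()}

        cand = scr.select_candidates(per_marker[config.markers[0]],
                                     per_marker[config.markers[1]], cutoff)
        candidates_by_cohort[cohort.name] = cand
        write_results(cand, cdir / "candidates.tsv")
        entry["n_candidates"] = len(cand)
        entry["candidates"] = list(cand.genes)

        background = set(per_marker[config.markers[0]].rows["repair_gene"])
        if len(cand) >= config.min_candidates_for_enrichment:
            gene_set: list[str] = list(cand.genes)
            entry["enrichment_gene_set"] = "candidates"
        else:
            union = enr.expand_for_small_lists(per_marker[config.markers[0]],
                                               per_marker[config.markers[1]], cutoff)
            gene_set = sorted(union & background)
            entry["enrichment_gene_set"] = "either-marker union (small list fallback)"
        if gene_set:
            report_enr = enr.enrich(gene_set, catalog, background,
                                    cohort_name=cohort.name)
            write_results(report_enr, cdir / "enrichment.tsv")
            head = report_enr.headline()
            entry["enrichment"] = {
                "n_genes": len(gene_set),
                "headline_pathway": head.pathway if head else None,
                "headline_p": head.p_one_sided if head else None,
            }
        else:
            entry["enrichment"] = {"n_genes": 0, "headline_pathway": None,
                                   "headline_p": None}

        if len(cand):
            table = sig.build_signature_table(cohort, cand.genes, catalog.genes,
                                              ifng_genes=config.ifng_genes)
            write_results(table, cdir / "signatures.tsv")
            panel = table.table
            rho_m, p_m, _ = sig.score_vs_expression(
                panel["meth_score"], cohort.expression.values.loc[config.markers[0]])
            entry["meth_score_vs_marker_rho"] = rho_m
            entry["meth_score_vs_marker_p"] = p_m
            if cohort.mutations is not None:
                rho_u, p_u, _ = sig.score_vs_expression(
                    panel["mut_score_all"],
                    cohort.expression.values.loc[config.markers[0]])
                entry["mut_score_vs_marker_rho"] = rho_u
                entry["mut_score_vs_marker_p"] = p_u
            else:
                entry["mut_score_vs_marker_rho"] = "not available"
            levels, trend_rho, trend_p = sig.dose_response(panel["ifng_score"],
                                                           panel["meth_score"])
            _write_frame(levels, cdir / "dose_response.tsv", index=False)
            entry["dose_trend_rho"] = trend_rho
            entry["dose_trend_p"] = trend_p

            centered = pat.center_methylation(cohort.methylation, cand.genes)
            clusters = pat.cluster_genes(centered)
            _write_frame(clusters.centered_matrix, cdir / "centered_methylation.tsv",
                         index_label="gene")
            write_run_summary(cdir / "clustering.json", {
                "gene_order": clusters.gene_order,
                "distance_metric": clusters.distance_metric,
                "linkage": [[float(x) for x in row] for row in clusters.linkage],
            })
            assoc = pat.methylation_association_matrix(cohort.methylation,
                                                       cand.genes, "correlation")
            _write_frame(assoc, cdir / "methylation_correlation.tsv",
                         index_label="gene")
            if (cohort.metadata is not None
                    and "tp53_mutant" in cohort.metadata.columns):
                labels = cohort.metadata["tp53_mutant"].reindex(
                    cohort.shared_samples())
                try:
                    groups = pat.compare_groups(cohort.methylation, cand.genes,
                                                labels)
                    _write_frame(groups, cdir / "tp53_comparison.tsv", index=False)
                    entry["tp53_n_significant"] = int(
                        (groups["p_bonferroni"] < config.alpha).sum())
                except ValueError as exc:
                    entry["tp53_n_significant"] = f"not available ({exc})"
        else:
            entry["signatures"] = "not available (empty candidate list)"

        report["cohorts"][cohort.name] = entry

    # cross-validation of every candidate list in the other cohorts
    crossval: dict[str, dict] = {}
    for cohort in cohorts:
        cand = candidates_by_cohort[cohort.name]
        if not len(cand):
            continue
        others = [c for c in cohorts if c.name != cohort.name]
        if not others:
            continue
        table = scr.cross_validate(cand, others, catalog, config.markers)
        _write_frame(table, outdir / f"crossval_{cohort.name}.tsv",
                     index_label="gene")
        crossval[cohort.name] = {
            "all_positive": sorted(table.index[table["all_positive"]]),
        }
    report["cross_validation"] = crossval

    write_run_summary(outdir / "report.json", report)
    return report
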