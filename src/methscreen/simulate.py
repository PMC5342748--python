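"""Seeded generator of TCGA-like squamous-cell-carcinoma cohorts.

A single latent "inflammation" factor per sample drives every coupling the
downstream analysis looks for: immune-gene expression (including the
CD274/PD-L1 and CTLA4 checkpoints and the six interferon-gamma signature
genes) loads positively on the factor, and a planted subset of DNA-repair
genes has methylation that loads on the same factor.  This one mechanism
simultaneously induces checkpoint-vs-methylation correlation, a
methylation-dose response of the inflammatory signature, and co-clustering
of the planted genes — while mutations are drawn independently of the
factor, so mutation scores stay null.

Model, per sample i with latent L_i ~ N(0, 1):

* immune-gene expression:  log2(x_gi + 1) = mu_g + b_g * L_i + eps,
  eps ~ N(0, expr_noise_sd); emitted on the raw RSEM-like scale
  x = max(2^v - 1, 0)
* linked repair-gene methylation:  beta_gi = invlogit(a_g + c_g * L_i + eta),
  eta ~ N(0, meth_noise_sd); unlinked genes omit the c_g * L_i term
* every repair gene also gets an expression row whose log2(x+1) value is
  depressed by ``own_gene_coupling * (beta_gi - mean_i beta_gi)`` with
  own_gene_coupling <= 0, so within-gene methylation-vs-expression
  correlation is negative, as observed on real tumor data
* mutations: independent Bernoulli(mutation_rate) per (sample, gene)

Per-gene baselines a_g and mu_g are drawn once from fixed uniform ranges
under the config seed, so genes are heterogeneous but reproducible and do
not depend on the number of samples requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .io import Cohort, GeneCatalog, MutationTable, OmicsMatrix, write_run_summary

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "expected_rho",
    "loading_for_target_rho",
    "write_cohort",
]

#: Six-gene interferon-gamma inflammatory signature (checkpoint-response marker).
IFNG_SIGNATURE_GENES = ("IFNG", "HLA-DRA", "CXCL9", "CXCL10", "IDO1", "STAT1")

DEFAULT_IMMUNE_GENES = ("CD274", "CTLA4") + IFNG_SIGNATURE_GENES

VARIANT_CLASSES = ("missense_mutation", "nonsense_mutation", "frame_shift_del", "splice_site")

# spawn keys for the named child streams of the config seed
_STREAMS = {"baselines": 0, "latent": 1, "meth": 2, "expr_immune": 3,
            "expr_repair": 4, "mutations": 5, "metadata": 6}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``latent_loading_meth`` maps each linked repair gene to its methylation
    loading c_g on the latent factor; ``latent_loading_expr`` maps immune
    genes to their expression loadings b_g (genes absent from the map get
    ``default_expr_loading``).  ``own_gene_coupling`` (<= 0) sets how
    strongly a repair gene's own expression is depressed by its methylation.
    ``available_genes``, when given, restricts which repair genes receive a
    methylation row — emulating the incomplete HM450 gene coverage of real
    cohorts (e.g. 152 of 179 genes measured).
    """

    n_samples: int
    repair_genes: GeneCatalog
    immune_genes: tuple[str, ...] = DEFAULT_IMMUNE_GENES
    latent_loading_meth: Mapping[str, float] = field(default_factory=dict)
    latent_loading_expr: Mapping[str, float] = field(default_factory=dict)
    default_expr_loading: float = 1.0
    meth_noise_sd: float = 1.0
    expr_noise_sd: float = 0.5
    own_gene_coupling: float = -2.0
    mutation_rate: float = 0.012
    tp53_mutation_rate: float = 0.7
    available_genes: tuple[str, ...] | None = None
    name: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.meth_noise_sd <= 0 or self.expr_noise_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.own_gene_coupling > 0:
            raise ValueError("own_gene_coupling must be <= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        unknown = set(self.latent_loading_meth) - set(self.repair_genes.genes)
        if unknown:
            raise ValueError(f"linked genes not in catalog: {sorted(unknown)}")
        required = {"CD274", "CTLA4", *IFNG_SIGNATURE_GENES}
        missing = required - set(self.immune_genes)
        if missing:
            raise ValueError(f"immune_genes must include {sorted(missing)}")
        if self.available_genes is not None:
            stray = set(self.available_genes) - set(self.repair_genes.genes)
            if stray:
                raise ValueError(f"available_genes not in catalog: {sorted(stray)}")

    @property
    def linked_genes(self) -> tuple[str, ...]:
        return tuple(self.latent_loading_meth.keys())

    def expr_loading(self, gene: str) -> float:
        return float(self.latent_loading_expr.get(gene, self.default_expr_loading))

    def to_jsonable(self) -> dict:
        return {
            "name": self.name,
            "n_samples": self.n_samples,
            "n_repair_genes": len(self.repair_genes),
            "immune_genes": list(self.immune_genes),
            "latent_loading_meth": dict(self.latent_loading_meth),
            "latent_loading_expr": dict(self.latent_loading_expr),
            "default_expr_loading": self.default_expr_loading,
            "meth_noise_sd": self.meth_noise_sd,
            "expr_noise_sd": self.expr_noise_sd,
            "own_gene_coupling": self.own_gene_coupling,
            "mutation_rate": self.mutation_rate,
            "tp53_mutation_rate": self.tp53_mutation_rate,
            "available_genes": None if self.available_genes is None
            else list(self.available_genes),
            "seed": self.seed,
        }


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


def _baselines(config: SimulationConfig) -> tuple[dict, dict, dict]:
    """Per-gene intercepts, drawn once under the seed, independent of n."""
    rng = _rng(config, "baselines")
    repair = config.repair_genes.genes
    a_g = {g: v for g, v in zip(repair, rng.uniform(-2.0, 1.0, size=len(repair)))}
    mu_immune = {g: v for g, v in
                 zip(config.immune_genes,
                     rng.uniform(5.0, 12.0, size=len(config.immune_genes)))}
    mu_repair = {g: v for g, v in zip(repair, rng.uniform(5.0, 12.0, size=len(repair)))}
    return a_g, mu_immune, mu_repair


def _expr_from_log2(v: np.ndarray) -> np.ndarray:
    """Invert the log2(x+1) transform onto the raw RSEM-like scale."""
    return np.maximum(np.exp2(v) - 1.0, 0.0)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort from the latent-factor model; bit-reproducible from seed."""
    n = config.n_samples
    samples = [f"{config.name}-{i:04d}" for i in range(n)]
    repair = config.repair_genes.genes
    a_g, mu_immune, mu_repair = _baselines(config)

    latent = _rng(config, "latent").standard_normal(n)

    # methylation of every repair gene (rows later restricted to available)
    meth_rng = _rng(config, "meth")
    beta = np.empty((len(repair), n))
    for gi, gene in enumerate(repair):
        eta = meth_rng.normal(0.0, config.meth_noise_sd, size=n)
        c_g = float(config.latent_loading_meth.get(gene, 0.0))
        beta[gi] = expit(a_g[gene] + c_g * latent + eta)

    # immune-gene expression
    imm_rng = _rng(config, "expr_immune")
    expr_rows: dict[str, np.ndarray] = {}
    for gene in config.immune_genes:
        eps = imm_rng.normal(0.0, config.expr_noise_sd, size=n)
        v = mu_immune[gene] + config.expr_loading(gene) * latent + eps
        expr_rows[gene] = _expr_from_log2(v)

    # own-expression of repair genes, depressed by centered methylation
    rep_rng = _rng(config, "expr_repair")
    for gi, gene in enumerate(repair):
        eps = rep_rng.normal(0.0, config.expr_noise_sd, size=n)
        centered = beta[gi] - beta[gi].mean()
        v = mu_repair[gene] + config.own_gene_coupling * centered + eps
        expr_rows[gene] = _expr_from_log2(v)

    available = list(config.available_genes) if config.available_genes is not None else repair
    avail_idx = [repair.index(g) for g in available]
    meth = OmicsMatrix(
        kind="methylation",
        values=pd.DataFrame(beta[avail_idx], index=available, columns=samples),
    )
    expression = OmicsMatrix(
        kind="expression",
        values=pd.DataFrame(
            np.vstack([expr_rows[g] for g in expr_rows]),
            index=list(expr_rows),
            columns=samples,
        ),
    )

    mutations, mutated_per_sample, tp53 = _draw_mutations(config, samples)
    metadata = _draw_metadata(config, samples, mutated_per_sample, tp53)

    return Cohort(name=config.name, methylation=meth, expression=expression,
                  mutations=mutations, metadata=metadata)


def _draw_mutations(config: SimulationConfig, samples: list[str]):
    rng = _rng(config, "mutations")
    repair = config.repair_genes.genes
    rows = []
    counts = np.zeros(len(samples), dtype=int)
    tp53 = np.zeros(len(samples), dtype=int)
    for gene in repair:
        rate = config.tp53_mutation_rate if gene == "TP53" else config.mutation_rate
        hits = rng.random(len(samples)) < rate
        classes = rng.choice(VARIANT_CLASSES, size=len(samples))
        if gene == "TP53":
            tp53 = hits.astype(int)
        for si in np.flatnonzero(hits):
            rows.append((samples[si], gene, classes[si]))
            counts[si] += 1
    frame = pd.DataFrame(rows, columns=list(MutationTable.COLUMNS))
    return MutationTable(records=frame), counts, tp53


def _draw_metadata(config: SimulationConfig, samples: list[str],
                   repair_mut_counts: np.ndarray, tp53: np.ndarray) -> pd.DataFrame:
    rng = _rng(config, "metadata")
    # background mutational load outside the repair catalog, independent of L
    background = rng.poisson(80.0, size=len(samples))
    return pd.DataFrame(
        {
            "sample": samples,
            "tp53_mutant": tp53,
            "mutational_load": background + repair_mut_counts,
        }
    ).set_index("sample")


# ---------------------------------------------------------------------------
# oracles and calibration helpers
# ---------------------------------------------------------------------------


def expected_rho(config: SimulationConfig, gene: str, marker: str = "CD274",
                 n: int = 1_000_000, oracle_seed: int = 987_654_321) -> float:
    """Monte-Carlo estimate of the population Spearman correlation between a
    linked gene's methylation and a marker's expression under the model.

    Uses its own fixed-seed sample of the generative model at large ``n``;
    intended as a test oracle, not part of the pipeline.  Unlinked genes
    return 0 by construction (their methylation is independent of the
    latent factor, hence of every immune gene).
    """
    c_g = float(config.latent_loading_meth.get(gene, 0.0))
    if c_g == 0.0:
        return 0.0
    a_g, mu_immune, _ = _baselines(config)
    if gene not in a_g:
        raise KeyError(f"gene {gene!r} not in catalog")
    if marker not in mu_immune:
        raise KeyError(f"marker {marker!r} not an immune gene")
    rng = np.random.default_rng(oracle_seed)
    latent = rng.standard_normal(n)
    beta = expit(a_g[gene] + c_g * latent + rng.normal(0, config.meth_noise_sd, n))
    v = (mu_immune[marker] + config.expr_loading(marker) * latent
         + rng.normal(0, config.expr_noise_sd, n))
    expr = _expr_from_log2(v)
    return float(spearmanr(beta, expr).statistic)


def loading_for_target_rho(target_rho: float, meth_noise_sd: float = 1.0,
                           expr_loading: float = 1.0,
                           expr_noise_sd: float = 0.5) -> float:
    """Methylation loading c_g giving a desired population Spearman rho.

    Both methylation and expression are strictly monotone transforms of
    jointly Gaussian variables, so the population Spearman correlation is
    (6/pi) * arcsin(r/2) with r the Pearson correlation of the underlying
    Gaussians; inverting that relation yields the loading in closed form.
    """
    if not 0.0 < target_rho < 1.0:
        raise ValueError("target_rho must be in (0, 1)")
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    q = r * np.sqrt(expr_loading**2 + expr_noise_sd**2) / expr_loading
    if q >= 1.0:
        raise ValueError("target_rho unreachable at this noise level")
    return float(meth_noise_sd * q / np.sqrt(1.0 - q**2))


def write_cohort(cohort: Cohort, outdir: str | Path,
                 config: SimulationConfig | None = None) -> Path:
    """Write a cohort as the standard TSV bundle (plus config echo if given)."""
    from .io import write_matrix, write_mutations, _write_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.methylation, outdir / "methylation.tsv")
    write_matrix(cohort.expression, outdir / "expression.tsv")
    if cohort.mutations is not None:
        write_mutations(cohort.mutations, outdir / "mutations.tsv")
    if cohort.metadata is not None:
        _write_frame(cohort.metadata, outdir / "metadata.tsv", index_label="sample")
    if config is not None:
        write_run_summary(outdir / "config.json", config.to_jsonable())
    return outdir
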