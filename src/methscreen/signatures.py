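"""Inflammatory-signature, methylation-score and mutation-score analytics.

Per-sample quantities derived from a cohort and its candidate gene list:

* **IFNG signature score** S — mean over the six interferon-gamma
  inflammatory genes (IFNG, HLA-DRA, CXCL9, CXCL10, IDO1, STAT1) of
  log2(expression + 1).  This signature has been reported as predictive of
  PD-1 inhibitor response, which is what makes the methylation link
  clinically interesting.
* **binary methylation call** — per candidate gene, 1 iff the sample's beta
  value strictly exceeds that gene's cohort mean, 0 if at or below it.
* **methylation score** M — count of hypermethylated candidate genes.
* **mutation scores** U — count of genes (all repair genes, or candidates
  only) carrying at least one somatic mutation; per gene, not per record.
* **combined score** — M + U_all, the simple sum.
* **ROC AUC** — Mann-Whitney probability that the continuous IFNG score of
  a hypermethylated sample exceeds that of a non-hypermethylated one.

The aggregation transform ("mean of the six log2(x+1) values") and the ROC
orientation (continuous signature scored against the binary methylation
class) are deliberate, documented choices; ``log2(sum + 1)`` aggregation is
available behind the ``aggregate`` option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import Cohort, MutationTable, OmicsMatrix
from .screen import spearman
from .simulate import IFNG_SIGNATURE_GENES

__all__ = [
    "IFNG_SIGNATURE_GENES",
    "SignatureTable",
    "ifng_signature",
    "binarize_methylation",
    "methylation_score",
    "mutation_score",
    "score_vs_expression",
    "roc_auc",
    "dose_response",
    "build_signature_table",
]

logger = logging.getLogger(__name__)


def ifng_signature(expr: OmicsMatrix, genes: tuple[str, ...] = IFNG_SIGNATURE_GENES,
                   aggregate: str = "mean_log2") -> pd.Series:
    """Per-sample six-gene inflammatory signature score.

    ``mean_log2`` (default): S_i = (1/6) * sum_g log2(x_gi + 1).
    ``log2_sum``: S_i = log2(sum_g x_gi + 1), the alternative reading.
    Missing signature genes are a hard error naming the gene.
    """
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"signature gene(s) missing from expression matrix: {missing}")
    sub = expr.values.loc[list(genes)].to_numpy(dtype=float)
    if aggregate == "mean_log2":
        score = np.log2(sub + 1.0).mean(axis=0)
    elif aggregate == "log2_sum":
        score = np.log2(sub.sum(axis=0) + 1.0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return pd.Series(score, index=expr.values.columns, name="ifng_score")


def binarize_methylation(beta_row: pd.Series) -> pd.Series:
    """Call a gene hypermethylated (1) in samples where beta strictly
    exceeds the gene's mean over non-missing samples; at-or-below is 0 and
    missing stays missing."""
    values = beta_row.astype(float)
    observed = values.dropna()
    if observed.empty:
        raise ValueError(f"gene {beta_row.name!r}: all values missing")
    if len(observed) < 2:
        raise ValueError(f"gene {beta_row.name!r}: need >= 2 non-missing values")
    mean = observed.mean()
    out = (values > mean).astype(float)
    out[values.isna()] = np.nan
    return out


def methylation_score(binary_meth: pd.DataFrame) -> pd.Series:
    """Per-sample count of hypermethylated candidate genes.

    Missing calls contribute 0 (conservative under-count); the number of
    imputed zeros is logged.
    """
    n_missing = int(binary_meth.isna().to_numpy().sum())
    if n_missing:
        logger.info("methylation_score: %d missing calls treated as 0", n_missing)
    return binary_meth.fillna(0.0).sum(axis=0).astype(int).rename("meth_score")


def mutation_score(mutations: MutationTable, gene_set, samples) -> pd.Series:
    """Per-sample count of genes in ``gene_set`` with >= 1 mutation record.

    Deduplicated per gene: multiple records of the same gene in one sample
    count once.  Samples absent from the table score 0.
    """
    gene_set = set(gene_set)
    sub = mutations.records[mutations.records["gene"].isin(gene_set)]
    counts = sub.groupby("sample")["gene"].nunique()
    return counts.reindex(list(samples), fill_value=0).astype(int).rename("mut_score")


def score_vs_expression(score: pd.Series, expr_gene: pd.Series) -> tuple[float, float, int]:
    """Spearman correlation between a per-sample score and a gene's
    expression, on their shared samples."""
    shared = score.index.intersection(expr_gene.index)
    return spearman(score.loc[shared].to_numpy(dtype=float),
                    expr_gene.loc[shared].to_numpy(dtype=float))


def roc_auc(score, labels) -> float:
    """ROC area under the curve of a continuous score for a binary label.

    Computed as the Mann-Whitney statistic via mid-ranks:
    (number of (positive, negative) pairs with score_pos > score_neg, plus
    half the tied pairs) / (n_pos * n_neg).  Both classes must be present.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    if score.shape != labels.shape:
        raise ValueError("score and labels must align")
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(score)  # mid-ranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def dose_response(ifng_score: pd.Series, meth_score: pd.Series) -> tuple[pd.DataFrame, float, float]:
    """Mean signature score per methylation-score level, plus the Spearman
    trend of signature vs score.

    Returns ``(levels, trend_rho, trend_p)`` where ``levels`` has one row
    per observed methylation-score level with its sample count and mean
    signature score.
    """
    shared = ifng_score.index.intersection(meth_score.index)
    s = ifng_score.loc[shared]
    m = meth_score.loc[shared]
    levels = (
        pd.DataFrame({"meth_score": m, "ifng_score": s})
        .groupby("meth_score")["ifng_score"]
        .agg(n_samples="size", mean_ifng="mean")
        .reset_index()
    )
    rho, p, _ = spearman(m.to_numpy(dtype=float), s.to_numpy(dtype=float))
    return levels, rho, p


@dataclass
class SignatureTable:
    """Per-sample signature and score panel for one cohort."""

    cohort_name: str
    table: pd.DataFrame          # index: sample
    binary_meth: pd.DataFrame    # candidate gene x sample 0/1 calls
    candidate_genes: list[str]
    transforms: dict

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index().rename(columns={"index": "sample"})

    def summary(self) -> dict:
        return {
            "cohort": self.cohort_name,
            "n_samples": int(len(self.table)),
            "candidate_genes": list(self.candidate_genes),
            "transforms": self.transforms,
        }


def build_signature_table(cohort: Cohort, candidate_genes, all_repair_genes,
                          ifng_genes: tuple[str, ...] = IFNG_SIGNATURE_GENES,
                          aggregate: str = "mean_log2") -> SignatureTable:
    """Assemble the full per-sample panel on the cohort's shared samples.

    Columns: ifng_score, meth_score, mut_score_all, mut_score_candidates,
    combined_score (= meth_score + mut_score_all) and, when metadata carries
    it, mutational_load.  Mutation columns are NA when the cohort has no
    mutation table.
    """
    shared = cohort.shared_samples()
    candidate_genes = [g for g in candidate_genes]
    missing = [g for g in candidate_genes if g not in cohort.methylation.values.index]
    if missing:
        raise KeyError(f"candidate gene(s) without methylation data: {missing}")

    s = ifng_signature(cohort.expression, ifng_genes, aggregate).loc[shared]
    binary = pd.DataFrame(
        {g: binarize_methylation(cohort.methylation.values.loc[g, shared])
         for g in candidate_genes}
    ).T
    m = methylation_score(binary)

    table = pd.DataFrame(index=pd.Index(shared, name="sample"))
    table["ifng_score"] = s
    table["meth_score"] = m
    if cohort.mutations is not None:
        u_all = mutation_score(cohort.mutations, all_repair_genes, shared)
        u_cand = mutation_score(cohort.mutations, candidate_genes, shared)
        table["mut_score_all"] = u_all
        table["mut_score_candidates"] = u_cand
        table["combined_score"] = table["meth_score"] + table["mut_score_all"]
    else:
        table["mut_score_all"] = np.nan
        table["mut_score_candidates"] = np.nan
        table["combined_score"] = np.nan
    if cohort.metadata is not None and "mutational_load" in cohort.metadata.columns:
        table["mutational_load"] = cohort.metadata["mutational_load"].reindex(shared)

    return SignatureTable(
        cohort_name=cohort.name,
        table=table,
        binary_meth=binary,
        candidate_genes=candidate_genes,
        transforms={
            "ifng_aggregate": aggregate,
            "ifng_genes": list(ifng_genes),
            "binarization": "1 iff beta > gene mean over non-missing samples",
            "roc_orientation": "continuous IFNG score vs binary methylation label",
        },
    )
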