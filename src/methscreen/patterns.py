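"""Differential-methylation structure of the candidate genes.

Mirrors the descriptive analyses run on the candidate lists: per-gene
mean-centering of beta values (hypermethylated samples positive,
hypomethylated negative), agglomerative clustering of genes under a
1 - Pearson correlation distance with average linkage, gene-by-gene
covariance/correlation matrices, and a stratified two-group comparison
(e.g. TP53-mutant vs wild-type) with rank-sum tests Bonferroni-corrected
over genes.

Centering is within-cohort: "differential" means relative to the cohort
mean of the same gene, not relative to matched normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .io import OmicsMatrix
from .screen import bonferroni_adjust

__all__ = [
    "ClusterResult",
    "center_methylation",
    "cluster_genes",
    "methylation_association_matrix",
    "compare_groups",
]


def center_methylation(meth: OmicsMatrix, genes) -> pd.DataFrame:
    """Per-gene mean-centered beta values (row means subtracted).

    Positive entries are hypermethylated relative to the cohort, negative
    hypomethylated; every centered row sums to ~0.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in meth.values.index]
    if missing:
        raise KeyError(f"gene(s) missing from methylation matrix: {missing}")
    if meth.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to center")
    sub = meth.values.loc[genes].astype(float)
    return sub.sub(sub.mean(axis=1), axis=0)


@dataclass
class ClusterResult:
    """Deterministic agglomerative clustering of candidate genes."""

    gene_order: list[str]          # left-to-right leaf order of the tree
    linkage: np.ndarray            # scipy linkage matrix over sorted genes
    distance_metric: str
    centered_matrix: pd.DataFrame  # rows follow the sorted input gene order

    def leaf_genes(self) -> list[str]:
        return self.gene_order

    def cophenetic(self) -> pd.DataFrame:
        """Gene x gene cophenetic (merge-height) distances."""
        genes = list(self.centered_matrix.index)
        if len(genes) < 2:
            return pd.DataFrame(np.zeros((len(genes),) * 2), index=genes, columns=genes)
        coph = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(coph, index=genes, columns=genes)


def cluster_genes(centered: pd.DataFrame, metric: str = "pearson",
                  method: str = "average") -> ClusterResult:
    """Cluster genes on 1 - Pearson correlation with average linkage.

    Genes are sorted lexicographically before the linkage is computed, so
    ties in merge distance resolve by gene name and identical input always
    yields the identical tree regardless of row or sample order.
    """
    genes = sorted(centered.index)
    mat = centered.loc[genes].to_numpy(dtype=float)
    if len(genes) < 2:
        return ClusterResult(gene_order=genes, linkage=np.empty((0, 4)),
                             distance_metric=f"1-{metric}",
                             centered_matrix=centered.loc[genes])
    if metric == "pearson":
        corr = np.corrcoef(mat)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
        condensed = squareform(dist, checks=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(mat)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    linkage = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(linkage)
    return ClusterResult(
        gene_order=[genes[i] for i in order],
        linkage=linkage,
        distance_metric=f"1-{metric}" if metric == "pearson" else metric,
        centered_matrix=centered.loc[genes],
    )


def methylation_association_matrix(meth: OmicsMatrix, genes,
                                   kind: str = "correlation") -> pd.DataFrame:
    """Gene x gene covariance or Pearson correlation of beta values.

    Pairwise-complete over samples.  Zero-variance genes get NA rows and
    columns in the correlation matrix (their correlation is undefined);
    the covariance matrix keeps their zeros.
    """
    if kind not in ("covariance", "correlation"):
        raise ValueError("kind must be covariance|correlation")
    genes = list(genes)
    missing = [g for g in genes if g not in meth.values.index]
    if missing:
        raise KeyError(f"gene(s) missing from methylation matrix: {missing}")
    sub = meth.values.loc[genes].astype(float).T  # samples x genes
    if kind == "covariance":
        out = sub.cov()
    else:
        out = sub.corr(method="pearson")
        degenerate = sub.std(ddof=1) == 0
        for g in degenerate[degenerate].index:
            out.loc[g, :] = np.nan
            out.loc[:, g] = np.nan
    return out


def compare_groups(meth: OmicsMatrix, genes, labels: pd.Series,
                   min_group: int = 5) -> pd.DataFrame:
    """Per-gene methylation difference between two sample groups.

    ``labels`` is a 0/1 series over samples.  Returns delta_mean
    (group 1 minus group 0), the two-sided rank-sum p and its Bonferroni
    adjustment over the genes tested.  Both groups must have at least
    ``min_group`` samples.
    """
    genes = list(genes)
    labels = labels.dropna()
    g0 = labels.index[labels == 0]
    g1 = labels.index[labels == 1]
    if len(g0) < min_group or len(g1) < min_group:
        raise ValueError(
            f"need >= {min_group} samples per group, got {len(g0)} and {len(g1)}"
        )
    rows = []
    for gene in genes:
        row = meth.row(gene)
        a = row.reindex(g1).dropna().to_numpy(dtype=float)
        b = row.reindex(g0).dropna().to_numpy(dtype=float)
        delta = float(a.mean() - b.mean())
        if len(a) == len(b) and np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical group distributions: no evidence of a shift
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((gene, len(a), len(b), delta, p))
    frame = pd.DataFrame(rows, columns=["gene", "n_group1", "n_group0",
                                        "delta_mean", "p_raw"])
    m = len(frame)
    frame["p_bonferroni"] = [bonferroni_adjust(p, m) for p in frame["p_raw"]]
    return frame
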