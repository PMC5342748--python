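"""Methylation-vs-expression Spearman screen with Bonferroni control.

The screen correlates each DNA-repair gene's methylation beta values with
the mRNA expression of a marker gene (CD274/PD-L1 or CTLA4) across the
samples of a cohort.  Genes whose rank correlation exceeds a cutoff for
BOTH markers form the cohort's candidate list; the cutoff can either be
fixed (0.3 is the conventional choice) or calibrated so that a target
fraction of screened genes exceeds it.  Raw p-values are Bonferroni
corrected within each (cohort, marker) family; corrected significance is
reported alongside candidates but is not a membership criterion — cutoff
membership is decided by rho alone, strictly above the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, GeneCatalog

__all__ = [
    "MIN_PAIRS",
    "ScreenResult",
    "CandidateList",
    "spearman",
    "bonferroni_adjust",
    "run_screen",
    "calibrate_cutoff",
    "select_candidates",
    "cross_validate",
]

logger = logging.getLogger(__name__)

#: Minimum number of complete (methylation, expression) pairs for a gene to
#: enter a screen.  Rank correlations on fewer observations are noise.
MIN_PAIRS = 10


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rank correlation on the complete pairs of two vectors.

    Pairs with a missing value in either vector are dropped.  rho is the
    Pearson correlation of mid-ranks (ties get average ranks); the two-sided
    p-value uses the large-sample t approximation.  Returns
    ``(rho, p_raw, n_pairs)``; rho is NaN when fewer than :data:`MIN_PAIRS`
    complete pairs remain or either rank vector has zero variance — callers
    exclude such genes rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be index-aligned with equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    n = int(keep.sum())
    if n < MIN_PAIRS:
        return float("nan"), float("nan"), n
    xs, ys = x[keep], y[keep]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), float("nan"), n
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue), n


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Bonferroni correction: min(1, p * m)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw must lie in [0, 1], got {p_raw}")
    if m < 1:
        raise ValueError("family size m must be a positive integer")
    return min(1.0, p_raw * m)


@dataclass
class ScreenResult:
    """Per-gene Spearman statistics for one (cohort, marker) screen.

    ``rows`` has columns repair_gene / n_pairs / rho / p_raw / p_bonferroni,
    sorted by descending rho.  ``m_tests`` is the Bonferroni family size:
    the number of genes retained in this screen (152/153/158-style counts on
    the real cohorts), per marker.  Genes without methylation data or with
    too few pairs are listed in ``excluded`` by reason.
    """

    cohort_name: str
    marker_gene: str
    rows: pd.DataFrame
    m_tests: int
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = ["repair_gene", "n_pairs", "rho", "p_raw", "p_bonferroni"]
        if list(self.rows.columns) != expected:
            raise ValueError(f"rows must have columns {expected}")
        if len(self.rows) and (self.rows["n_pairs"] < MIN_PAIRS).any():
            raise ValueError(f"all retained rows need n_pairs >= {MIN_PAIRS}")

    def rho_of(self, gene: str) -> float:
        sub = self.rows[self.rows["repair_gene"] == gene]
        return float(sub["rho"].iloc[0]) if len(sub) else float("nan")

    def hits(self, cutoff: float) -> set[str]:
        """Genes with rho strictly above the cutoff."""
        return set(self.rows.loc[self.rows["rho"] > cutoff, "repair_gene"])

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def summary(self) -> dict:
        return {
            "cohort": self.cohort_name,
            "marker": self.marker_gene,
            "m_tests": self.m_tests,
            "n_rows": int(len(self.rows)),
            "excluded": {k: sorted(v) for k, v in self.excluded.items()},
        }


def run_screen(cohort: Cohort, catalog: GeneCatalog, marker: str) -> ScreenResult:
    """Correlate every catalog gene's methylation with a marker's expression.

    One row per catalog gene with usable data; the Bonferroni family size is
    the number of retained rows.  Genes absent from the methylation matrix
    are recorded as ``no_data`` (mirroring the incomplete HM450 coverage of
    real cohorts); genes with fewer than :data:`MIN_PAIRS` complete pairs or
    tied-constant values are recorded as ``insufficient`` / ``degenerate``.
    """
    if marker not in cohort.expression.values.index:
        raise KeyError(f"marker {marker!r} absent from expression matrix of "
                       f"cohort {cohort.name!r}")
    shared = cohort.shared_samples()
    marker_expr = cohort.expression.values.loc[marker, shared].to_numpy(dtype=float)
    meth = cohort.methylation.values

    excluded: dict[str, list[str]] = {"no_data": [], "insufficient": [], "degenerate": []}
    records = []
    for gene in catalog.genes:
        if gene not in meth.index:
            excluded["no_data"].append(gene)
            continue
        beta = meth.loc[gene, shared].to_numpy(dtype=float)
        rho, p_raw, n_pairs = spearman(beta, marker_expr)
        if np.isnan(rho):
            reason = "insufficient" if n_pairs < MIN_PAIRS else "degenerate"
            excluded[reason].append(gene)
            continue
        records.append((gene, n_pairs, rho, p_raw))

    m = len(records)
    if m == 0:
        logger.warning("screen %s/%s retained no genes", cohort.name, marker)
    rows = pd.DataFrame(records, columns=["repair_gene", "n_pairs", "rho", "p_raw"])
    rows["p_bonferroni"] = [bonferroni_adjust(p, m) for p in rows["p_raw"]] if m else []
    rows = rows.sort_values("rho", ascending=False, kind="mergesort").reset_index(drop=True)
    for reason, genes in excluded.items():
        if genes:
            logger.info("screen %s/%s excluded %d genes (%s)",
                        cohort.name, marker, len(genes), reason)
    return ScreenResult(cohort_name=cohort.name, marker_gene=marker,
                        rows=rows, m_tests=m, excluded=excluded)


def calibrate_cutoff(result: ScreenResult, fraction: float) -> float:
    """Smallest cutoff on the observed-rho midpoint grid such that at most
    ``fraction`` of screened genes exceed it.

    The candidate grid is: one point below the minimum rho, the midpoints
    between consecutive distinct rho values, and the maximum rho itself.
    With fraction 0.10 on a 152-gene screen, at most 15 genes exceed the
    returned cutoff.  If all rho values are equal no cutoff separates them;
    the common value is returned (zero genes strictly exceed it) with a
    warning.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rhos = result.rows["rho"].to_numpy(dtype=float)
    if rhos.size == 0:
        raise ValueError("cannot calibrate a cutoff on an empty screen")
    distinct = np.unique(rhos)  # ascending
    if distinct.size == 1:
        logger.warning("all rho values equal (%.4f); no cutoff separates them",
                       distinct[0])
        return float(distinct[0])
    grid = np.concatenate((
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1]],
    ))
    n = rhos.size
    for c in grid:
        if (rhos > c).sum() / n <= fraction:
            return float(c)
    return float(grid[-1])  # unreachable: max rho always qualifies


@dataclass
class CandidateList:
    """Repair genes exceeding the cutoff for BOTH markers in one cohort."""

    cohort_name: str
    cutoff: float
    genes: list[str]
    per_marker_hits: dict[str, set]
    significance: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        inter = set.intersection(*self.per_marker_hits.values()) \
            if self.per_marker_hits else set()
        if set(self.genes) != inter:
            raise ValueError("genes must equal the intersection of per-marker hits")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        markers = sorted(self.per_marker_hits)
        rows = []
        for gene in self.genes:
            row: dict = {"gene": gene}
            for m in markers:
                row[f"p_bonferroni_{m}"] = self.significance.get((gene, m), float("nan"))
            rows.append(row)
        cols = ["gene"] + [f"p_bonferroni_{m}" for m in markers]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> dict:
        return {
            "cohort": self.cohort_name,
            "cutoff": self.cutoff,
            "n_candidates": len(self.genes),
            "per_marker_hits": {m: sorted(g) for m, g in self.per_marker_hits.items()},
        }


def select_candidates(screen_a: ScreenResult, screen_b: ScreenResult,
                      cutoff: float) -> CandidateList:
    """Intersect the two markers' hit sets (rho strictly above cutoff).

    Candidate order follows descending rho in the first screen.  Bonferroni
    p-values for both markers are carried in the significance map but do not
    gate membership.
    """
    if screen_a.cohort_name != screen_b.cohort_name:
        raise ValueError(
            f"screens come from different cohorts: "
            f"{screen_a.cohort_name!r} vs {screen_b.cohort_name!r}"
        )
    hits = {screen_a.marker_gene: screen_a.hits(cutoff),
            screen_b.marker_gene: screen_b.hits(cutoff)}
    inter = hits[screen_a.marker_gene] & hits[screen_b.marker_gene]
    ordered = [g for g in screen_a.rows["repair_gene"] if g in inter]
    significance: dict[tuple[str, str], float] = {}
    for scr in (screen_a, screen_b):
        sub = scr.rows.set_index("repair_gene")["p_bonferroni"]
        for gene in ordered:
            significance[(gene, scr.marker_gene)] = float(sub[gene])
    return CandidateList(cohort_name=screen_a.cohort_name, cutoff=cutoff,
                         genes=ordered, per_marker_hits=hits,
                         significance=significance)


def cross_validate(candidates: CandidateList, cohorts: Iterable[Cohort],
                   catalog: GeneCatalog,
                   markers: tuple[str, str] = ("CD274", "CTLA4")) -> pd.DataFrame:
    """Re-screen a candidate list in other cohorts.

    Returns a gene × (cohort, marker) table of rho values; genes without
    usable data in a cohort are NA, never zero.  The boolean column
    ``all_positive`` flags genes with rho > 0 in every tested association —
    the cross-cohort consistency criterion used to nominate genes shared
    between squamous histologies.
    """
    cohorts = list(cohorts)
    columns: dict[str, pd.Series] = {}
    for cohort in cohorts:
        for marker in markers:
            scr = run_screen(cohort, catalog.subset(candidates.genes), marker)
            rho = scr.rows.set_index("repair_gene")["rho"]
            columns[f"{cohort.name}:{marker}"] = rho.reindex(candidates.genes)
    table = pd.DataFrame(columns, index=pd.Index(candidates.genes, name="gene"))
    table["all_positive"] = (table > 0).all(axis=1) & table.notna().all(axis=1)
    return table
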