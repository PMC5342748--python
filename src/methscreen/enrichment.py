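"""Repair-pathway enrichment of a candidate list (one-sided Fisher test).

The question: among the N repair genes screened in a cohort (the
background), K belong to a mechanistic pathway group; of the n candidate
genes, k are in that group.  Is k larger than the hypergeometric draw would
predict?  The one-sided Fisher exact p-value is the upper tail
P(X >= k) with X ~ Hypergeometric(N, K, n).

As published, only the group with the highest relative candidate proportion
is formally tested ("headline" group).  Selecting the maximum before
testing inflates the type-I error of that single p-value; an optional
Bonferroni-over-groups correction is available for selection-adjusted
inference, but the default reproduces the published procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io import GeneCatalog
from .screen import CandidateList, ScreenResult

__all__ = ["EnrichmentResult", "hypergeom_tail", "enrich", "expand_for_small_lists"]

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Equals the one-sided Fisher exact p of the 2x2 table
    [[k, n-k], [K-k, N-n-(K-k)]].  Evaluated through log-space survival
    probabilities, so it stays finite and accurate up to N ~ 1e4.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k}, n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """One pathway group's 2x2 contingency summary and test."""

    pathway: str
    k: int          # pathway genes among candidates
    n: int          # candidate count
    K: int          # pathway genes in background
    N: int          # background size (repair genes with usable data)
    odds_ratio: float
    p_one_sided: float
    headline: bool = False

    @property
    def pct_candidates(self) -> float:
        return 100.0 * self.k / self.n if self.n else float("nan")

    @property
    def pct_background(self) -> float:
        return 100.0 * self.K / self.N if self.N else float("nan")

    def table(self) -> list[list[int]]:
        return [[self.k, self.n - self.k],
                [self.K - self.k, self.N - self.n - (self.K - self.k)]]


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b = k, n - k
    c, d = K - k, N - n - (K - k)
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


@dataclass
class EnrichmentReport:
    """All per-group results for one candidate list, sorted by p."""

    cohort_name: str
    results: list[EnrichmentResult]
    adjusted_over_groups: bool = False

    def headline(self) -> EnrichmentResult | None:
        for r in self.results:
            if r.headline:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway": r.pathway,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "pct_candidates": r.pct_candidates,
                "pct_background": r.pct_background,
                "odds_ratio": r.odds_ratio,
                "p_one_sided": r.p_one_sided,
                "headline": int(r.headline),
            }
            for r in self.results
        ]
        cols = ["pathway", "k", "n", "K", "N", "pct_candidates", "pct_background",
                "odds_ratio", "p_one_sided", "headline"]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> dict:
        head = self.headline()
        return {
            "cohort": self.cohort_name,
            "n_groups": len(self.results),
            "adjusted_over_groups": self.adjusted_over_groups,
            "headline_pathway": head.pathway if head else None,
            "headline_p": head.p_one_sided if head else None,
        }


def enrich(candidates: CandidateList | list[str], catalog: GeneCatalog,
           background: set[str] | list[str],
           adjust_over_groups: bool = False,
           cohort_name: str | None = None) -> EnrichmentReport:
    """Test each pathway group for over-representation among candidates.

    ``background`` is the set of repair genes with usable data in the
    cohort; candidates must be a subset of it and are counted inside the
    background (the only reading under which a 12.5% homologous-
    recombination share of a 152-gene background is the integer 19).  The
    group with the highest relative candidate proportion is flagged as the
    headline test.  With ``adjust_over_groups`` the p-values are Bonferroni
    multiplied by the number of groups tested.
    """
    if isinstance(candidates, CandidateList):
        cohort_name = cohort_name or candidates.cohort_name
        cand = list(candidates.genes)
    else:
        cand = list(candidates)
        cohort_name = cohort_name or "unnamed"
    bg = set(background)
    stray = set(cand) - bg
    if stray:
        raise ValueError(f"candidates outside background: {sorted(stray)}")
    stray = bg - set(catalog.genes)
    if stray:
        raise ValueError(f"background genes outside catalog: {sorted(stray)}")
    if not cand:
        logger.warning("empty candidate list for %s; nothing to enrich", cohort_name)
        return EnrichmentReport(cohort_name=cohort_name, results=[])

    N, n = len(bg), len(cand)
    results = []
    for label in catalog.group_labels():
        members = set(catalog.genes_in_group(label))
        K = len(members & bg)
        if K == 0:
            continue
        k = len(members & set(cand))
        p = hypergeom_tail(k, n, K, N)
        if adjust_over_groups:
            p = min(1.0, p * len(catalog.group_labels()))
        results.append(EnrichmentResult(
            pathway=label, k=k, n=n, K=K, N=N,
            odds_ratio=_odds_ratio(k, n, K, N), p_one_sided=p,
        ))
    # headline: highest candidate share relative to background share
    best = max(results, key=lambda r: (r.pct_candidates - r.pct_background, r.pathway))
    best.headline = True
    results.sort(key=lambda r: (r.p_one_sided, r.pathway))
    return EnrichmentReport(cohort_name=cohort_name, results=results,
                            adjusted_over_groups=adjust_over_groups)


def expand_for_small_lists(screen_a: ScreenResult, screen_b: ScreenResult,
                           cutoff: float) -> set[str]:
    """Union of the two markers' hit sets.

    The fallback gene set when a cohort's both-marker candidate list is too
    small for a meaningful enrichment test: every gene correlated with
    EITHER marker above the cutoff is included.
    """
    if screen_a.cohort_name != screen_b.cohort_name:
        raise ValueError("screens come from different cohorts")
    return screen_a.hits(cutoff) | screen_b.hits(cutoff)
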