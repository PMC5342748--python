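"""Spearman screen, cutoff calibration, candidate selection, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methscreen as ms
from methscreen.screen import MIN_PAIRS, ScreenResult, calibrate_cutoff

from conftest import random_matrix


def midrank_spearman_oracle(x, y):
    """Independent construction: explicit mid-ranks + Pearson on the ranks,
    p from the t approximation."""
    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(rx)
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, min(1.0, p)


class TestSpearman:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
         [10, 20, 30, 40, 50, 60, 70, 80, 90, 100], 1.0),
        ([1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
         [10, 9, 8, 7, 6, 5, 4, 3, 2, 1], -1.0),
    ])
    def test_monotone_identity_and_reversal(self, x, y, expected):
        rho, _, n = ms.spearman(np.array(x, float), np.array(y, float))
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == len(x)

    def test_classic_five_point_example(self):
        """Untied ranks with sum of squared rank differences 4:
        rho = 1 - 6*4/(5*24) = 0.8 (checked below MIN_PAIRS via raw scipy
        and via the screen entry point on a padded vector)."""
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        assert stats.spearmanr(x, y).statistic == pytest.approx(0.8, abs=1e-12)
        oracle_rho, _ = midrank_spearman_oracle(x, y)
        assert oracle_rho == pytest.approx(0.8, abs=1e-12)

    def test_matches_midrank_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(MIN_PAIRS, 40))
            x = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n) + x
            rho, p, _ = ms.spearman(x, y)
            if np.isnan(rho):
                continue
            orho, op = midrank_spearman_oracle(x, y)
            assert rho == pytest.approx(orho, abs=1e-12)
            assert p == pytest.approx(op, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda v: v**3])
    def test_invariant_under_strictly_monotone_transforms(self, rng, transform):
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        rho0, _, _ = ms.spearman(x, y)
        rho1, _, _ = ms.spearman(transform(x), y)
        rho2, _, _ = ms.spearman(x, transform(y))
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert rho2 == pytest.approx(rho0, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, np.nan], float)
        y = np.array([np.nan, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], float)
        rho, _, n = ms.spearman(x, y)
        assert n == 9
        assert np.isnan(rho)  # 9 < MIN_PAIRS: excluded, not an exception

    def test_zero_rank_variance_excluded(self):
        x = np.ones(20)
        y = np.arange(20, dtype=float)
        rho, _, n = ms.spearman(x, y)
        assert np.isnan(rho) and n == 20


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 152, 1.0),
        (1e-5, 152, 1.52e-3),
        (0.0, 152, 0.0),
    ])
    def test_adjustment(self, p, m, expected):
        assert ms.bonferroni_adjust(p, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ms.bonferroni_adjust(1.5, 10)
        with pytest.raises(ValueError):
            ms.bonferroni_adjust(0.1, 0)


class TestRunScreen:
    def test_planted_genes_take_top_ranks(self, tiny, catalog):
        config, cohort = tiny
        res = ms.run_screen(cohort, config.repair_genes, "CD274")
        top = list(res.rows["repair_gene"].head(len(config.linked_genes)))
        assert set(top) == set(config.linked_genes)

    def test_rows_sorted_and_bonferroni_consistent(self, tiny, catalog):
        config, cohort = tiny
        res = ms.run_screen(cohort, config.repair_genes, "CTLA4")
        rho = res.rows["rho"].to_numpy()
        assert (np.diff(rho) <= 0).all()
        expected = np.minimum(1.0, res.rows["p_raw"] * res.m_tests)
        np.testing.assert_allclose(res.rows["p_bonferroni"], expected, rtol=0, atol=0)

    def test_gene_availability_reported_not_dropped_silently(self, hnsc_like, catalog):
        """27 of 179 catalog genes lack methylation data: 152 rows retained
        and the 27 unmeasured genes listed as no_data."""
        _, cohort = hnsc_like
        res = ms.run_screen(cohort, catalog, "CD274")
        assert res.m_tests == 152
        assert len(res.rows) == 152
        assert len(res.excluded["no_data"]) == 27

    def test_absent_marker_is_hard_error(self, tiny, catalog):
        config, cohort = tiny
        with pytest.raises(KeyError, match="NOT_A_MARKER"):
            ms.run_screen(cohort, config.repair_genes, "NOT_A_MARKER")

    def test_constant_methylation_yields_empty_screen(self, tiny, catalog):
        config, cohort = tiny
        frame = cohort.methylation.values.copy()
        frame.loc[:, :] = 0.5
        degenerate = ms.Cohort(
            name=cohort.name,
            methylation=ms.OmicsMatrix(kind="methylation", values=frame),
            expression=cohort.expression)
        res = ms.run_screen(degenerate, config.repair_genes, "CD274")
        assert len(res.rows) == 0
        assert set(res.excluded["degenerate"]) == set(frame.index)


def make_screen(rhos, cohort="X", marker="CD274", n=30):
    rows = pd.DataFrame({
        "repair_gene": [f"G{i}" for i in range(len(rhos))],
        "n_pairs": n,
        "rho": rhos,
        "p_raw": np.linspace(0.001, 0.5, len(rhos)),
    })
    rows["p_bonferroni"] = np.minimum(1.0, rows["p_raw"] * len(rhos))
    rows = rows.sort_values("rho", ascending=False).reset_index(drop=True)
    return ScreenResult(cohort_name=cohort, marker_gene=marker,
                        rows=rows, m_tests=len(rhos))


class TestCalibrateCutoff:
    def test_ten_value_example(self):
        rhos = [0.5, 0.4, 0.3, 0.2, 0.1, 0.0, -0.1, -0.2, -0.3, -0.4]
        cutoff = calibrate_cutoff(make_screen(rhos), fraction=0.1)
        assert 0.4 < cutoff < 0.5
        assert sum(r > cutoff for r in rhos) == 1

    def test_fraction_one_passes_everything(self):
        rhos = [0.5, 0.2, -0.1]
        cutoff = calibrate_cutoff(make_screen(rhos), fraction=1.0)
        assert cutoff < min(rhos)

    def test_all_equal_returns_common_value(self):
        cutoff = calibrate_cutoff(make_screen([0.3] * 5), fraction=0.1)
        assert cutoff == 0.3

    def test_matches_exhaustive_midpoint_oracle(self, rng):
        for _ in range(50):
            rhos = np.round(rng.uniform(-1, 1, size=int(rng.integers(2, 30))), 2)
            fraction = float(rng.uniform(0.05, 0.9))
            result = calibrate_cutoff(make_screen(list(rhos)), fraction)
            distinct = np.unique(rhos)
            grid = np.concatenate(([distinct[0] - 1.0],
                                   (distinct[:-1] + distinct[1:]) / 2,
                                   [distinct[-1]]))
            feasible = [c for c in grid if (rhos > c).mean() <= fraction]
            assert result == pytest.approx(min(feasible), abs=1e-15)

    def test_ten_percent_of_152_is_at_most_15(self, rng):
        rhos = rng.uniform(-0.5, 0.8, size=152)
        cutoff = calibrate_cutoff(make_screen(list(rhos)), fraction=0.10)
        assert (rhos > cutoff).sum() <= 15


class TestSelectCandidates:
    def test_intersection_of_hit_sets(self):
        a = make_screen([0.9, 0.8, 0.7, 0.1])          # hits G0,G1,G2
        b = make_screen([0.1, 0.8, 0.7, 0.9], marker="CTLA4")
        cand = ms.select_candidates(a, b, cutoff=0.3)
        assert set(cand.genes) == {"G1", "G2", "G3"} & {"G0", "G1", "G2"}

    def test_cutoff_above_max_gives_valid_empty_list(self):
        a = make_screen([0.2, 0.1])
        b = make_screen([0.2, 0.1], marker="CTLA4")
        cand = ms.select_candidates(a, b, cutoff=0.5)
        assert len(cand) == 0

    def test_cohort_mismatch_is_hard_error(self):
        a = make_screen([0.5], cohort="A")
        b = make_screen([0.5], cohort="B", marker="CTLA4")
        with pytest.raises(ValueError, match="different cohorts"):
            ms.select_candidates(a, b, 0.3)

    def test_strict_inequality_at_cutoff(self):
        a = make_screen([0.3, 0.31])
        b = make_screen([0.3, 0.31], marker="CTLA4")
        cand = ms.select_candidates(a, b, cutoff=0.3)
        assert cand.genes == ["G1"]  # rho == cutoff is not a hit

    def test_candidates_subset_of_both_hit_sets(self, rng):
        for _ in range(25):
            k = int(rng.integers(3, 20))
            a = make_screen(list(rng.uniform(-1, 1, k)))
            b = make_screen(list(rng.uniform(-1, 1, k)), marker="CTLA4")
            cutoff = float(rng.uniform(-0.5, 0.8))
            cand = ms.select_candidates(a, b, cutoff)
            assert set(cand.genes) <= a.hits(cutoff)
            assert set(cand.genes) <= b.hits(cutoff)
            for gene in cand.genes:
                assert a.rho_of(gene) > cutoff and b.rho_of(gene) > cutoff

    def test_significance_carried_but_not_gating(self, tiny):
        config, cohort = tiny
        a = ms.run_screen(cohort, config.repair_genes, "CD274")
        b = ms.run_screen(cohort, config.repair_genes, "CTLA4")
        cand = ms.select_candidates(a, b, 0.3)
        for gene in cand.genes:
            assert (gene, "CD274") in cand.significance
            assert (gene, "CTLA4") in cand.significance


class TestCrossValidate:
    def test_source_cohort_reproduces_source_rhos(self, tiny, catalog):
        config, cohort = tiny
        a = ms.run_screen(cohort, config.repair_genes, "CD274")
        b = ms.run_screen(cohort, config.repair_genes, "CTLA4")
        cand = ms.select_candidates(a, b, 0.3)
        table = ms.cross_validate(cand, [cohort], config.repair_genes)
        for gene in cand.genes:
            assert table.loc[gene, f"{cohort.name}:CD274"] == pytest.approx(
                a.rho_of(gene), abs=1e-12)

    def test_shared_planted_genes_flagged_all_positive(self, catalog):
        import dataclasses
        from methscreen.pipeline import tiny_config
        config = tiny_config(2, catalog)
        config = dataclasses.replace(config, n_samples=120)
        other = dataclasses.replace(config, name="OTHER", seed=999)
        source, validation = ms.generate_cohort(config), ms.generate_cohort(other)
        a = ms.run_screen(source, config.repair_genes, "CD274")
        b = ms.run_screen(source, config.repair_genes, "CTLA4")
        cand = ms.select_candidates(a, b, 0.3)
        planted = set(config.linked_genes) & set(cand.genes)
        assert planted, "fixture must recover at least one planted gene"
        table = ms.cross_validate(cand, [validation], config.repair_genes)
        assert table.loc[sorted(planted), "all_positive"].all()

    def test_missing_gene_reported_na_not_zero(self, tiny, catalog):
        config, cohort = tiny
        a = ms.run_screen(cohort, config.repair_genes, "CD274")
        b = ms.run_screen(cohort, config.repair_genes, "CTLA4")
        cand = ms.select_candidates(a, b, 0.3)
        # validation cohort lacking the first candidate's methylation row
        frame = cohort.methylation.values.drop(index=cand.genes[0])
        reduced = ms.Cohort(name="REDUCED",
                            methylation=ms.OmicsMatrix("methylation", frame),
                            expression=cohort.expression)
        table = ms.cross_validate(cand, [reduced], config.repair_genes)
        assert np.isnan(table.loc[cand.genes[0], "REDUCED:CD274"])
        assert not table.loc[cand.genes[0], "all_positive"]


def test_no_relevant_negative_correlations_among_null_genes(hnsc_like, catalog):
    """Unlinked genes essentially never reach rho < -0.3 at n=278."""
    config, cohort = hnsc_like
    res = ms.run_screen(cohort, catalog, "CD274")
    null_rows = res.rows[~res.rows["repair_gene"].isin(config.linked_genes)]
    frac = (null_rows["rho"] < -0.3).mean()
    assert frac <= 0.01
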