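"""Expression-matched background scoring: bins, backgrounds, p-values, rank score."""

import numpy as np
import pandas as pd
import pytest

from ithkit import (
    ExpressionMatrix,
    ScoringConfig,
    ValidationError,
    build_expression_bins,
    rank_signature_score,
    relative_score,
    sample_background_sets,
    score_cells,
    score_program,
)


class TestBins:
    def test_equal_bins_by_rank(self, rng):
        values = np.arange(30, dtype=float).reshape(30, 1) * np.ones((30, 4))
        m = ExpressionMatrix(values, [f"g{i:02d}" for i in range(30)],
                             [f"c{j}" for j in range(4)], ["s"] * 4)
        bins = build_expression_bins(m, n_bins=3)
        sizes = pd.Series(bins).value_counts()
        assert sorted(sizes) == [10, 10, 10]
        # lowest-expression genes in bin 0, highest in bin 2
        assert bins["g00"] == 0 and bins["g29"] == 2

    def test_ties_split_deterministically_by_gene_id(self):
        m = ExpressionMatrix(np.ones((6, 2)), [f"g{i}" for i in range(6)],
                             ["c1", "c2"], ["s"] * 2)
        b1 = build_expression_bins(m, 2)
        b2 = build_expression_bins(m, 2)
        assert b1 == b2
        assert [b1[f"g{i}"] for i in range(6)] == [0, 0, 0, 1, 1, 1]

    def test_bin_ranges_ordered(self, random_matrix):
        bins = build_expression_bins(random_matrix, 5)
        means = random_matrix.values.mean(axis=1)
        by_bin = {}
        for g, b in bins.items():
            by_bin.setdefault(b, []).append(means[random_matrix.gene_ids.index(g)])
        for b in range(3):
            # non-adjacent bins have disjoint mean-expression ranges
            assert max(by_bin[b]) <= min(by_bin[b + 2])

    def test_too_many_bins(self, random_matrix):
        with pytest.raises(ValidationError):
            build_expression_bins(random_matrix, random_matrix.n_genes + 1)


class TestBackgrounds:
    def test_size_and_count(self, random_matrix):
        bins = build_expression_bins(random_matrix, 4)
        sig = random_matrix.gene_ids[:7]
        cfg = ScoringConfig(n_background_sets=25, n_bins=4, seed=0)
        bgs = sample_background_sets(sig, bins, cfg)
        assert len(bgs) == 25
        assert all(len(b) == 7 for b in bgs)

    def test_draws_come_from_matching_bins(self, random_matrix):
        bins = build_expression_bins(random_matrix, 4)
        sig = random_matrix.gene_ids[:5]
        bgs = sample_background_sets(sig, bins, ScoringConfig(n_background_sets=50, n_bins=4))
        for bg in bgs:
            for sig_gene, bg_gene in zip(sig, bg):
                assert bins[bg_gene] == bins[sig_gene]

    def test_single_bin_is_uniform_over_all_genes(self, random_matrix):
        bins = {g: 0 for g in random_matrix.gene_ids}
        bgs = sample_background_sets(
            random_matrix.gene_ids[:3], bins,
            ScoringConfig(n_background_sets=300, n_bins=2, seed=1),
        )
        drawn = {g for bg in bgs for g in bg}
        assert len(drawn) > 0.8 * random_matrix.n_genes

    def test_seeded_reproducibility(self, random_matrix):
        bins = build_expression_bins(random_matrix, 4)
        cfg = ScoringConfig(n_background_sets=20, n_bins=4, seed=42)
        assert sample_background_sets(random_matrix.gene_ids[:4], bins, cfg) == \
            sample_background_sets(random_matrix.gene_ids[:4], bins, cfg)

    def test_missing_gene_listed(self, random_matrix):
        bins = build_expression_bins(random_matrix, 4)
        with pytest.raises(ValidationError, match="NOT_A_GENE"):
            sample_background_sets(["NOT_A_GENE"], bins, ScoringConfig())


class TestScoreCells:
    def _matrix(self, rng, n_genes=40, n_cells=10):
        return ExpressionMatrix(
            rng.lognormal(0, 1, size=(n_genes, n_cells)),
            [f"g{i:02d}" for i in range(n_genes)],
            [f"c{j:02d}" for j in range(n_cells)],
            ["s"] * n_cells,
        )

    def test_p_values_match_brute_force_recount(self, rng):
        m = self._matrix(rng)
        sig = m.gene_ids[:6]
        bins = build_expression_bins(m, 4)
        cfg = ScoringConfig(n_background_sets=20, n_bins=4, seed=3)
        bgs = sample_background_sets(sig, bins, cfg)
        out = score_cells(m, sig, bgs, cfg)

        centered = m.values - m.values.mean(axis=1, keepdims=True)
        gi = {g: i for i, g in enumerate(m.gene_ids)}
        for j, cell in enumerate(m.cell_ids):
            m_sig = np.mean([centered[gi[g], j] for g in sig])
            count = sum(
                np.mean([centered[gi[g], j] for g in bg]) >= m_sig for bg in bgs
            )
            expected_p = (count + 1) / (len(bgs) + 1)
            assert out.loc[out.cell_id == cell, "p_value"].item() == pytest.approx(expected_p)

    def test_extreme_cell_attains_score_one(self, rng):
        m = self._matrix(rng, n_genes=30, n_cells=8)
        # cell 0 wildly overexpresses the signature; backgrounds drawn from
        # other genes, so its signature mean beats every background mean
        m.values[:5, 0] *= 100
        sig = m.gene_ids[:5]
        bgs = [list(rng.choice(m.gene_ids[5:], size=5, replace=False)) for _ in range(50)]
        cfg = ScoringConfig(n_background_sets=50, n_bins=3, seed=0)
        out = score_cells(m, sig, bgs, cfg)
        best = out.loc[out.cell_id == "c00"]
        assert best["p_value"].item() == pytest.approx(1 / 51)
        assert best["score"].item() == 1.0

    def test_scores_span_unit_interval(self, rng):
        m = self._matrix(rng, n_genes=50, n_cells=40)
        out = score_program(m, m.gene_ids[:8], ScoringConfig(n_background_sets=30, n_bins=5))
        assert out["score"].min() == 0.0
        assert out["score"].max() == 1.0
        assert out["score"].between(0, 1).all()

    def test_monotone_in_signature_expression(self, rng):
        """Raising one cell's signature expression never lowers its p-derived rank."""
        m = self._matrix(rng, n_genes=30, n_cells=12)
        sig = m.gene_ids[:5]
        cfg = ScoringConfig(n_background_sets=40, n_bins=3, seed=2)
        bins = build_expression_bins(m, 3)
        bgs = sample_background_sets(sig, bins, cfg)
        before = score_cells(m, sig, bgs, cfg)
        boosted = self._matrix(np.random.default_rng(0), 30, 12)
        boosted.values[:, :] = m.values
        boosted.values[:5, 3] += 5.0
        after = score_cells(boosted, sig, bgs, cfg)
        rank_before = before["p_value"].rank().iloc[3]
        rank_after = after["p_value"].rank().iloc[3]
        assert rank_after <= rank_before

    def test_null_p_values_roughly_uniform(self, rng):
        m = self._matrix(rng, n_genes=200, n_cells=150)
        sig = list(rng.choice(m.gene_ids, size=10, replace=False))
        out = score_program(m, sig, ScoringConfig(n_background_sets=100, n_bins=10, seed=8))
        from scipy.stats import kstest
        assert kstest(out["p_value"], "uniform").statistic < 0.15


class TestRelativeScore:
    def _scores(self, cells, vals):
        return pd.DataFrame({"cell_id": cells, "score": vals})

    def test_difference(self):
        rel = relative_score(self._scores(["a", "b"], [1.0, 0.25]),
                             self._scores(["a", "b"], [0.0, 0.25]))
        assert rel["a"] == 1.0 and rel["b"] == 0.0

    def test_cell_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            relative_score(self._scores(["a"], [1.0]), self._scores(["b"], [1.0]))


class TestRankSignatureScore:
    def test_all_genes_gives_half(self, rng):
        expr = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        assert rank_signature_score(expr, list(expr.index)) == pytest.approx(0.5)

    def test_top_gene_of_ten(self):
        expr = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        assert rank_signature_score(expr, ["g9"]) == pytest.approx(0.95)

    def test_matches_brute_force(self, rng):
        expr = pd.Series(rng.normal(size=100), index=[f"g{i:03d}" for i in range(100)])
        sig = list(rng.choice(expr.index, size=10, replace=False))
        # brute force: percentile (rank - 0.5)/G with average ranks
        ranks = expr.rank(method="average")
        expected = float(((ranks[sig] - 0.5) / len(expr)).mean())
        assert rank_signature_score(expr, sig) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_monotone_transform(self, rng):
        expr = pd.Series(rng.lognormal(size=50), index=[f"g{i:02d}" for i in range(50)])
        sig = list(expr.index[:7])
        s1 = rank_signature_score(expr, sig)
        s2 = rank_signature_score(np.log(expr) * 3 + 1, sig)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_empty_signature_rejected(self, rng):
        expr = pd.Series(rng.normal(size=5), index=list("abcde"))
        with pytest.raises(ValidationError):
            rank_signature_score(expr, [])
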