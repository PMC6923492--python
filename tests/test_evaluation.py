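import numpy as np
import pandas as pd
import pytest

import cescore as ces
from cescore.containers import ScreenMatrix
from cescore.evaluation import delong_auc_variance

from _oracles import delong_components_bruteforce, pair_counting_auc


def make_screen(values, label="scores"):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    lines = [f"L{j}" for j in range(values.shape[1])]
    return ScreenMatrix(genes, lines, values, label)


# ---------------------------------------------------------------------------
# Ranking


class TestRankGenes:
    def test_sorted_column(self):
        table = ces.rank_genes(make_screen([[-2.0], [0.0], [1.0]]))
        np.testing.assert_array_equal(table.ranks[:, 0], [1, 2, 3])

    def test_ties_get_average_rank(self):
        table = ces.rank_genes(make_screen([[0.0], [0.0], [1.0]]))
        np.testing.assert_array_equal(table.ranks[:, 0], [1.5, 1.5, 3.0])

    def test_overall_score_is_mean_of_available_ranks(self):
        values = np.array([[-2.0, 1.0], [0.0, -5.0], [1.0, 0.0]])
        table = ces.rank_genes(make_screen(values))
        assert table.overall_score[0] == pytest.approx((1 + 3) / 2)
        assert list(table.n_lines_used) == [2, 2, 2]

    def test_missing_scores_excluded_from_average(self):
        values = np.array([[-2.0, np.nan], [0.0, -5.0], [1.0, 0.0]])
        table = ces.rank_genes(make_screen(values))
        assert table.overall_score[0] == pytest.approx(1.0)
        assert table.n_lines_used[0] == 1

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(50, 4))
        values[rng.random(values.shape) < 0.2] = np.nan
        table = ces.rank_genes(make_screen(values))
        for j in range(4):
            col = table.ranks[:, j]
            k = int(np.sum(~np.isnan(col)))
            assert np.nansum(col) == pytest.approx(k * (k + 1) / 2)


# ---------------------------------------------------------------------------
# Gene sets, ROC / AUC


def series(values, prefix="G"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestROC:
    def test_perfect_separation(self):
        scores = series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = ces.GeneSetLabels({"G0", "G1", "G2"}, {"G3", "G4", "G5"})
        assert ces.roc_auc(scores, labels).auc == 1.0

    def test_all_ties_give_half(self):
        scores = series([5.0] * 6)
        labels = ces.GeneSetLabels({"G0", "G1", "G2"}, {"G3", "G4", "G5"})
        assert ces.roc_auc(scores, labels).auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = series(np.round(rng.normal(size=10), 1))
            labels = ces.GeneSetLabels({f"G{i}" for i in range(4)},
                                       {f"G{i}" for i in range(4, 10)})
            got = ces.roc_auc(scores, labels).auc
            want = pair_counting_auc(scores.values[:4], scores.values[4:])
            assert got == pytest.approx(want, abs=1e-12)

    def test_complement_invariant_for_tie_free_scores(self):
        rng = np.random.default_rng(2)
        scores = series(rng.normal(size=30))
        labels = ces.GeneSetLabels({f"G{i}" for i in range(10)},
                                   {f"G{i}" for i in range(10, 30)})
        auc = ces.roc_auc(scores, labels).auc
        flipped = ces.roc_auc(-scores, labels).auc
        assert auc + flipped == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = series(rng.normal(size=40))
        labels = ces.GeneSetLabels({f"G{i}" for i in range(15)},
                                   {f"G{i}" for i in range(15, 40)})
        base = ces.roc_auc(scores, labels).auc
        assert ces.roc_auc(np.exp(scores), labels).auc == pytest.approx(base)
        assert ces.roc_auc(scores ** 3 + 5 * scores, labels).auc == pytest.approx(base)

    def test_ambiguous_genes_removed_from_both_sets(self):
        labels = ces.GeneSetLabels({"A", "B"}, {"B", "C"})
        assert labels.positive == {"A"}
        assert labels.negative == {"C"}

    def test_empty_class_rejected(self):
        scores = series([1.0, 2.0])
        labels = ces.GeneSetLabels({"G0", "G1"}, {"ABSENT"})
        with pytest.raises(ValueError, match="negative"):
            ces.roc_auc(scores, labels)


# ---------------------------------------------------------------------------
# DeLong


class TestDeLong:
    def test_identical_methods_are_degenerate(self):
        rng = np.random.default_rng(4)
        scores = series(rng.normal(size=30))
        labels = ces.GeneSetLabels({f"G{i}" for i in range(10)},
                                   {f"G{i}" for i in range(10, 30)})
        res = ces.delong_test(scores, scores.copy(), labels)
        assert res.degenerate
        assert res.z == 0.0
        assert res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_variance_matches_bruteforce_placements(self):
        rng = np.random.default_rng(5)
        scores = series(np.round(rng.normal(size=18), 1))
        labels = ces.GeneSetLabels({f"G{i}" for i in range(7)},
                                   {f"G{i}" for i in range(7, 18)})
        auc, var = delong_auc_variance(scores, labels)
        # Oracle works on the "higher = positive" orientation.
        bauc, _, _, bvar = delong_components_bruteforce(
            -scores.values[:7], -scores.values[7:]
        )
        assert auc == pytest.approx(bauc, abs=1e-12)
        assert var == pytest.approx(bvar, rel=1e-10)

    def test_detects_a_clearly_better_method(self):
        rng = np.random.default_rng(6)
        n = 80
        latent = np.concatenate([rng.normal(-2, 1, n), rng.normal(0, 1, n)])
        good = series(latent + rng.normal(0, 0.3, 2 * n))
        bad = series(rng.normal(size=2 * n))
        labels = ces.GeneSetLabels({f"G{i}" for i in range(n)},
                                   {f"G{i}" for i in range(n, 2 * n)})
        res = ces.delong_test(good, bad, labels)
        assert res.auc_a > res.auc_b
        assert res.p_value < 1e-4


# ---------------------------------------------------------------------------
# SSMD


class TestSSMD:
    def labels(self):
        return ces.GeneSetLabels({"G0", "G1"}, {"G2", "G3"})

    def test_hand_computed_value(self):
        scores = make_screen([[-2.0], [-1.0], [0.0], [1.0]])
        out = ces.ssmd(scores, self.labels())
        assert out["L0"] == pytest.approx(-2.0)

    def test_identical_class_distributions_give_zero(self):
        scores = make_screen([[1.0], [3.0], [1.0], [3.0]])
        out = ces.ssmd(scores, self.labels())
        assert out["L0"] == pytest.approx(0.0)

    def test_sign_flips_when_labels_swapped(self):
        rng = np.random.default_rng(7)
        scores = make_screen(rng.normal(size=(4, 2)))
        forward = ces.ssmd(scores, self.labels())
        swapped = ces.ssmd(scores, ces.GeneSetLabels({"G2", "G3"}, {"G0", "G1"}))
        np.testing.assert_allclose(swapped.values, -forward.values)

    def test_abs_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(4, 1))
        a = ces.ssmd(make_screen(values), self.labels())
        b = ces.ssmd(make_screen(3.0 * values + 7.0), self.labels())
        assert abs(a["L0"]) == pytest.approx(abs(b["L0"]))

    def test_small_class_gives_missing(self):
        scores = make_screen([[-2.0], [np.nan], [0.0], [1.0]])
        out = ces.ssmd(scores, self.labels())
        assert np.isnan(out["L0"])


# ---------------------------------------------------------------------------
# Hit-rate curves


class TestHitRate:
    def test_always_top_ranked(self):
        table = ces.rank_genes(make_screen([[-5.0, -5.0], [0.0, 0.0], [1.0, 1.0]]))
        curve = ces.hit_rate_curve("G0", table, t_max=3)
        np.testing.assert_array_equal(curve.hit_rate, [1.0, 1.0, 1.0])
        assert curve.auc == 1.0

    def test_always_last_with_tight_threshold(self):
        table = ces.rank_genes(make_screen([[-5.0], [0.0], [1.0]]))
        curve = ces.hit_rate_curve("G2", table, t_max=2)
        assert curve.auc == 0.0

    def test_enumerated_three_line_curve(self):
        # Gene ranked 1, 2 and 5 in the three cell lines.
        values = np.zeros((5, 3))
        values[:, 0] = [-9, 0, 1, 2, 3]
        values[:, 1] = [-1, -9, 1, 2, 3]
        values[:, 2] = [4, -9, -8, -7, -6]
        table = ces.rank_genes(make_screen(values))
        curve = ces.hit_rate_curve("G0", table, t_max=5)
        np.testing.assert_allclose(curve.hit_rate, [1/3, 2/3, 2/3, 2/3, 1.0])
        assert curve.auc == pytest.approx(10 / 15)

    def test_monotone_and_invariant_to_line_relabelling(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(30, 6))
        table = ces.rank_genes(make_screen(values))
        curve = ces.hit_rate_curve("G3", table, t_max=20)
        assert np.all(np.diff(curve.hit_rate) >= 0)
        shuffled = make_screen(values[:, ::-1])
        curve2 = ces.hit_rate_curve("G3", ces.rank_genes(shuffled), t_max=20)
        assert curve2.auc == pytest.approx(curve.auc)

    def test_absent_gene_rejected(self):
        table = ces.rank_genes(make_screen([[-1.0], [1.0]]))
        with pytest.raises(KeyError):
            ces.hit_rate_curve("NOPE", table, t_max=5)


# ---------------------------------------------------------------------------
# Cell-specific selection


class TestCellSpecific:
    def build_tables(self, M=300, N=4, seed=10):
        rng = np.random.default_rng(seed)
        mats = [make_screen(rng.normal(size=(M, N))) for _ in range(3)]
        return [ces.rank_genes(m) for m in mats]

    def test_commonly_essential_gene_excluded(self):
        """A gene in the top-k of every line has a good overall score and
        must not be called cell-specific."""
        rng = np.random.default_rng(11)
        values = rng.normal(size=(300, 4))
        values[0, :] = -100.0  # top rank everywhere
        t = ces.rank_genes(make_screen(values))
        hits = ces.select_cell_specific(t, t, t, top_k=10, overall_min=150,
                                        novelty_cutoff=50)
        assert "G0" not in {h.gene_id for h in hits.hits}

    def test_gene_without_within_line_signal_excluded(self):
        ces_t, cr_t, sh_t = self.build_tables()
        hits = ces.select_cell_specific(ces_t, cr_t, sh_t, top_k=5,
                                        overall_min=150, novelty_cutoff=50)
        top5 = set()
        for j in range(len(ces_t.cell_line_ids)):
            col = ces_t.ranks[:, j]
            top5 |= {ces_t.gene_ids[i] for i in np.where(col <= 5)[0]}
        assert {h.gene_id for h in hits.hits} <= top5

    def test_novel_requires_both_screens_to_miss(self):
        rng = np.random.default_rng(12)
        M, N = 200, 2
        base = rng.normal(size=(M, N))
        ces_vals = base.copy()
        ces_vals[0, 0] = -100.0  # CES top hit in line 0
        ces_vals[0, 1] = 100.0   # poor everywhere else -> bad overall score
        crispr_vals = base.copy()
        crispr_vals[0, 0] = 100.0  # CRISPR ranks it last
        shrna_vals = base.copy()
        shrna_vals[0, 0] = -100.0  # shRNA also finds it
        hits = ces.select_cell_specific(
            ces.rank_genes(make_screen(ces_vals)),
            ces.rank_genes(make_screen(crispr_vals)),
            ces.rank_genes(make_screen(shrna_vals)),
            top_k=5, overall_min=90, novelty_cutoff=100,
        )
        hit = [h for h in hits.hits if h.gene_id == "G0"]
        assert hit and not hit[0].novel

    def test_thresholds_validated(self):
        ces_t, cr_t, sh_t = self.build_tables()
        with pytest.raises(ValueError, match="top_k"):
            ces.select_cell_specific(ces_t, cr_t, sh_t, top_k=0)
        with pytest.raises(ValueError, match="overall_min"):
            ces.select_cell_specific(ces_t, cr_t, sh_t, top_k=5,
                                     overall_min=10_000)


# ---------------------------------------------------------------------------
# Between-screen consistency


class TestConsistency:
    def test_identical_matrices(self):
        rng = np.random.default_rng(13)
        a = make_screen(rng.normal(size=(100, 3)))
        b = ScreenMatrix(list(a.gene_ids), list(a.cell_line_ids),
                         a.values.copy(), "shRNA")
        rep = ces.consistency_report(a, b, n_perm=5, seed=0)
        np.testing.assert_allclose(rep.per_line["pearson_r"], 1.0)
        np.testing.assert_allclose(rep.per_line["mse"], 0.0, atol=1e-15)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(14)
        a = make_screen(rng.normal(size=(50, 2)))
        b = ScreenMatrix(list(a.gene_ids), list(a.cell_line_ids),
                         -a.values, "shRNA")
        rep = ces.consistency_report(a, b, n_perm=5, seed=0)
        np.testing.assert_allclose(rep.per_line["pearson_r"], -1.0)

    def test_permutation_null_mse_near_two_for_independent_screens(self):
        """Independent standard-normal columns: E[(X - Y_perm)^2] = 2."""
        rng = np.random.default_rng(15)
        M = 5000
        a = make_screen(rng.normal(size=(M, 2)))
        b = ScreenMatrix(list(a.gene_ids), list(a.cell_line_ids),
                         rng.normal(size=(M, 2)), "shRNA")
        rep = ces.consistency_report(a, b, n_perm=20, seed=1)
        assert abs(rep.mean_perm_mse - 2.0) < 0.1

    def test_sparse_line_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(16)
        a = make_screen(rng.normal(size=(10, 2)))
        b = ScreenMatrix(list(a.gene_ids), list(a.cell_line_ids),
                         rng.normal(size=(10, 2)), "shRNA")
        b.values[2:, 0] = np.nan
        rep = ces.consistency_report(a, b, n_perm=3, seed=0)
        assert list(rep.per_line["cell_line"]) == ["L1"]
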