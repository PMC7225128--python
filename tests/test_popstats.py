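import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from statekinetics import popstats


class TestRankSumDE:
    def test_small_lfc_filtered(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5.0, 0.1, 50)
        A = np.vstack([base, base + 2.0])
        B = np.vstack([base + 0.10, base])  # gene 0: |lfc| = 0.10 < 0.15
        table = popstats.rank_sum_de(A, B, min_frac=0.0)
        assert not table["tested"][0]
        assert np.isnan(table["p"][0])
        assert table["tested"][1]

    def test_low_fraction_filtered(self):
        A = np.zeros((1, 100))
        B = np.zeros((1, 100))
        A[0, :5] = 3.0  # 5% expressing in both groups
        B[0, :5] = 1.0
        table = popstats.rank_sum_de(A, B, min_lfc=0.0)
        assert not table["tested"][0]

    def test_exact_p_fully_separated_6v6(self):
        """Complete separation of 6 vs 6 gives the exact two-sided
        rank-sum p of 2 * 6! * 6! / 12! = 1/462."""
        a = np.arange(7.0, 13.0)[None, :]
        b = np.arange(1.0, 7.0)[None, :]
        table = popstats.rank_sum_de(a, b, min_lfc=0.0, min_frac=0.0)
        assert table["p"][0] == pytest.approx(1.0 / 462.0, rel=1e-12)

    def test_constant_gene_flagged_p_one(self):
        A = np.vstack([np.full(10, 2.0), np.arange(10.0)])
        B = np.vstack([np.full(10, 2.0), np.arange(10.0) + 5.0])
        table = popstats.rank_sum_de(A, B, min_lfc=0.0, min_frac=0.0)
        assert table["constant_flag"][0]
        assert table["p"][0] == 1.0

    def test_bonferroni_uses_tested_count(self):
        rng = np.random.default_rng(1)
        A = rng.normal(0, 1, (20, 30)) + 10
        B = rng.normal(0, 1, (20, 30)) + 10
        table = popstats.rank_sum_de(A, B, min_lfc=0.0, min_frac=0.0)
        m = int(table["tested"].sum())
        expected = np.minimum(table["p"] * m, 1.0)
        np.testing.assert_allclose(table["p_bonferroni"], expected)

    def test_group_size_precondition(self):
        with pytest.raises(ValueError, match=">= 3 cells"):
            popstats.rank_sum_de(np.ones((2, 2)), np.ones((2, 5)))

    def test_power_on_shifted_genes(self):
        """A 1-unit log-mean shift at n=200/group is detected for >= 80%
        of spiked genes after Bonferroni."""
        rng = np.random.default_rng(2)
        n_genes, n_spiked = 300, 50
        A = rng.normal(5.0, 1.0, (n_genes, 200))
        B = rng.normal(5.0, 1.0, (n_genes, 200))
        A[:n_spiked] += 1.0
        table = popstats.rank_sum_de(A, B)
        assert table["significant"][:n_spiked].mean() >= 0.8


class TestGeneAUROC:
    def test_perfect_separation(self):
        assert popstats.gene_auroc(
            np.array([5.0, 6.0, 1.0, 2.0]), np.array([1, 1, 0, 0])
        ) == pytest.approx(1.0)

    def test_constant_gene_is_chance(self):
        assert popstats.gene_auroc(
            np.full(10, 3.0), np.array([1] * 5 + [0] * 5)
        ) == pytest.approx(0.5)

    def test_worked_example_with_tie(self):
        """labels (1,1,0,0), values (3,2,2,1) -> (1 + 1 + 0.5 + 1)/4."""
        auc = popstats.gene_auroc(
            np.array([3.0, 2.0, 2.0, 1.0]), np.array([1, 1, 0, 0])
        )
        assert auc == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            popstats.gene_auroc(np.arange(4.0), np.ones(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equals_sklearn_roc_auc(self, seed):
        """The rank-sum identity must agree with an independent AUROC
        implementation on random instances with ties."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = rng.integers(6, 60)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        x = rng.integers(0, 6, n).astype(float)  # heavy ties
        assert popstats.gene_auroc(x, y) == pytest.approx(
            roc_auc_score(y, x), abs=1e-12
        )


class TestDMOverdispersion:
    def test_low_mean_gene_filtered(self):
        rng = np.random.default_rng(3)
        expr = rng.gamma(2.0, 1.0, (60, 200))
        expr[0] = 0.05 * rng.random(200)  # mean below 0.1
        table = popstats.dm_overdispersion(expr, window=20)
        assert table["filtered"][0]
        assert np.isnan(table["dm"][0])

    def test_common_curve_gives_zero_dm(self):
        """Genes lying on one exact CV^2-mean curve have DM = 0."""
        rng = np.random.default_rng(4)
        n_genes, n_cells = 40, 5000
        means = np.linspace(1.0, 20.0, n_genes)
        # construct expression with exactly two support points per gene:
        # values {0, 2m} each with prob 1/2 -> CV^2 = 1/1 = const
        expr = np.where(
            rng.random((n_genes, n_cells)) < 0.5, 0.0, 2.0 * means[:, None]
        )
        table = popstats.dm_overdispersion(expr, window=11)
        interior = slice(6, -6)
        assert np.abs(table["dm"].to_numpy()[interior]).max() < 0.05

    def test_inflated_gene_ranks_first(self):
        rng = np.random.default_rng(5)
        n_genes, n_cells = 41, 8000
        means = np.linspace(1.0, 5.0, n_genes)
        expr = np.where(
            rng.random((n_genes, n_cells)) < 0.5, 0.0, 2.0 * means[:, None]
        )
        # inflate one interior gene's CV^2 10x: mixture {0 w.p. 10/11}
        g = 20
        p = 1.0 / 11.0
        expr[g] = np.where(
            rng.random(n_cells) < p, means[g] / p, 0.0
        )
        table = popstats.dm_overdispersion(expr, window=11)
        assert table["dm"][g] == pytest.approx(1.0, abs=0.05)  # log10(10)
        assert table["dm"].idxmax() == g

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(6)
        expr = rng.gamma(2.0, 2.0, (50, 300))
        perm = rng.permutation(50)
        a = popstats.dm_overdispersion(expr, window=15)["dm"].to_numpy()
        b = popstats.dm_overdispersion(expr[perm], window=15)["dm"].to_numpy()
        np.testing.assert_allclose(a[perm], b, rtol=1e-12)

    def test_window_larger_than_genes_rejected(self):
        with pytest.raises(ValueError, match="window"):
            popstats.dm_overdispersion(np.ones((5, 10)) * 2, window=20)


class TestKLDivergence:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(7)
        est = popstats.kl_divergence(
            rng.normal(size=(5000, 2)), rng.normal(size=(5000, 2)), seed=0
        )
        assert abs(est.kl) < 0.05

    def test_gaussian_shift_closed_form(self):
        rng = np.random.default_rng(8)
        est = popstats.kl_divergence(
            rng.normal(1.0, 1.0, (10000, 1)), rng.normal(0.0, 1.0, (10000, 1)), seed=0
        )
        assert est.kl == pytest.approx(0.5, rel=0.1)

    def test_unequal_sizes_prior_corrected(self):
        rng = np.random.default_rng(9)
        est = popstats.kl_divergence(
            rng.normal(size=(2000, 1)), rng.normal(size=(8000, 1)), seed=0
        )
        assert abs(est.kl) < 0.05

    def test_asymmetric_on_skewed_construction(self):
        rng = np.random.default_rng(10)
        xa = rng.normal(0.0, 1.0, (6000, 1))
        xb = rng.normal(0.0, 2.5, (6000, 1))
        ab = popstats.kl_divergence(xa, xb, seed=0, classifier="gbm").kl
        ba = popstats.kl_divergence(xb, xa, seed=0, classifier="gbm").kl
        assert ab != pytest.approx(ba, abs=0.02)
        assert ab > -0.05 and ba > -0.05

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            popstats.kl_divergence(np.zeros((10, 1)), np.zeros((100, 1)))

    def test_degenerate_features_dropped_with_warning(self):
        rng = np.random.default_rng(11)
        xa = np.column_stack([rng.normal(size=200), np.ones(200)])
        xb = np.column_stack([rng.normal(size=200), np.ones(200)])
        with pytest.warns(UserWarning, match="degenerate"):
            popstats.kl_divergence(xa, xb, seed=0)


class TestIncorporationWald:
    def test_study_scale_counts_significant(self):
        """21% vs 17% incorporation at n = 10279 vs 13464 is decisively
        significant by the Wald test."""
        out = popstats.incorporation_wald(
            ((round(0.21 * 10279), 10279), (round(0.17 * 13464), 13464))
        )
        assert out["p"] < 0.001
        assert out["odds_ratio"] > 1.0

    def test_equal_rates_null(self):
        out = popstats.incorporation_wald(((30, 100), (60, 200)))
        assert out["odds_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert out["p"] > 0.9

    def test_hand_odds_ratio_and_wald_z(self):
        """2x2 counts (30/100 vs 10/100): OR = 27/7; Wald z from the
        standard log-OR variance 1/a + 1/b + 1/c + 1/d."""
        out = popstats.incorporation_wald(((30, 100), (10, 100)))
        assert out["odds_ratio"] == pytest.approx(27.0 / 7.0, rel=1e-6)
        se = np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90)
        z_expected = np.log(27.0 / 7.0) / se
        assert abs(out["wald_z"]) == pytest.approx(z_expected, rel=1e-4)

    def test_perfect_separation_flagged(self):
        with pytest.warns(UserWarning, match="separation"):
            out = popstats.incorporation_wald(((0, 50), (25, 50)))
        assert out["separation"]
        assert np.isnan(out["p"])

    def test_per_cell_form_matches_counts_form(self):
        y = np.array([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90, dtype=float)
        g = np.array(["a"] * 100 + ["b"] * 100)
        out = popstats.incorporation_wald(y, g)
        assert out["odds_ratio"] == pytest.approx(7.0 / 27.0, rel=1e-6) or out[
            "odds_ratio"
        ] == pytest.approx(27.0 / 7.0, rel=1e-6)
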