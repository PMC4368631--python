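import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, nbinom, poisson

from promdiff.differential import (
    differential_table,
    estimate_dispersion,
    log2_fold_change,
    nb_exact_test,
    select_significant,
    size_factors,
)
from promdiff.io_formats import ValidationError

from conftest import make_count_matrix


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile([[10], [20], [30]], (1, 4))
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_hand_evaluated_median_of_ratios(self):
        got = size_factors(np.array([[10, 20], [30, 60]]))
        np.testing.assert_allclose(got, [0.7071, 1.4142], atol=1e-4)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(20)
        counts = rng.integers(1, 500, size=(300, 5)).astype(float)
        base = size_factors(counts)
        scaled = counts.copy()
        scaled[:, 2] *= 8
        got = size_factors(scaled)
        # scaling one column by c multiplies its factor by c up to the
        # shared geometric-mean reference shift c^(1/m)
        shift = 8 ** (1 / 5)
        np.testing.assert_allclose(got[2], base[2] * 8 / shift, rtol=1e-10)
        np.testing.assert_allclose(np.delete(got, 2), np.delete(base, 2) / shift, rtol=1e-10)

    def test_no_all_positive_gene_is_an_error(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValidationError, match="all-positive"):
            size_factors(counts)


class TestDispersion:
    def test_constant_normalized_counts_hit_floor(self):
        counts = np.full((5, 4), 100)
        alpha = estimate_dispersion(counts, np.ones(4), shrink=False)
        np.testing.assert_allclose(alpha, 1e-8)

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(21)
        counts = rng.poisson(100, size=(2000, 6))
        alpha = estimate_dispersion(counts, np.ones(6), shrink=False)
        assert np.median(alpha) <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(22)
        r = 1 / 0.2
        counts = rng.negative_binomial(r, r / (r + 100), size=(2000, 6))
        alpha = estimate_dispersion(counts, np.ones(6), shrink=False)
        assert 0.1 <= np.median(alpha) <= 0.3

    def test_group_aware_variance_ignores_real_shifts(self):
        rng = np.random.default_rng(23)
        groups = ["patient"] * 2 + ["control"] * 4
        counts = np.column_stack(
            [rng.poisson(400, size=1000)] * 2 + [rng.poisson(100, size=1000)] * 4
        )
        pooled = estimate_dispersion(counts, np.ones(6), shrink=False)
        grouped = estimate_dispersion(counts, np.ones(6), groups=groups, shrink=False)
        assert np.median(grouped) < 0.01 < np.median(pooled)

    def test_all_zero_gene_gets_floor(self):
        counts = np.vstack([np.zeros(4), np.full(4, 50)])
        alpha = estimate_dispersion(counts, np.ones(4), shrink=False)
        assert alpha[0] == 1e-8


class TestNbExactTest:
    def test_balanced_split_has_p_one(self):
        assert nb_exact_test(40, 40, 3.0, 3.0, 0.1) == 1.0

    def test_group_swap_symmetry(self):
        assert nb_exact_test(10, 90, 2.0, 4.0, 0.2) == pytest.approx(
            nb_exact_test(90, 10, 4.0, 2.0, 0.2), rel=1e-12
        )

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test(0, 0, 1.0, 2.0, 0.1) == 1.0

    def test_p_in_unit_interval_and_stable_for_large_totals(self):
        p = nb_exact_test(480_000, 520_000, 2.0, 4.0, 0.01)
        assert 0 < p <= 1

    def test_matches_brute_force_enumeration(self):
        """Direct linear-space enumeration of the two-sided conditional
        definition, for every split of every total up to 50."""
        s_a, s_b, alpha = 1.5, 3.0, 0.2

        def brute(ka, kb):
            tot = ka + kb
            if tot == 0:
                return 1.0
            q = tot / (s_a + s_b)
            r = 1 / alpha
            a = np.arange(tot + 1)
            pa = nbinom.pmf(a, r, r / (r + q * s_a))
            pb = nbinom.pmf(tot - a, r, r / (r + q * s_b))
            prod = pa * pb
            return min(1.0, prod[prod <= prod[ka] * (1 + 1e-10)].sum() / prod.sum())

        for tot in range(51):
            for ka in range(tot + 1):
                assert nb_exact_test(ka, tot - ka, s_a, s_b, alpha) == pytest.approx(
                    brute(ka, tot - ka), abs=1e-12
                )

    @pytest.mark.parametrize("total", [1, 7, 50, 200])
    def test_dispersion_zero_equals_binomial_conditional(self, total):
        """Poisson group sums conditioned on the total are binomial; the
        probability-ordered two-sided binomial test is the oracle."""
        s_a, s_b = 2.0, 4.0
        frac = s_a / (s_a + s_b)
        pmf = binom.pmf(np.arange(total + 1), total, frac)
        for ka in range(total + 1):
            expected = min(1.0, pmf[pmf <= pmf[ka] * (1 + 1e-10)].sum())
            assert nb_exact_test(ka, total - ka, s_a, s_b, 0.0) == pytest.approx(
                expected, abs=1e-10
            )


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        counts = np.tile([[10, 10, 10, 10]], (3, 1)).T.T
        lfc = log2_fold_change(counts, np.ones(4), np.array([0, 1]), np.array([2, 3]))
        np.testing.assert_allclose(lfc, 0.0)

    def test_formula_evaluation(self):
        counts = np.array([[40, 40, 10, 10]])
        lfc = log2_fold_change(counts, np.ones(4), np.array([0, 1]), np.array([2, 3]))
        assert lfc[0] == pytest.approx(np.log2(41 / 11))

    def test_all_zero_gene_gives_zero(self):
        counts = np.zeros((1, 4), dtype=int)
        lfc = log2_fold_change(counts, np.ones(4), np.array([0, 1]), np.array([2, 3]))
        assert lfc[0] == 0.0

    def test_doubling_counts_and_factors_leaves_lfc_unchanged(self):
        rng = np.random.default_rng(24)
        counts = rng.integers(0, 300, size=(100, 6))
        f = size_factors(np.maximum(counts, 1))
        a = log2_fold_change(counts, f, np.array([0, 1]), np.arange(2, 6))
        b = log2_fold_change(counts * 2, f * 2, np.array([0, 1]), np.arange(2, 6))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSelection:
    def _tables(self, rows):
        """rows: per mark, list of (lfc, p) per gene."""
        out = {}
        for mark, values in rows.items():
            out[mark] = pd.DataFrame(
                {"log2FC": [v[0] for v in values], "pval": [v[1] for v in values]},
                index=pd.Index([f"g{i}" for i in range(len(values))], name="gene_id"),
            )
        return out

    def test_single_mark_hit_selects_gene(self):
        tables = self._tables({
            "H3K4me3": [(1.5, 0.01)], "H3K27me3": [(0.0, 1.0)], "H3K9ac": [(0.0, 1.0)],
        })
        call = select_significant(tables)
        assert call.selected_genes == ["g0"]
        assert call.table.loc["g0", "H3K4me3"]
        assert not call.table.loc["g0", "H3K27me3"]

    def test_below_fold_threshold_never_selected(self):
        tables = self._tables({m: [(0.5, 1e-10)] for m in ("a", "b", "c")})
        assert select_significant(tables).selected_genes == []

    def test_negative_fold_change_counts(self):
        tables = self._tables({
            "H3K4me3": [(0.0, 1.0)], "H3K27me3": [(-2.0, 0.04)], "H3K9ac": [(0.2, 0.5)],
        })
        assert select_significant(tables).selected_genes == ["g0"]

    def test_mismatched_gene_universe_rejected(self):
        tables = self._tables({"a": [(1, 0.01)], "b": [(1, 0.01)]})
        tables["b"].index = pd.Index(["other"], name="gene_id")
        with pytest.raises(ValidationError):
            select_significant(tables)


class TestDifferentialTable:
    def test_null_pvalues_are_calibrated(self):
        """No effects, NB noise, 2 vs 4: P(p <= 0.05) stays below 8%."""
        rng = np.random.default_rng(25)
        r = 1 / 0.05
        mu = 100
        counts = rng.negative_binomial(r, r / (r + mu), size=(1500, 6))
        mat = make_count_matrix(counts, groups=("patient",) * 2 + ("control",) * 4)
        table = differential_table(mat)
        assert (table["pval"] <= 0.05).mean() <= 0.08
        assert ((table["pval"] > 0) & (table["pval"] <= 1)).all()

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(26)
        null = rng.poisson(100, size=(200, 6))
        hit = np.concatenate([rng.poisson(400, size=2), rng.poisson(100, size=4)])[None, :]
        mat = make_count_matrix(np.vstack([null, hit]), groups=("patient",) * 2 + ("control",) * 4)
        table = differential_table(mat)
        assert table["pval"].iloc[-1] < 0.01
        assert table["log2FC"].iloc[-1] > 1.5
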