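"""Size factors, dispersion estimation, NB Wald contrast and BH adjustment."""

import numpy as np
import pytest
from scipy import stats

from sclnc.diffexp import (
    base_means,
    bh_adjust,
    build_design_matrix,
    estimate_dispersion,
    nb_wald_contrast,
    normalized_counts,
    run_de,
    size_factors_median_ratios,
)
from sclnc.synthetic import simulate_nb_matrix

from conftest import oracle_bh


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.array([[5], [10], [50]]), (1, 4))
        assert np.allclose(size_factors_median_ratios(counts), 1.0)

    def test_worked_two_by_two_example(self):
        # geometric means: sqrt(200), sqrt(1800); every ratio column is
        # (1/sqrt 2, sqrt 2) -> medians 0.7071 and 1.4142
        counts = np.array([[10, 20], [30, 60]])
        s = size_factors_median_ratios(counts)
        assert np.allclose(s, [0.7071, 1.4142], atol=1e-4)

    def test_column_scaling_equivariance_of_relative_factors(self):
        # only ratios of size factors are identified; scaling a column by c
        # multiplies its factor by c relative to every other sample
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = rng.integers(1, 200, size=(20, 5))
            s = size_factors_median_ratios(counts)
            c = int(rng.integers(2, 6))
            scaled = counts.copy()
            scaled[:, 2] *= c
            s2 = size_factors_median_ratios(scaled)
            mask = np.arange(5) != 2
            assert np.allclose(s2[2] / s2[mask], c * s[2] / s[mask], rtol=1e-9)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 100, size=(30, 4))
        s1 = size_factors_median_ratios(counts)
        s2 = size_factors_median_ratios(counts[rng.permutation(30)])
        assert np.allclose(s1, s2)

    def test_no_reference_gene_raises_with_advice(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors_median_ratios(counts)
        # poscounts-style fallback still normalizes
        s = size_factors_median_ratios(counts, pseudo_reference=True)
        assert np.all(s > 0)


class TestNormalizedCounts:
    def test_unit_factors_identity(self):
        counts = np.arange(12).reshape(3, 4)
        assert np.allclose(normalized_counts(counts, np.ones(4)), counts)

    def test_doubled_column_with_doubled_factor_unchanged(self):
        counts = np.array([[10, 10], [20, 20]])
        scaled = counts.copy()
        scaled[:, 1] *= 2
        norm = normalized_counts(scaled, np.array([1.0, 2.0]))
        assert np.allclose(norm, counts)

    def test_base_mean_is_row_mean_of_normalized(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 100, size=(10, 6))
        s = np.exp(rng.normal(0, 0.2, size=6))
        assert np.allclose(base_means(counts, s), normalized_counts(counts, s).mean(axis=1))


@pytest.fixture(scope="module")
def design_20_per_group():
    m, _ = simulate_nb_matrix(1, 20, 0.1, {}, seed=0)
    return build_design_matrix(m.sample_metadata(), "cell_type", ("FP", "DA"))


class TestDispersion:
    def test_poisson_counts_hit_the_floor(self, design_20_per_group):
        m, _ = simulate_nb_matrix(200, 20, 1e-12, {}, seed=8)
        d = estimate_dispersion(m.counts, np.ones(40), design_20_per_group)
        # Poisson data: most genes at/near the 1e-8 floor
        assert np.median(d) < 0.01
        assert (d < 0.01).mean() > 0.8

    def test_nb_dispersion_recovered(self, design_20_per_group):
        m, _ = simulate_nb_matrix(500, 20, 0.1, {}, seed=7)
        s = size_factors_median_ratios(m.counts)
        d = estimate_dispersion(m.counts, s, design_20_per_group)
        assert 0.05 <= np.median(d) <= 0.2

    def test_constant_gene_at_floor(self):
        counts = np.full((1, 6), 17)
        X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
        d = estimate_dispersion(counts, np.ones(6), X)
        assert d[0] < 1e-6


class TestWaldContrast:
    def _fit(self, counts, n_per_group, disp=0.05):
        n = 2 * n_per_group
        X = np.column_stack(
            [np.ones(n), np.repeat([0.0, 1.0], n_per_group)]
        )
        gene_ids = [f"G{i}" for i in range(counts.shape[0])]
        return nb_wald_contrast(
            counts, np.ones(n), np.full(counts.shape[0], disp), X, gene_ids
        )

    def test_identical_group_means_null(self):
        row = np.array([30, 35, 28, 33, 30, 35, 28, 33], dtype=float)
        tab = self._fit(row[np.newaxis, :], 4)
        assert abs(tab.loc[0, "log2FoldChange"]) < 1e-6
        assert tab.loc[0, "pvalue"] > 0.999

    def test_label_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(5, 200, size=(20, 12)).astype(float)
        tab1 = self._fit(counts, 6)
        swapped = np.concatenate([counts[:, 6:], counts[:, :6]], axis=1)
        tab2 = self._fit(swapped, 6)
        assert np.allclose(tab1["log2FoldChange"], -tab2["log2FoldChange"], atol=1e-5)
        assert np.allclose(tab1["pvalue"], tab2["pvalue"], atol=1e-6)

    def test_all_zero_gene_undefined(self):
        tab = self._fit(np.zeros((1, 8)), 4)
        assert np.isnan(tab.loc[0, "pvalue"])
        assert tab.loc[0, "baseMean"] == 0

    def test_coefficient_matches_statsmodels_nb_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(19)
        alpha = 0.1
        mu = np.repeat([40.0, 160.0], 8)
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu)).astype(float)
        X = np.column_stack([np.ones(16), np.repeat([0.0, 1.0], 8)])
        tab = self._fit(y[np.newaxis, :], 8, disp=alpha)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert np.isclose(tab.loc[0, "log2FoldChange"], ref.params[1] / np.log(2), atol=1e-4)
        assert np.isclose(tab.loc[0, "lfcSE"], ref.bse[1] / np.log(2), rtol=0.02)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.05]))[0] == pytest.approx(0.05)

    def test_hand_worked_step_up(self):
        # (0.01, 0.02, 0.03): 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_matches_literal_oracle_on_small_lists(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            p = rng.uniform(0, 1, size=n)
            assert np.allclose(bh_adjust(p), oracle_bh(list(p)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, size=100)
        order = np.argsort(p)
        adj = bh_adjust(p)[order]
        assert np.all(np.diff(adj) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_nan_passthrough(self):
        adj = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestRunDE:
    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(0)
        signs = rng.choice([-1.0, 1.0], size=20)
        planted = {i: 2.0 * float(signs[i]) for i in range(20)}
        m, truth = simulate_nb_matrix(200, 10, 0.05, planted, seed=0)
        de = run_de(m, contrast="cell_type", levels=("FP", "DA"), alpha=0.01)
        sig = set(de.significant_genes())
        planted_ids = set(truth["lfc"])
        assert len(sig & planted_ids) / len(planted_ids) >= 0.8
        tab = de.table.set_index("gene_id")
        err = np.array(
            [tab.loc[g, "log2FoldChange"] - truth["lfc"][g] for g in sorted(planted_ids)]
        )
        assert abs(err.mean()) < 0.1
        # sampling-error derivation at baseline means 20-200 gives per-gene
        # P(|err|<0.3) of 0.87-0.96; 0.85 is a 2-sigma-safe aggregate bound
        assert (np.abs(err) < 0.3).mean() >= 0.85

    def test_null_type_one_error_in_band(self):
        m, _ = simulate_nb_matrix(500, 10, 0.05, {}, seed=0)
        de = run_de(m, contrast="cell_type", levels=("FP", "DA"))
        p = de.table["pvalue"].dropna()
        assert 0.02 <= (p < 0.05).mean() <= 0.09

    def test_padj_significant_subset_of_raw(self):
        m, _ = simulate_nb_matrix(100, 5, 0.05, {0: 3.0}, seed=2)
        de = run_de(m, contrast="cell_type", levels=("FP", "DA"), alpha=0.05)
        t = de.table
        assert np.all(t["padj"].dropna() >= t.loc[t["padj"].notna(), "pvalue"])
        sig = t[t["significant"]]
        assert np.all(sig["pvalue"] < de.alpha)

    def test_infinite_filter_empties_table(self):
        m, _ = simulate_nb_matrix(50, 3, 0.05, {}, seed=3)
        de = run_de(m, contrast="cell_type", levels=("FP", "DA"), min_base_mean=np.inf)
        assert len(de.table) == 0
        assert de.n_excluded_low_expression == 50

    def test_unknown_contrast_rejected(self):
        m, _ = simulate_nb_matrix(10, 3, 0.05, {}, seed=4)
        with pytest.raises(ValueError, match="condition"):
            run_de(m, contrast="condition")

    def test_de_table_tsv_round_trip(self, tmp_path):
        from sclnc.diffexp import DETable

        m, _ = simulate_nb_matrix(30, 3, 0.05, {0: 2.0}, seed=5)
        de = run_de(m, contrast="cell_type", levels=("FP", "DA"))
        path = tmp_path / "de.tsv"
        de.write_tsv(str(path))
        back = DETable.read_tsv(str(path))
        assert back.contrast == "cell_type"
        assert back.levels == ("FP", "DA")
        assert back.alpha == de.alpha
        assert np.allclose(
            back.table["log2FoldChange"], de.table["log2FoldChange"], equal_nan=True
        )
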