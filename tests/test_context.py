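"""5 kb genomic-context rule, cis correlation and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from sclnc.annotation import GenomeAnnotation
from sclnc.context import (
    CodingIndex,
    cis_correlation,
    classify_genomic_context,
    distance_matrix,
    length_distribution,
    ma_table,
    pca_embedding,
    strand_tally,
)

from conftest import make_gene, oracle_nearest_gap


def _coding(gene_id, start, end, chrom="chr1", strand="+"):
    return make_gene(gene_id, chrom=chrom, strand=strand, exons=[(start, end)], biotype="coding")


class TestFiveKbRule:
    def _index(self, *genes):
        return CodingIndex(GenomeAnnotation(list(genes)))

    def test_overlap_is_intragenic_gap_zero(self):
        idx = self._index(_coding("PC1", 1000, 5000))
        lnc = make_gene("L1", exons=[(4000, 4500)])
        cls, pair = classify_genomic_context(lnc, idx)
        assert cls == "intragenic"
        assert pair.gap_bp == 0
        assert pair.relation == "overlapping_sense"

    def test_antisense_overlap_relation(self):
        idx = self._index(_coding("PC1", 1000, 5000, strand="-"))
        lnc = make_gene("L1", strand="+", exons=[(4000, 4500)])
        _, pair = classify_genomic_context(lnc, idx)
        assert pair.relation == "overlapping_antisense"

    @pytest.mark.parametrize(
        "gap,expected",
        [(0, "intragenic"), (1, "intragenic"), (4999, "intragenic"),
         (5000, "intragenic"), (5001, "intergenic"), (6000, "intergenic")],
    )
    def test_window_boundary(self, gap, expected):
        idx = self._index(_coding("PC1", 1000, 2000))
        # lncRNA placed exactly `gap` bp downstream of the coding span
        lnc = make_gene("L1", exons=[(2001 + gap, 2500 + gap)])
        cls, pair = classify_genomic_context(lnc, idx)
        assert cls == expected
        assert pair.gap_bp == gap

    def test_signed_offset_orientation(self):
        # coding gene on minus strand: a lncRNA to its right is upstream
        idx = self._index(_coding("PC1", 1000, 2000, strand="-"))
        lnc = make_gene("L1", exons=[(2501, 2900)])
        _, pair = classify_genomic_context(lnc, idx)
        assert pair.relation == "upstream"
        assert pair.signed_offset == -500

    def test_tie_broken_by_gene_id(self):
        idx = self._index(_coding("PCB", 1000, 2000), _coding("PCA", 3001, 4000))
        lnc = make_gene("L1", exons=[(2501, 2500 + 1)])  # 500 bp from both
        _, pair = classify_genomic_context(lnc, idx)
        assert pair.coding_id == "PCA"

    def test_no_coding_on_chromosome_is_intergenic(self):
        idx = self._index(_coding("PC1", 1000, 2000, chrom="chr9"))
        cls, pair = classify_genomic_context(make_gene("L1"), idx)
        assert cls == "intergenic" and pair is None

    def test_matches_brute_force_nearest_gap(self):
        rng = np.random.default_rng(21)
        coding = [
            _coding(f"PC{i:03d}", int(s), int(s) + int(rng.integers(500, 4000)),
                    chrom=f"chr{rng.integers(1, 3)}")
            for i, s in enumerate(rng.integers(1, 200_000, size=60))
        ]
        idx = CodingIndex(GenomeAnnotation(coding))
        for i in range(1000):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(1, 200_000))
            lnc = make_gene(f"L{i}", chrom=chrom, exons=[(start, start + int(rng.integers(200, 2500)))])
            cls, pair = classify_genomic_context(lnc, idx)
            want = oracle_nearest_gap(lnc, coding)
            if want is None:
                assert pair is None
            else:
                assert (pair.gap_bp, pair.coding_id) == want
                assert cls == ("intragenic" if want[0] <= 5000 else "intergenic")


class TestCisCorrelation:
    def _pairs(self, xy):
        return pd.DataFrame(
            {
                "lnc_id": [f"L{i}" for i in range(len(xy))],
                "coding_id": [f"P{i}" for i in range(len(xy))],
                "gap_bp": 0,
                "lnc_lfc": [a for a, _ in xy],
                "coding_lfc": [b for _, b in xy],
            }
        )

    def test_perfect_positive_linearity(self):
        r, n, _ = cis_correlation(self._pairs([(1, 2), (2, 4), (3, 6)]))
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_perfect_negative_linearity(self):
        r, _, _ = cis_correlation(self._pairs([(1, -1), (2, -2), (3, -3)]))
        assert r == pytest.approx(-1.0)

    def test_null_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        xy = rng.standard_normal((1000, 2))
        r, n, _ = cis_correlation(self._pairs([tuple(row) for row in xy]))
        assert abs(r) < 0.1
        assert n == 1000

    def test_zero_variance_undefined(self):
        r, _, _ = cis_correlation(self._pairs([(1, 1), (1, 2), (1, 3)]))
        assert np.isnan(r)

    def test_pair_order_invariance_and_symmetry(self):
        rng = np.random.default_rng(2)
        xy = [tuple(row) for row in rng.standard_normal((50, 2))]
        r1, _, _ = cis_correlation(self._pairs(xy))
        r2, _, _ = cis_correlation(self._pairs(xy[::-1]))
        r3, _, _ = cis_correlation(self._pairs([(b, a) for a, b in xy]))
        assert r1 == pytest.approx(r2)
        assert r1 == pytest.approx(r3)

    def test_sign_concordance_reported(self):
        _, _, table = cis_correlation(self._pairs([(1, 2), (-1, -3), (1, -1), (2, 5)]))
        assert table.attrs["sign_concordance"] == pytest.approx(0.75)


class TestSummaries:
    def test_strand_tally(self):
        genes = [make_gene(f"L{i}", strand=s) for i, s in enumerate("++-+-")]
        assert strand_tally(genes) == (3, 2)
        assert strand_tally([]) == (0, 0)

    def test_length_histogram_conserves_total(self):
        rng = np.random.default_rng(30)
        genes = []
        for i in range(200):
            start = 1000 * i + 1
            length = int(rng.integers(100, 6000))
            genes.append(make_gene(f"L{i}", exons=[(start, start + length - 1)]))
        counts, edges = length_distribution(genes)
        assert counts.sum() == 200

    def test_single_gene_binning(self):
        g = make_gene("L1", exons=[(101, 200)])  # length 100
        counts, _ = length_distribution([g], bins=[0, 200, np.inf])
        assert list(counts) == [1, 0]

    def test_planted_length_mixture_proportions(self):
        rng = np.random.default_rng(31)
        short = [make_gene(f"S{i}", exons=[(1, int(rng.integers(300, 500)))]) for i in range(300)]
        long_ = [make_gene(f"G{i}", exons=[(1, int(rng.integers(3000, 5000)))]) for i in range(100)]
        counts, _ = length_distribution(short + long_, bins=[0, 1000, np.inf])
        assert counts[0] == 300 and counts[1] == 100


class TestDistanceMatrix:
    def test_duplicate_column_zero_distance(self):
        m = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 7.0]])
        d = distance_matrix(m)
        assert d[0, 1] == pytest.approx(0.0)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_single_gene_delta_on_log_scale(self):
        # two samples differ in one gene by a factor of 8 -> 3 on log2(x+1)
        m = np.array([[0.0, 0.0], [7.0, 63.0]])
        d = distance_matrix(m)
        assert d[0, 1] == pytest.approx(np.log2(64) - np.log2(8))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(33)
        m = rng.uniform(0, 100, size=(40, 6))
        d = distance_matrix(m)
        logged = np.log2(m + 1)
        for i in range(6):
            for j in range(6):
                want = np.sqrt(((logged[:, i] - logged[:, j]) ** 2).sum())
                assert d[i, j] == pytest.approx(want)


class TestPCA:
    def test_planted_groups_separate_on_pc1(self):
        rng = np.random.default_rng(34)
        base = rng.uniform(10, 100, size=(50, 1))
        group_shift = np.concatenate([np.ones(5), 4 * np.ones(5)])
        m = base * group_shift[np.newaxis, :] * rng.lognormal(0, 0.05, size=(50, 10))
        coords, explained = pca_embedding(m)
        pc1 = coords[:, 0]
        assert max(pc1[:5]) < min(pc1[5:]) or min(pc1[:5]) > max(pc1[5:])
        assert explained[0] > 0.5

    def test_identical_columns_all_zero(self):
        m = np.tile(np.arange(1.0, 11.0)[:, np.newaxis], (1, 4))
        coords, explained = pca_embedding(m)
        assert np.allclose(coords, 0)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(35)
        m = rng.uniform(0, 50, size=(30, 8))
        c1, _ = pca_embedding(m)
        c2, _ = pca_embedding(m.copy())
        assert np.array_equal(c1, c2)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(36)
        m = rng.uniform(0, 50, size=(30, 8))
        _, ev = pca_embedding(m, n_components=5)
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9

    def test_truncation_warns(self):
        m = np.random.default_rng(37).uniform(0, 10, size=(20, 2))
        with pytest.warns(UserWarning, match="truncating"):
            coords, _ = pca_embedding(m, n_components=5)
        assert coords.shape == (2, 2)


class TestMATable:
    def _de(self):
        from sclnc.diffexp import run_de
        from sclnc.synthetic import simulate_nb_matrix

        m, _ = simulate_nb_matrix(40, 4, 0.05, {0: 3.0}, seed=6)
        return run_de(m, contrast="cell_type", levels=("FP", "DA"), alpha=0.05)

    def test_rows_and_flags_consistent(self):
        de = self._de()
        ma = ma_table(de)
        assert len(ma) == len(de.table)
        assert ma["significant"].equals(de.table["significant"])

    def test_log2_base_mean_of_one_is_zero(self):
        de = self._de()
        de.table.loc[0, "baseMean"] = 1.0
        assert ma_table(de).loc[0, "log2_baseMean"] == pytest.approx(0.0)
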