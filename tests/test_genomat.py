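"""Genotype QC, imputation, kinship, PCA, and cross-panel comparison."""

import numpy as np
import pandas as pd
import pytest

from wheatgs import genomat, syndata
from wheatgs.genomat import (
    GenotypeMatrix,
    additive_relationship,
    common_markers,
    filter_markers,
    impute_em,
    pca_scores,
    read_genotypes,
    simple_matching,
)


def make_g(values, line_prefix="L", marker_prefix="m"):
    values = np.asarray(values, float)
    return GenotypeMatrix(
        values,
        [f"{line_prefix}{i}" for i in range(values.shape[0])],
        [f"{marker_prefix}{j}" for j in range(values.shape[1])],
    )


class TestContainer:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(np.zeros((2, 2)), ["a", "a"], ["m1", "m2"])
        with pytest.raises(ValueError):
            GenotypeMatrix(np.zeros((2, 2)), ["a", "b"], ["m1", "m1"])

    def test_out_of_range_codes_rejected(self):
        with pytest.raises(ValueError):
            make_g([[2.0, 0.0]])

    def test_vcf_import(self, tmp_path):
        """Biallelic sites map to -1/0/1 (het -> 0, missing -> NaN);
        multi-allelic sites are skipped with a warning."""
        cyvcf2 = pytest.importorskip("cyvcf2")
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\tL3\n"
            "chr1\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t1/1\t0/1\n"
            "chr1\t200\tm2\tC\tT\t.\t.\t.\tGT\t1/1\t./.\t0/0\n"
            "chr1\t300\tm3\tG\tA,C\t.\t.\t.\tGT\t0/0\t1/1\t2/2\n"
        )
        with pytest.warns(UserWarning, match="multi-allelic"):
            g = genomat.read_vcf(vcf)
        assert g.marker_ids == ["m1", "m2"]
        assert g.line_ids == ["L1", "L2", "L3"]
        assert list(g.values[:, 0]) == [-1.0, 1.0, 0.0]
        assert g.values[0, 1] == 1.0 and np.isnan(g.values[1, 1]) and g.values[2, 1] == -1.0

    def test_tsv_roundtrip(self, panel, tmp_path):
        g, _ = panel
        g.write(tmp_path / "g.tsv", tmp_path / "map.csv")
        back = read_genotypes(tmp_path / "g.tsv", tmp_path / "map.csv")
        assert back.line_ids == g.line_ids
        assert back.marker_ids == g.marker_ids
        assert np.allclose(back.values, g.values)


class TestFilterMarkers:
    def test_monomorphic_removed(self):
        g = make_g([[1, 1], [1, -1], [1, 1], [1, -1]])
        out = filter_markers(g, maf_min=0.01, max_missing=1.0)
        assert out.marker_ids == ["m1"]

    def test_noop_thresholds_are_identity(self, panel):
        g, _ = panel
        out = filter_markers(g, maf_min=0.0, max_missing=1.0)
        assert out.marker_ids == g.marker_ids

    def test_hand_computed_mafs(self):
        # columns have MAF 0.0, 0.125, 0.25, 0.5, 0.375 over 4 lines
        g = make_g(
            [
                [-1, -1, -1, 1, 1],
                [-1, -1, -1, 1, 0],
                [-1, -1, 1, -1, -1],
                [-1, 0, -1, -1, -1],
            ]
        )
        assert np.allclose(g.maf(), [0.0, 0.125, 0.25, 0.5, 0.375])
        out = filter_markers(g, maf_min=0.2, max_missing=1.0)
        assert out.marker_ids == ["m2", "m3", "m4"]

    def test_high_missing_removed(self):
        vals = np.array([[1, 1], [-1, np.nan], [1, np.nan], [-1, np.nan]])
        out = filter_markers(make_g(vals), maf_min=0.0, max_missing=0.5)
        assert out.marker_ids == ["m0"]

    def test_nothing_survives_is_error(self):
        g = make_g([[1, 1], [1, 1]])
        with pytest.raises(ValueError):
            filter_markers(g, maf_min=0.05, max_missing=0.2)


class TestImputeEm:
    def test_no_missing_is_identity(self, panel):
        g, _ = panel
        out = impute_em(g)
        assert out is g or np.array_equal(out.values, g.values)

    def test_single_marker_imputes_observed_mean(self):
        g = make_g(np.array([[1.0], [-1.0], [1.0], [1.0], [np.nan]]))
        out = impute_em(g)
        assert out.values[4, 0] == pytest.approx(0.5)

    def test_beats_column_mean_under_structure(self):
        """Conditional-expectation imputation exploits LD/structure that
        per-column means cannot, so its RMSE must be strictly lower."""
        spec = syndata.PanelSpec(n_lines=120, n_markers=300, n_subpops=3, fst=0.3,
                                 maf_range=(0.1, 0.5), n_chroms=3, seed=21)
        g, _ = syndata.simulate_panel(spec)
        masked, mask = syndata.mask_genotypes(g, 0.05, seed=22)
        out = impute_em(masked)
        col_mean = np.nanmean(masked.values, axis=0)
        mean_fill = np.where(mask, col_mean[None, :], masked.values)
        rmse_em = np.sqrt(np.mean((out.values[mask] - g.values[mask]) ** 2))
        rmse_mean = np.sqrt(np.mean((mean_fill[mask] - g.values[mask]) ** 2))
        assert rmse_em < rmse_mean

    def test_observed_entries_untouched_and_range_clipped(self, panel):
        g, _ = panel
        masked, mask = syndata.mask_genotypes(g, 0.1, seed=31)
        out = impute_em(masked)
        assert np.array_equal(out.values[~mask], g.values[~mask])
        assert out.values[mask].min() >= -1.0 and out.values[mask].max() <= 1.0

    def test_idempotent(self, panel):
        g, _ = panel
        masked, _ = syndata.mask_genotypes(g, 0.05, seed=41)
        once = impute_em(masked)
        twice = impute_em(once)
        assert np.array_equal(once.values, twice.values)

    def test_all_missing_marker_is_error(self):
        vals = np.array([[1.0, np.nan], [-1.0, np.nan]])
        with pytest.raises(ValueError, match="m1"):
            impute_em(make_g(vals))

    def test_commutes_with_line_reordering(self):
        spec = syndata.PanelSpec(n_lines=40, n_markers=60, n_chroms=2, seed=51)
        g, _ = syndata.simulate_panel(spec)
        masked, _ = syndata.mask_genotypes(g, 0.1, seed=52)
        perm = np.random.default_rng(53).permutation(40)
        direct = impute_em(filter_markers(masked, 0.05, 0.5)).take_lines(perm)
        permuted = impute_em(filter_markers(masked.take_lines(perm), 0.05, 0.5))
        assert direct.line_ids == permuted.line_ids
        assert np.allclose(direct.values, permuted.values, atol=1e-8)


class TestAdditiveRelationship:
    def test_identical_lines_share_diagonal(self):
        vals = np.array([[1, -1, 1, -1], [1, -1, 1, -1], [-1, 1, -1, 1]], float)
        k = additive_relationship(make_g(vals))
        assert k.values[0, 1] == pytest.approx(k.values[0, 0])

    def test_rows_sum_to_zero(self, panel):
        g, _ = panel
        k = additive_relationship(g)
        assert np.allclose(k.values.sum(axis=1), 0.0, atol=1e-10)

    def test_matches_hand_computation(self):
        vals = np.array([[1, -1, 1, 1], [-1, -1, 1, -1], [1, 1, -1, -1]], float)
        g = make_g(vals)
        # brute-force oracle: explicit centering and scaling loops
        p = np.array([np.mean((vals[:, j] + 1) / 2) for j in range(4)])
        w = np.array([[vals[i, j] - vals[:, j].mean() for j in range(4)] for i in range(3)])
        c = 2 * sum(pj * (1 - pj) for pj in p)
        expected = np.array(
            [[sum(w[i, j] * w[k, j] for j in range(4)) / c for k in range(3)] for i in range(3)]
        )
        assert np.allclose(additive_relationship(g).values, expected)

    def test_psd_on_random_panels(self):
        rng = np.random.default_rng(61)
        for _ in range(100):
            vals = rng.choice([-1.0, 1.0], size=(12, 20))
            if np.ptp(vals, axis=0).sum() == 0:
                continue
            assert additive_relationship(make_g(vals)).is_psd()

    def test_all_monomorphic_is_error(self):
        with pytest.raises(ValueError):
            additive_relationship(make_g([[1, 1], [1, 1]]))


class TestPcaScores:
    def test_separates_diverged_subpops(self):
        spec = syndata.PanelSpec(n_lines=200, n_markers=500, n_subpops=2, fst=0.3,
                                 maf_range=(0.1, 0.5), n_chroms=4, seed=71)
        g, labels = syndata.simulate_panel(spec)
        pc1 = pca_scores(g, 1)[:, 0]
        best = max(
            max((pc1 > t) == labels.astype(bool), (pc1 <= t) == labels.astype(bool),
                key=lambda m: m.mean()).mean()
            for t in np.quantile(pc1, np.linspace(0.05, 0.95, 50))
        )
        assert best >= 0.95

    def test_duplicate_lines_get_identical_scores(self):
        vals = np.array([[1, -1, 1, -1, 1], [1, -1, 1, -1, 1], [-1, 1, -1, 1, -1],
                         [1, 1, -1, -1, 1]], float)
        s = pca_scores(make_g(vals), 2)
        assert np.allclose(s[0], s[1])

    def test_variance_explained_non_increasing(self, panel):
        g, _ = panel
        s = pca_scores(g, 5)
        variances = s.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_invalid_n_pc(self, panel):
        g, _ = panel
        with pytest.raises(ValueError):
            pca_scores(g, 0)


class TestCommonMarkersAndMatching:
    def test_identical_sets_unchanged(self, panel):
        g, _ = panel
        a, b = common_markers(g, g)
        assert a.marker_ids == b.marker_ids == g.marker_ids

    def test_set_intersection_order(self):
        g1 = GenotypeMatrix(np.zeros((2, 3)), ["x", "y"], ["a", "b", "c"])
        g2 = GenotypeMatrix(np.zeros((2, 3)), ["x", "y"], ["b", "c", "d"])
        a, b = common_markers(g1, g2)
        assert a.marker_ids == b.marker_ids == ["b", "c"]

    def test_empty_intersection_is_error(self):
        g1 = GenotypeMatrix(np.zeros((2, 1)), ["x", "y"], ["a"])
        g2 = GenotypeMatrix(np.zeros((2, 1)), ["x", "y"], ["b"])
        with pytest.raises(ValueError):
            common_markers(g1, g2)

    def test_constructed_overlap_count(self, panel):
        g, _ = panel
        sub = g.take_markers(np.arange(100))
        renamed = GenotypeMatrix(
            np.column_stack([sub.values, np.ones((g.n_lines, 2))]),
            sub.line_ids, sub.marker_ids + ["zz1", "zz2"],
        )
        a, b = common_markers(g, renamed)
        assert a.n_markers == b.n_markers == 100

    def test_self_matching_is_one(self, panel):
        g, _ = panel
        sub = g.take_lines(np.arange(5))
        mean, mat = simple_matching(sub, sub)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)

    def test_direct_count(self):
        g1 = GenotypeMatrix(np.array([[1.0, -1.0, 1.0, 1.0]]), ["a"], list("wxyz"))
        g2 = GenotypeMatrix(np.array([[1.0, -1.0, 1.0, -1.0]]), ["b"], list("wxyz"))
        mean, _ = simple_matching(g1, g2)
        assert mean == pytest.approx(0.75)

    def test_related_cross_matches_better_than_unrelated_panel(self, panel):
        g, _ = panel
        prog = syndata.simulate_biparental(
            g.values[0], g.values[1], 40, "DH", g.genetic_map, seed=81
        )
        other, _ = syndata.simulate_panel(
            syndata.PanelSpec(n_lines=40, n_markers=400, n_subpops=2, fst=0.4,
                              maf_range=(0.05, 0.5), n_chroms=5, seed=99)
        )
        other = GenotypeMatrix(other.values, [f"U{i}" for i in range(40)], g.marker_ids,
                               g.genetic_map)
        related, _ = simple_matching(g, prog)
        unrelated, _ = simple_matching(g, other)
        assert related > unrelated

    def test_mismatched_marker_sets_rejected(self, panel):
        g, _ = panel
        with pytest.raises(ValueError):
            simple_matching(g, g.take_markers(np.arange(10)))
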