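import numpy as np
import pandas as pd
import pytest

from fourdn import centrality, feature_analyzer as fa, synthetic
from fourdn.errors import AlignmentError, ValidationError
from fourdn.genome_model import BinIndex, ExpressionTrack, GeneTable


def toy_pair(rng, n=20, seed_track=None):
    cfg = synthetic.SimConfig(n_bins=n, block_size=max(n // 4, 2), seed=3)
    H = synthetic.simulate_hic(cfg)
    r = synthetic.simulate_expression(cfg)
    return H, r


class TestBuildFeatureMatrix:
    def test_columns_equal_standalone_calls(self, rng):
        H, r = toy_pair(rng, 30)
        fm = fa.build_feature_matrix(H, r)
        cen = centrality.all_centralities(H)
        m = H.mask
        assert np.array_equal(fm.values[:, 0], cen["degree"].values[m])
        assert np.array_equal(fm.values[:, 1], cen["eigenvector"].values[m])
        assert np.array_equal(fm.values[:, 2], cen["betweenness"].values[m])
        assert np.array_equal(fm.values[:, 3], cen["closeness"].values[m])
        assert np.array_equal(fm.values[:, 4], r.values[m])
        assert fm.values.shape[1] == 5

    def test_zero_expression_zero_fifth_column(self, rng):
        H, r = toy_pair(rng, 12)
        r0 = ExpressionTrack(r.bins, np.zeros(12))
        fm = fa.build_feature_matrix(H, r0)
        assert np.all(fm.values[:, 4] == 0)

    def test_bin_mismatch_rejected(self, rng):
        H, r = toy_pair(rng, 12)
        other = ExpressionTrack(BinIndex.from_range("chrX", 100, 12),
                                np.zeros(12))
        with pytest.raises(AlignmentError):
            fa.build_feature_matrix(H, other)


class TestFirstPrincipalComponent:
    def test_two_block_matrix_split_by_sign(self, hic_factory):
        n = 12
        lab = np.arange(n) < n // 2
        A = np.where(np.outer(lab, lab) | np.outer(~lab, ~lab), 1.0, 0.1)
        np.fill_diagonal(A, 1.0)
        pc1 = fa.first_principal_component(hic_factory(A))
        sign = pc1 > 0
        assert np.array_equal(sign, lab) or np.array_equal(sign, ~lab)

    def test_constant_matrix_warns_zero(self, hic_factory):
        with pytest.warns(UserWarning, match="degenerate"):
            pc1 = fa.first_principal_component(hic_factory(np.ones((6, 6))))
        assert np.all(pc1 == 0)

    def test_matches_eigendecomposition_oracle(self, rng,
                                               random_hic_factory):
        from fourdn import hic_norm

        H = random_hic_factory(rng, 15)
        pc1 = fa.first_principal_component(H)
        C = hic_norm.correlation_matrix(H).values
        Xc = C - C.mean(axis=0, keepdims=True)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        lead = V[:, -1]
        exp = Xc @ lead
        s = np.sign(pc1 @ exp) or 1.0
        assert np.abs(pc1 - s * exp).max() < 1e-8


class TestNormalizeFeatures:
    def test_constant_column_maps_to_zero(self, rng):
        H, r = toy_pair(rng, 12)
        fm = fa.build_feature_matrix(H, r)
        fm.values[:, 4] = 3.14
        out = fa.normalize_features([fm])
        assert np.all(out[0].values[:, 4] == 0)

    def test_joint_zscore_mean_zero_sd_one(self, rng):
        mats = []
        for t in range(3):
            cfg = synthetic.SimConfig(n_bins=25, block_size=5, seed=t)
            H = synthetic.simulate_hic(cfg)
            r = synthetic.simulate_expression(cfg)
            fm = fa.build_feature_matrix(H, r)
            fm.timepoint = t
            mats.append(fm)
        out = fa.normalize_features(mats)
        X = np.vstack([f.values for f in out])
        assert np.abs(X.mean(axis=0)).max() < 1e-12
        assert np.abs(X.std(axis=0) - 1.0).max() < 1e-12

    def test_identical_matrices_stay_identical(self, rng):
        H, r = toy_pair(rng, 12)
        fm = fa.build_feature_matrix(H, r)
        out = fa.normalize_features([fm, fm])
        assert np.array_equal(out[0].values, out[1].values)


class TestRankChanges:
    def make_stack(self, rows_list):
        bins = BinIndex.from_range("chr1", 100, len(rows_list[0]))
        ids = np.arange(len(rows_list[0]))
        return [fa.FeatureMatrix(np.asarray(v, float), bins, ids,
                                 timepoint=t)
                for t, v in enumerate(rows_list)]

    def test_identical_rows_score_zero(self):
        X = np.ones((4, 5))
        stack = self.make_stack([X, X, X])
        rk = fa.rank_changes(stack)
        assert np.all(rk.scores == 0)

    def test_pythagorean_score(self):
        X0 = np.zeros((3, 5))
        X1 = np.zeros((3, 5))
        X1[1, 0] = 3.0
        X1[1, 1] = 4.0
        rk = fa.rank_changes(self.make_stack([X0, X1]))
        assert rk.scores[1] == pytest.approx(5.0)
        assert rk.top_bin_ids[0] == 1

    def test_single_timepoint_rejected(self):
        stack = self.make_stack([np.zeros((3, 5))])
        with pytest.raises(ValidationError, match="timepoint"):
            fa.rank_changes(stack)

    def test_affine_invariance_through_normalization(self, rng):
        # shifting any raw feature column leaves ranks untouched after z-score
        mats = []
        for t in range(2):
            cfg = synthetic.SimConfig(n_bins=25, block_size=5, seed=10 + t)
            H = synthetic.simulate_hic(cfg)
            r = synthetic.simulate_expression(cfg)
            fm = fa.build_feature_matrix(H, r)
            fm.timepoint = t
            mats.append(fm)
        base = fa.rank_changes(fa.normalize_features(mats))
        shifted = []
        for f in mats:
            g = fa.FeatureMatrix(f.values + np.array([5.0, 0, -2.0, 0, 1.0]),
                                 f.bins, f.bin_ids, f.timepoint)
            shifted.append(g)
        alt = fa.rank_changes(fa.normalize_features(shifted))
        assert np.abs(base.scores - alt.scores).max() < 1e-10

    def test_depends_only_on_timepoint_order(self):
        rng = np.random.default_rng(5)
        X = [rng.normal(size=(6, 5)) for _ in range(3)]
        a = fa.rank_changes(self.make_stack(X))
        relabeled = self.make_stack(X)
        for f, t in zip(relabeled, [10.0, 20.5, 99.0]):
            f.timepoint = t
        b = fa.rank_changes(relabeled)
        assert np.array_equal(a.order, b.order)
        assert np.abs(a.scores - b.scores).max() < 1e-15


class TestGeneReport:
    def ranking(self, n=5, scores=None):
        bins = BinIndex.from_range("chr1", 100, n)
        scores = np.arange(n, dtype=float) if scores is None else scores
        order = np.argsort(-scores, kind="stable")
        return fa.ChangeRanking(np.arange(n), scores, order, bins, top_k=3)

    def genes(self, rows):
        return GeneTable(pd.DataFrame(rows, columns=["symbol", "chrom",
                                                     "start", "end", "tpm"]))

    def test_urls_contain_symbol(self):
        g = self.genes([("MYOD1", "chr1", 410, 460, 5.0)])
        rep = fa.gene_report(self.ranking(), g)
        top = rep.records.iloc[0]
        assert top.genes == "MYOD1"
        assert "MYOD1" in top.ncbi_urls and "ncbi" in top.ncbi_urls
        assert "MYOD1" in top.genecards_urls

    def test_locus_without_genes_empty(self):
        rep = fa.gene_report(self.ranking(), self.genes([]))
        assert all(rep.records["genes"] == "")

    def test_overlap_join_matches_bruteforce(self, rng):
        n = 10
        bins = BinIndex.from_range("chr1", 100, n)
        scores = rng.random(n)
        order = np.argsort(-scores, kind="stable")
        rk = fa.ChangeRanking(np.arange(n), scores, order, bins, top_k=3)
        starts = rng.integers(0, 900, size=15)
        g = self.genes([(f"g{i}", "chr1", s, s + 80, 1.0)
                        for i, s in enumerate(starts)])
        rep = fa.gene_report(rk, g)
        for rec in rep.records.itertuples(index=False):
            expected = sorted(
                row.symbol for row in g.df.itertuples(index=False)
                if row.start < rec.end and row.end > rec.start)
            assert rec.genes.split(",") if rec.genes else [] == expected

    def test_report_sorted_by_descending_score(self, rng):
        rep = fa.gene_report(self.ranking(), self.genes([]))
        s = rep.records["score"].to_numpy()
        assert np.all(np.diff(s) <= 0)

    def test_html_and_tsv_written(self, tmp_path):
        # TP53 placed inside the top-ranked locus (bin 4: 400-500)
        g = self.genes([("TP53", "chr1", 410, 490, 2.0)])
        rep = fa.gene_report(self.ranking(), g)
        rep.to_tsv(tmp_path / "r.tsv")
        rep.to_html(tmp_path / "r.html")
        assert "genecards.org" in (tmp_path / "r.html").read_text()
        assert len(pd.read_csv(tmp_path / "r.tsv", sep="\t")) == 3
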