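import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from screg import links as lk
from screg import synth
from screg._types import CoaccessLinkSet, LsiEmbedding, NucleusFeatureMatrix


class TestWeightedGraphicalLasso:
    def test_uniform_penalty_matches_sklearn(self):
        # sklearn's GraphicalLasso is the independent cross-check at a
        # scalar penalty; the weighted solver must agree there
        from sklearn.covariance import GraphicalLasso

        rng = np.random.default_rng(0)
        A = rng.normal(size=(500, 5))
        A[:, 1] += 0.8 * A[:, 0]
        S = np.cov(A, rowvar=False)
        alpha = 0.1
        P = np.full((5, 5), alpha)
        np.fill_diagonal(P, 0.0)
        W, theta = lk.weighted_graphical_lasso(S, P, max_iter=200, tol=1e-8)
        ref = GraphicalLasso(alpha=alpha, covariance="precomputed", tol=1e-10).fit(S)
        np.testing.assert_allclose(theta, ref.precision_, atol=5e-3)

    def test_heavy_penalty_zeroes_offdiagonal(self):
        rng = np.random.default_rng(1)
        S = np.cov(rng.normal(size=(100, 4)), rowvar=False)
        P = np.full((4, 4), 100.0)
        np.fill_diagonal(P, 0.0)
        _, theta = lk.weighted_graphical_lasso(S, P)
        off = theta[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0, atol=1e-10)


class TestDistanceParam:
    def test_d0_within_factor_two_of_planted_scale(self, linked_accessibility):
        # links planted only at 10-kb spacing: the optimal decay scale
        # must land within a factor 2 of the window/10 = 10 kb grid point
        mat, peaks, _ = linked_accessibility
        d0, lam = lk.estimate_distance_param(
            mat, peaks, n_regions=30, window=100_000, seed=0,
            d0_grid=np.array([2_000, 5_000, 10_000, 20_000, 50_000]),
        )
        assert 5_000 <= d0 <= 20_000
        assert lam > 0

    def test_seed_reproducible(self, linked_accessibility):
        mat, peaks, _ = linked_accessibility
        kw = dict(n_regions=10, window=100_000, d0_grid=np.array([5_000, 20_000]))
        a = lk.estimate_distance_param(mat, peaks, seed=3, **kw)
        b = lk.estimate_distance_param(mat, peaks, seed=3, **kw)
        assert a == b

    def test_too_few_peaks_rejected(self):
        rng = np.random.default_rng(2)
        mat = NucleusFeatureMatrix(
            sp.csr_matrix(rng.poisson(2, size=(20, 2))),
            [f"n{i}" for i in range(20)], ["a", "b"], feature_kind="peak",
        )
        peaks = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 1000],
                              "end": [400, 1400]})
        with pytest.raises(ValueError):
            lk.estimate_distance_param(mat, peaks, n_regions=5, window=10_000)


class TestCoaccessScan:
    @pytest.fixture(scope="class")
    def scan(self, linked_accessibility):
        mat, peaks, _ = linked_accessibility
        d0, lam = lk.estimate_distance_param(
            mat, peaks, n_regions=30, window=100_000, seed=0,
            d0_grid=np.array([5_000, 10_000, 20_000]),
        )
        return lk.coaccess_scan(mat, peaks, d0, lam, window=100_000, step=50_000)

    def test_planted_pairs_recovered(self, linked_accessibility, scan):
        mat, _, true_pairs = linked_accessibility
        names = list(mat.features)
        ts = {frozenset((names[i], names[j])) for i, j in true_pairs}
        cutoff = lk.choose_cutoff(scan)
        df = scan.links
        sel = df[np.abs(df["score"]) >= cutoff]
        hits = {frozenset((a, b)) for a, b in zip(sel["a"], sel["b"])}
        precision = len(hits & ts) / len(hits)
        recall = len(hits & ts) / len(ts)
        assert precision >= 0.8 and recall >= 0.8

    def test_null_pairs_score_near_zero(self, linked_accessibility, scan):
        mat, _, true_pairs = linked_accessibility
        names = list(mat.features)
        ts = {frozenset((names[i], names[j])) for i, j in true_pairs}
        df = scan.links
        null = df[[frozenset((a, b)) not in ts for a, b in zip(df["a"], df["b"])]]
        true = df[[frozenset((a, b)) in ts for a, b in zip(df["a"], df["b"])]]
        assert np.abs(null["score"]).max() < np.abs(true["score"]).min()

    def test_each_pair_reported_once(self, scan):
        keys = {frozenset((a, b)) for a, b in zip(scan.links["a"], scan.links["b"])}
        assert len(keys) == len(scan.links)

    def test_no_links_beyond_window(self, scan):
        assert (scan.links["distance"] <= 100_000).all()

    def test_discard_fraction_moderate(self, scan):
        n_disc = scan.links.attrs["n_discarded"]
        n_pairs = scan.links.attrs["n_pairs"]
        assert 0 <= n_disc / n_pairs <= 0.15


class TestChooseCutoff:
    def test_cutoff_separates_two_regimes(self, linked_accessibility):
        mat, peaks, true_pairs = linked_accessibility
        d0, lam = lk.estimate_distance_param(
            mat, peaks, n_regions=30, window=100_000, seed=0,
            d0_grid=np.array([10_000]),
        )
        scan = lk.coaccess_scan(mat, peaks, d0, lam, window=100_000, step=50_000)
        cutoff = lk.choose_cutoff(scan)
        names = list(mat.features)
        ts = {frozenset((names[i], names[j])) for i, j in true_pairs}
        df = scan.links
        is_true = np.array([frozenset((a, b)) in ts for a, b in zip(df["a"], df["b"])])
        noise_max = np.abs(df.loc[~is_true, "score"]).max()
        true_min = np.abs(df.loc[is_true, "score"]).min()
        assert noise_max < cutoff <= true_min

    def test_cutoff_in_grid(self):
        links = CoaccessLinkSet(
            pd.DataFrame({"a": ["x", "y"], "b": ["y", "z"],
                          "score": [0.5, 0.01], "distance": [1, 1], "n_windows": [1, 1]})
        )
        grid = np.array([0.05, 0.1, 0.2])
        assert lk.choose_cutoff(links, grid=grid) in grid

    def test_component_count_monotone(self, linked_accessibility):
        import igraph

        mat, peaks, _ = linked_accessibility
        d0, lam = lk.estimate_distance_param(
            mat, peaks, n_regions=10, window=100_000, seed=0,
            d0_grid=np.array([10_000]),
        )
        scan = lk.coaccess_scan(mat, peaks, d0, lam, window=100_000, step=50_000)
        df = scan.links
        nodes = sorted(set(df["a"]) | set(df["b"]))
        nidx = {n: i for i, n in enumerate(nodes)}
        counts = []
        for t in np.quantile(np.abs(df["score"]), [0.1, 0.5, 0.9]):
            sub = df[np.abs(df["score"]) >= t]
            g = igraph.Graph(n=len(nodes),
                             edges=[(nidx[a], nidx[b]) for a, b in zip(sub["a"], sub["b"])])
            counts.append(len(g.connected_components()))
        assert counts == sorted(counts)


class TestGeneActivity:
    def _single_link(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(3, size=(40, 1)) + 1
        mat = NucleusFeatureMatrix(sp.csr_matrix(X), [f"n{i}" for i in range(40)],
                                   ["chr1:0-400"], feature_kind="peak")
        links = CoaccessLinkSet(
            pd.DataFrame({"a": ["chr1:0-400"], "b": ["geneA"], "score": [1.0],
                          "distance": [100], "n_windows": [1]}),
            kind="region-tss",
        )
        return mat, links, X

    def test_single_unit_link_is_scaled_counts(self):
        mat, links, X = self._single_link()
        out = lk.gene_activity(mat, links, embedding=None, nn=1)
        act = np.asarray(out.values.todense()).ravel()
        # proportional to the counts up to the per-nucleus size factor
        corr = np.corrcoef(act, X.ravel())[0, 1]
        assert corr > 0.9

    def test_nn_one_smoothing_is_identity(self):
        mat, links, _ = self._single_link()
        emb = LsiEmbedding(np.random.default_rng(4).normal(size=(40, 3)),
                           [f"n{i}" for i in range(40)], [0, 1, 2])
        a = lk.gene_activity(mat, links, embedding=None)
        b = lk.gene_activity(mat, links, embedding=emb, nn=1)
        np.testing.assert_allclose(np.asarray(a.values.todense()),
                                   np.asarray(b.values.todense()))

    def test_unlinked_gene_zero(self):
        mat, links, _ = self._single_link()
        links.links.loc[0, "score"] = -0.5  # negative scores are ignored
        out = lk.gene_activity(mat, links)
        assert np.asarray(out.values.todense()).sum() == 0

    def test_linked_gene_tracks_cluster_accessibility(self, linked_accessibility):
        mat, peaks, _ = linked_accessibility
        links = CoaccessLinkSet(
            pd.DataFrame({"a": [mat.features[0]], "b": ["g0"], "score": [1.0],
                          "distance": [5_000], "n_windows": [1]}),
            kind="region-tss",
        )
        out = lk.gene_activity(mat, links, nn=1)
        act = np.asarray(out.values.todense()).ravel()
        acc = np.asarray(mat.values[:, 0].todense()).ravel()
        assert np.corrcoef(act, acc)[0, 1] > 0.8


class TestLinkCcres:
    @pytest.fixture(scope="class")
    def ccre_world(self, multiome_world):
        genome, truth, frags, rna = multiome_world
        mat = synth.peak_matrix(frags, truth.regions)
        real = lk.link_ccres(mat, rna.matrix, truth.regions, truth.gene_tss,
                             50_000, 0.01, window=150_000, step=75_000, cutoff=0.0)
        return genome, truth, mat, rna, real

    def test_true_links_recovered(self, ccre_world):
        genome, truth, mat, rna, out = ccre_world
        regions = truth.regions
        name_of = dict(zip(
            [f"{c}:{s}-{e}" for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])],
            regions["name"],
        ))
        got = {(name_of.get(a), b) for a, b in zip(out.links["a"], out.links["b"])}
        # rank candidate pairs by score and measure recovery of true links
        # reachable within the window
        tss = truth.gene_tss.set_index("name")
        reachable = set()
        centre = dict(zip(regions["name"], (regions["start"] + regions["end"]) // 2))
        for r, g in truth.true_links:
            if abs(int(tss.loc[g, "start"]) - int(centre[r])) <= 150_000:
                reachable.add((r, g))
        # recall at a false-positive rate of 10% over all scored pairs
        scored = out.links.sort_values("score", ascending=False)
        pairs = [(name_of.get(a), b) for a, b in zip(scored["a"], scored["b"])]
        is_true = np.array([p in reachable for p in pairs])
        n_neg = (~is_true).sum()
        fp_budget = int(0.1 * n_neg)
        cum_fp = np.cumsum(~is_true)
        k = int(np.searchsorted(cum_fp, fp_budget))
        recall = is_true[:k].sum() / len(reachable)
        assert recall >= 0.8

    def test_shuffled_expression_yields_no_strong_links(self, ccre_world):
        genome, truth, mat, rna, real = ccre_world
        rng = np.random.default_rng(0)
        R = np.asarray(rna.matrix.values.todense())
        R = R[rng.permutation(len(R))]
        shuffled = NucleusFeatureMatrix(sp.csr_matrix(R), rna.matrix.nuclei,
                                        rna.matrix.features, feature_kind="gene")
        null = lk.link_ccres(mat, shuffled, truth.regions, truth.gene_tss,
                             50_000, 0.01, window=150_000, step=75_000, cutoff=0.0)
        assert np.abs(null.links["score"]).max() < np.abs(real.links["score"]).max() * 0.5

    def test_distances_bounded(self, ccre_world):
        genome, truth, mat, rna, out = ccre_world
        assert (out.links["distance"] <= 150_000).all()

    def test_no_shared_nuclei_rejected(self, ccre_world):
        genome, truth, mat, rna, _ = ccre_world
        other = NucleusFeatureMatrix(rna.matrix.values, [f"zz{i}" for i in range(rna.matrix.shape[0])],
                                     rna.matrix.features, feature_kind="gene")
        with pytest.raises(ValueError):
            lk.link_ccres(mat, other, truth.regions, truth.gene_tss, 50_000, 0.01)
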