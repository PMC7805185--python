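"""Rank tests, ordination, imputation, correlation and clustering, each
checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata, spearmanr

import semipep as sp
from semipep.stats import results_frame


# ---------------------------------------------------------------------------
# independent textbook-formula oracles

def oracle_kw_dunn(samples):
    """Kruskal-Wallis H (tie corrected) and Dunn pairwise z from the
    textbook formulas, computed from scratch."""
    all_vals = np.concatenate(samples)
    n = len(all_vals)
    ranks = rankdata(all_vals)
    splits = np.cumsum([len(s) for s in samples])[:-1]
    group_ranks = np.split(ranks, splits)
    h = (12.0 / (n * (n + 1))
         * sum(len(g) * (g.mean() - (n + 1) / 2.0) ** 2 for g in group_ranks))
    _, t = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (t ** 3 - t).sum() / float(n ** 3 - n)
    h /= tie
    sigma2 = n * (n + 1) / 12.0 - (t ** 3 - t).sum() / (12.0 * (n - 1))
    zs = {}
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            num = group_ranks[i].mean() - group_ranks[j].mean()
            se = np.sqrt(sigma2 * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
            zs[(i, j)] = num / se
    return h, zs


def oracle_bh(p):
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * n / (rank_idx + 1))
        q[i] = prev
    return q


def oracle_pcoa(D, k):
    D = np.asarray(D, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    return evals, evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0))


def _feature_frame(groups_values, samples=None):
    vals = np.concatenate(groups_values)
    cols = samples or [f"s{i}" for i in range(len(vals))]
    groups = {}
    k = 0
    for gi, gv in enumerate(groups_values):
        for _ in gv:
            groups[cols[k]] = f"g{gi}"
            k += 1
    return pd.DataFrame([vals], index=["f"], columns=cols), groups


class TestKruskalDunn:
    def test_identical_groups_null(self):
        table, groups = _feature_frame([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        (res,) = sp.kruskal_dunn(table, groups)
        assert res.p_kw > 0.9
        assert res.significant_pairs(0.05) == []

    def test_separated_groups_match_rank_formula(self):
        samples = [np.array([1., 2., 3.]), np.array([4., 5., 6.]),
                   np.array([7., 8., 9.])]
        table, groups = _feature_frame(samples)
        (res,) = sp.kruskal_dunn(table, groups)
        h, zs = oracle_kw_dunn(samples)
        assert res.h_statistic == pytest.approx(h, abs=1e-10)
        got = {tuple(pw.pair): pw.z for pw in res.pairwise}
        for (i, j), z in zs.items():
            assert got[(f"g{i}", f"g{j}")] == pytest.approx(z, abs=1e-10)

    def test_adjusted_p_is_bonferroni(self, rng):
        samples = [rng.normal(size=6), rng.normal(1, size=6),
                   rng.normal(2, size=6)]
        table, groups = _feature_frame(samples)
        (res,) = sp.kruskal_dunn(table, groups)
        for pw in res.pairwise:
            assert pw.p_adj == pytest.approx(min(1.0, pw.p_raw * 3))
            assert pw.p_adj >= pw.p_raw

    def test_missing_dropped_per_feature(self):
        table, groups = _feature_frame(
            [[1.0, 2.0, np.nan], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        (res,) = sp.kruskal_dunn(table, groups)
        oracle_h, _ = oracle_kw_dunn([np.array([1., 2.]),
                                      np.array([4., 5., 6.]),
                                      np.array([7., 8., 9.])])
        assert res.h_statistic == pytest.approx(oracle_h, abs=1e-10)

    def test_single_group_skipped_with_note(self):
        table = pd.DataFrame([[1.0, 2.0, np.nan, np.nan]], index=["f"],
                             columns=list("abcd"))
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        (res,) = sp.kruskal_dunn(table, groups)
        assert res.note and np.isnan(res.p_kw)

    def test_sample_order_invariance(self, rng):
        samples = [rng.normal(size=5), rng.normal(size=5), rng.normal(size=5)]
        table, groups = _feature_frame(samples)
        perm = list(rng.permutation(table.columns))
        (a,) = sp.kruskal_dunn(table, groups)
        (b,) = sp.kruskal_dunn(table[perm], groups)
        assert a.h_statistic == pytest.approx(b.h_statistic, abs=1e-12)
        za = {tuple(p.pair): p.z for p in a.pairwise}
        zb = {tuple(p.pair): p.z for p in b.pairwise}
        assert za.keys() == zb.keys()
        for k in za:
            assert za[k] == pytest.approx(zb[k], abs=1e-12)

    def test_results_frame_tidy(self, rng):
        table, groups = _feature_frame([rng.normal(size=4),
                                        rng.normal(size=4)])
        df = results_frame(sp.kruskal_dunn(table, groups))
        assert set(df.columns) >= {"feature", "H", "p_kw", "pair", "z",
                                   "p_adj"}
        assert len(df) == 1  # one pair for two groups


class TestBH:
    def test_single_p(self):
        assert sp.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_step_up_formula(self):
        p = [0.01, 0.02, 0.03, 0.9]
        assert np.allclose(sp.bh_fdr(p), oracle_bh(p))
        assert np.allclose(sp.bh_fdr(p), [0.04, 0.04, 0.04, 0.9])

    def test_all_ones(self):
        assert np.allclose(sp.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_random_vectors_match_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(sp.bh_fdr(p), oracle_bh(p), atol=1e-12)


class TestBrayCurtis:
    def test_identical_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert sp.bray_curtis(m).at["a", "b"] == 0.0

    def test_disjoint_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 2.0]], index=["a", "b"])
        assert sp.bray_curtis(m).at["a", "b"] == 1.0

    def test_hand_computation(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"])
        assert sp.bray_curtis(m).at["a", "b"] == pytest.approx(2.0 / 6.0)

    def test_matches_scipy(self, rng):
        X = rng.uniform(size=(12, 30))
        D = sp.bray_curtis(pd.DataFrame(X))
        ref = squareform(pdist(X, metric="braycurtis"))
        assert np.allclose(D.to_numpy(), ref, atol=1e-12)

    def test_missing_treated_as_zero(self):
        m = pd.DataFrame([[1.0, np.nan], [1.0, 2.0]], index=["a", "b"])
        assert sp.bray_curtis(m).at["a", "b"] == pytest.approx(2.0 / 4.0)


class TestPCoA:
    def test_line_ordering_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])[:, None]
        D = pd.DataFrame(squareform(pdist(pts)))
        res = sp.pcoa(D, k=1)
        order = np.argsort(res.scores["PCo1"].to_numpy())
        assert list(order) in ([0, 1, 2, 3], [3, 2, 1, 0])

    def test_euclidean_distances_preserved(self, rng):
        pts = rng.normal(size=(15, 2))
        D = pd.DataFrame(squareform(pdist(pts)))
        res = sp.pcoa(D, k=2)
        got = squareform(pdist(res.scores.to_numpy()))
        assert np.allclose(got, D.to_numpy(), atol=1e-8)

    def test_matches_dense_eigensolver(self, rng):
        pts = rng.normal(size=(4, 3))
        D = squareform(pdist(pts))
        res = sp.pcoa(pd.DataFrame(D), k=3)
        evals, scores = oracle_pcoa(D, 3)
        assert np.allclose(res.eigenvalues, evals[:3], atol=1e-8)
        assert np.allclose(np.abs(res.scores.to_numpy()), np.abs(scores),
                           atol=1e-8)

    def test_matches_skbio(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        X = rng.uniform(size=(10, 25))
        D = sp.bray_curtis(pd.DataFrame(X))
        mine = sp.pcoa(D, k=3)
        ref = skbio_ord.pcoa(D.to_numpy(), number_of_dimensions=3)
        assert np.allclose(np.abs(mine.scores.to_numpy()),
                           np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6)

    def test_requested_axes_reduced_to_positive(self):
        D = pd.DataFrame(squareform(pdist(np.array([[0.], [1.], [2.]]))))
        res = sp.pcoa(D, k=3)
        assert res.scores.shape[1] <= 2


class TestBPCA:
    @staticmethod
    def _rank2(rng, n=60, d=20, noise=0.1):
        U = rng.normal(size=(n, 2))
        V = rng.normal(size=(2, d))
        return U @ V + rng.normal(0, noise, size=(n, d))

    def test_no_missing_identity(self, rng):
        X = pd.DataFrame(self._rank2(rng))
        out, info = sp.bpca_impute(X, seed=0)
        pd.testing.assert_frame_equal(out, X)
        assert info["n_missing"] == 0

    def test_observed_entries_unchanged(self, rng):
        X = self._rank2(rng)
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out, _ = sp.bpca_impute(Xm, seed=0)
        assert np.allclose(out[~mask], X[~mask])

    def test_beats_mean_imputation(self, rng):
        X = self._rank2(rng)
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out, info = sp.bpca_impute(Xm, seed=0)
        col_mean = np.nanmean(Xm, axis=0)
        mean_filled = np.where(mask, col_mean[None, :], X)
        rmse = np.sqrt(((out[mask] - X[mask]) ** 2).mean())
        rmse_mean = np.sqrt(((mean_filled[mask] - X[mask]) ** 2).mean())
        assert rmse < rmse_mean

    def test_single_observation_column_warns(self, rng):
        X = self._rank2(rng, n=10, d=4)
        X[1:, 0] = np.nan
        with pytest.warns(UserWarning, match="single observed"):
            out, _ = sp.bpca_impute(X, seed=0)
        assert np.isfinite(out).all()


class TestPCAPLSDA:
    def test_pc1_aligns_with_dominant_direction(self, rng):
        direction = np.array([3.0, 1.0, 0.5])
        direction /= np.linalg.norm(direction)
        X = (rng.normal(size=(50, 1)) * 10) @ direction[None, :] \
            + rng.normal(0, 0.1, size=(50, 3))
        res = sp.pca(pd.DataFrame(X), n_components=2)
        pc1 = res.extras["loadings"]["PC1"].to_numpy()
        assert abs(pc1 @ direction) > 0.99

    @staticmethod
    def _grouped(rng, shift=6.0, n=12, d=8):
        X, labels = [], {}
        k = 0
        for gi in range(3):
            block = rng.normal(size=(n, d))
            block[:, gi] += shift
            for row in block:
                X.append(row)
                labels[f"s{k}"] = f"g{gi}"
                k += 1
        return pd.DataFrame(X, index=list(labels)), labels

    def test_plsda_scores_orthogonal(self, rng):
        X, labels = self._grouped(rng)
        res = sp.plsda(X, labels, n_latent=2)
        T = res.scores.to_numpy()
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8

    def test_plsda_loo_centroid_accuracy(self, rng):
        X, labels = self._grouped(rng)
        correct = 0
        for held in X.index:
            keep = [s for s in X.index if s != held]
            res = sp.plsda(X.loc[keep], labels, n_latent=2)
            centroids = res.scores.groupby(
                pd.Series({s: labels[s] for s in keep})).mean()
            # project the held-out sample into score space via the rotations
            mu = X.loc[keep].mean()
            z = (X.loc[held] - mu).to_numpy() @ \
                res.extras["rotations"].to_numpy()
            pred = (centroids - z).pow(2).sum(axis=1).idxmin()
            correct += pred == labels[held]
        assert correct / len(X.index) > 0.9

    def test_plsda_truncates_to_rank(self, rng):
        X = pd.DataFrame(np.tile(rng.normal(size=(6, 1)), (1, 4)),
                         index=[f"s{i}" for i in range(6)])
        labels = {f"s{i}": "a" if i < 3 else "b" for i in range(6)}
        res = sp.plsda(X, labels, n_latent=3)
        assert res.scores.shape[1] == 1


class TestPcoCorrelate:
    def _scores(self, rng, n=30):
        return pd.DataFrame(rng.normal(size=(n, 3)),
                            index=[f"s{i}" for i in range(n)],
                            columns=["PCo1", "PCo2", "PCo3"])

    def test_self_correlation_diagonal(self, rng):
        a = self._scores(rng)
        res = sp.pco_correlate(a, a)
        by_pair = {(c.axis_a, c.axis_b): c for c in res}
        for ax in a.columns:
            assert by_pair[(ax, ax)].r == pytest.approx(1.0)
            assert by_pair[(ax, ax)].reported

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = self._scores(rng)
        b = a.copy()
        b["PCo1"] = np.exp(b["PCo1"])
        r1 = sp.pco_correlate(a, a)
        r2 = sp.pco_correlate(a, b)
        for c1, c2 in zip(r1, r2):
            assert c1.r == pytest.approx(c2.r, abs=1e-12)

    def test_reporting_rule(self, rng):
        a = self._scores(rng, n=200)
        b = self._scores(rng, n=200)
        res = sp.pco_correlate(a, b, report_min_abs_r=0.2, alpha=0.05)
        for c in res:
            expected_r, expected_p = spearmanr(a[c.axis_a], b[c.axis_b])
            assert c.r == pytest.approx(expected_r)
            assert c.reported == (abs(c.r) > 0.2 and c.p < 0.05)

    def test_too_few_shared_samples_rejected(self, rng):
        a = self._scores(rng, n=5)
        b = self._scores(rng, n=5)
        b.index = [f"t{i}" for i in range(3)] + list(a.index[:2])
        with pytest.raises(ValueError):
            sp.pco_correlate(a, b)


def _oracle_average_linkage(X):
    """Brute-force agglomerative average linkage; returns merge heights."""
    clusters = {i: [i] for i in range(len(X))}
    D = squareform(pdist(X))
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                          index=["a", "b", "c"])
        res = sp.hierarchical_cluster(df)
        assert res["merge_heights"][0] == 0.0

    def test_near_identical_cluster_first(self):
        df = pd.DataFrame([[0.0, 0.0], [0.1, 0.0], [9.0, 9.0]],
                          index=["a", "b", "c"])
        res = sp.hierarchical_cluster(df)
        order = res["leaf_order"]
        assert abs(order.index("a") - order.index("b")) == 1

    def test_matches_brute_force_agglomeration(self, rng):
        X = rng.normal(size=(10, 20))
        res = sp.hierarchical_cluster(pd.DataFrame(X), linkage="average")
        assert np.allclose(np.sort(res["merge_heights"]),
                           np.sort(_oracle_average_linkage(X)), atol=1e-10)


class TestJaccard:
    def test_presence_absence(self):
        m = pd.DataFrame([[1.0, 0.0, 2.0], [3.0, 0.0, 0.0]], index=["a", "b"])
        assert sp.jaccard_dissimilarity(m).at["a", "b"] == pytest.approx(0.5)
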