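"""Group-difference testing, ordination, imputation and clustering.

The battery mirrors a standard label-free omics comparison: per-feature
Kruskal-Wallis with Dunn-Bonferroni post hoc pairwise tests (tie
corrected; Bonferroni over the k(k-1)/2 group pairs per feature, with
BH-FDR across features as an opt-in extra step), Bray-Curtis distances
and principal coordinates analysis, PCA and PLS-DA on BPCA-completed
matrices, Spearman correlation of the top principal coordinates of two
data blocks with a |R| > 0.2 and p < 0.05 reporting rule, and
agglomerative clustering of group-mean feature profiles.

Missing-value policy per analysis: Kruskal-Wallis/Dunn drop missing
values per feature; PCA/PLS-DA require a BPCA-completed matrix;
distance computations treat missing abundances as zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sph
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adj: float


@dataclass
class TestResult:
    feature: str
    h_statistic: float
    p_kw: float
    pairwise: list[PairwiseResult]
    q_value: float | None = None
    note: str = ""

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [pw.pair for pw in self.pairwise if pw.p_adj < alpha]


@dataclass
class OrdinationResult:
    method: str                      # PCoA | PCA | PLSDA
    scores: pd.DataFrame             # samples x axes
    eigenvalues: np.ndarray
    explained_variance: np.ndarray   # fraction per retained axis
    extras: dict = field(default_factory=dict)


@dataclass
class CorrelationResult:
    axis_a: str
    axis_b: str
    r: float
    p: float
    n: int
    reported: bool


# ---------------------------------------------------------------------------
# rank tests


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray,
                   groups: list[str]) -> list[PairwiseResult]:
    """Dunn's z from pooled ranks with tie correction, Bonferroni over
    the group pairs."""
    n = len(values)
    ranks = rankdata(values)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)) if n > 1 else 0.0
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(PairwiseResult((a, b), float(z), float(p), min(1.0, p * m)))
    return out


def kruskal_dunn(feature_table: pd.DataFrame, groups: dict[str, str],
                 alpha: float = 0.05, fdr_across_features: bool = False
                 ) -> list[TestResult]:
    """Kruskal-Wallis + Dunn-Bonferroni for every feature (row).

    ``feature_table`` is features x samples; ``groups`` maps sample id
    to group label.  Missing values are dropped pairwise per feature; a
    feature with fewer than two groups having >= 2 observations is
    skipped with a note.
    """
    labels_all = np.array([groups[s] for s in feature_table.columns])
    results: list[TestResult] = []
    for feat, row in feature_table.iterrows():
        vals = row.to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        v, lab = vals[mask], labels_all[mask]
        present = [g for g in sorted(set(lab)) if (lab == g).sum() >= 2]
        if len(present) < 2:
            results.append(TestResult(str(feat), np.nan, np.nan, [],
                                      note="fewer than 2 groups with >=2 samples"))
            continue
        keep = np.isin(lab, present)
        v, lab = v[keep], lab[keep]
        samples = [v[lab == g] for g in present]
        if all(np.all(s == samples[0][0]) for s in samples):
            h, p = 0.0, 1.0  # all values identical: no evidence
        else:
            h, p = sps.kruskal(*samples)
        results.append(TestResult(str(feat), float(h), float(p),
                                  _dunn_pairwise(v, lab, present)))
    if fdr_across_features:
        tested = [r for r in results if not np.isnan(r.p_kw)]
        if tested:
            q = bh_fdr(np.array([r.p_kw for r in tested]))
            for r, qv in zip(tested, q):
                r.q_value = float(qv)
    return results


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tidy one-row-per-(feature, pair) frame of test results."""
    rows = []
    for r in results:
        if not r.pairwise:
            rows.append({"feature": r.feature, "H": r.h_statistic,
                         "p_kw": r.p_kw, "pair": "", "z": np.nan,
                         "p_raw": np.nan, "p_adj": np.nan, "q": r.q_value,
                         "note": r.note})
        for pw in r.pairwise:
            rows.append({"feature": r.feature, "H": r.h_statistic,
                         "p_kw": r.p_kw, "pair": f"{pw.pair[0]} vs {pw.pair[1]}",
                         "z": pw.z, "p_raw": pw.p_raw, "p_adj": pw.p_adj,
                         "q": r.q_value, "note": r.note})
    return pd.DataFrame(rows)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# distances and ordination


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (rows).

    Missing values are treated as zeros; a pair of all-zero samples gets
    distance 0 with a warning.
    """
    X = np.nan_to_num(np.asarray(matrix, dtype=float))
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative values")
    n = X.shape[0]
    D = np.zeros((n, n))
    zero_pair = False
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        zero_pair = zero_pair or bool(np.any(tot == 0))
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    if zero_pair:
        logger.warning("bray_curtis: all-zero sample pair; distance set to 0")
    ids = matrix.index if isinstance(matrix, pd.DataFrame) else range(n)
    return pd.DataFrame(D, index=ids, columns=ids)


def pcoa(D: pd.DataFrame, k: int = 3) -> OrdinationResult:
    """Principal coordinates analysis via Gower double-centering.

    Negative eigenvalues are excluded (magnitudes logged in extras);
    explained variance is relative to the sum of positive eigenvalues.
    """
    Dm = np.asarray(D, dtype=float)
    if Dm.shape[0] != Dm.shape[1] or not np.allclose(Dm, Dm.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(Dm), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    n = Dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dm ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals[0]))
    n_pos = int(pos.sum())
    if k > n_pos:
        logger.warning("pcoa: requested %d axes but only %d positive "
                       "eigenvalues; reducing", k, n_pos)
        k = n_pos
    lam = evals[:k]
    scores = evecs[:, :k] * np.sqrt(lam)
    ids = D.index if isinstance(D, pd.DataFrame) else range(n)
    cols = [f"PCo{i + 1}" for i in range(k)]
    total_pos = evals[pos].sum()
    return OrdinationResult(
        method="PCoA",
        scores=pd.DataFrame(scores, index=ids, columns=cols),
        eigenvalues=evals[:k],
        explained_variance=lam / total_pos if total_pos > 0 else lam * 0,
        extras={"negative_eigenvalue_magnitudes": np.abs(evals[evals < 0]),
                "n_positive": n_pos, "correction": "none"},
    )


# ---------------------------------------------------------------------------
# BPCA-style imputation


def bpca_impute(X: pd.DataFrame | np.ndarray, n_components: int | None = None,
                max_iter: int = 500, tol: float = 1e-6,
                seed: int = 0) -> tuple[pd.DataFrame | np.ndarray, dict]:
    """Complete a samples x features matrix by probabilistic PCA EM.

    Missing entries are treated as latent: each iteration re-estimates
    the principal subspace from the completed matrix (maximum-likelihood
    PPCA, with component weights sqrt(lambda - sigma^2) so directions at
    or below the noise floor are shrunk to zero) and replaces missing
    cells by their conditional expectation given the observed cells.
    Observed entries are returned unchanged.  Columns with a single
    observed value fall back to that value (feature mean) with a
    warning.
    """
    is_df = isinstance(X, pd.DataFrame)
    A = np.asarray(X, dtype=float).copy()
    n, d = A.shape
    miss = np.isnan(A)
    info = {"converged": True, "n_iter": 0, "n_missing": int(miss.sum())}
    if not miss.any():
        return (X.copy() if is_df else A), info

    obs_count = (~miss).sum(axis=0)
    if np.any(obs_count == 0):
        raise ValueError("feature with no observed values")
    single = obs_count == 1
    if single.any():
        warnings.warn(f"{int(single.sum())} feature(s) with a single observed "
                      "value imputed by their feature mean")
    col_mean = np.nanmean(A, axis=0)
    A[miss] = np.take(col_mean, np.where(miss)[1])

    q = n_components if n_components is not None else min(n - 1, 10, d)
    q = max(1, min(q, n - 1, d))
    prev = A[miss].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = A.mean(axis=0)
        Ac = A - mu
        U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
        lam = s ** 2 / n
        sigma2 = float(lam[q:].mean()) if lam.size > q else 1e-12
        W = Vt[:q].T * np.sqrt(np.maximum(lam[:q] - sigma2, 0.0))
        # conditional expectation of missing cells per sample
        for i in np.unique(np.where(miss)[0]):
            o = ~miss[i]
            m = miss[i]
            Wo = W[o]
            M = Wo.T @ Wo + max(sigma2, 1e-12) * np.eye(q)
            z = np.linalg.solve(M, Wo.T @ Ac[i, o])
            A[i, m] = (W[m] @ z) + mu[m]
        delta = float(np.max(np.abs(A[miss] - prev))) if miss.any() else 0.0
        prev = A[miss].copy()
        if delta < tol:
            converged = True
            break
    info.update(converged=converged, n_iter=it, sigma2=sigma2)
    if not converged:
        logger.warning("bpca_impute: no convergence in %d iterations "
                       "(last delta %.3g); returning best iterate", max_iter, delta)
    if is_df:
        return pd.DataFrame(A, index=X.index, columns=X.columns), info
    return A, info


# ---------------------------------------------------------------------------
# PCA / PLS-DA


def pca(X: pd.DataFrame, n_components: int = 3,
        scale: bool = False) -> OrdinationResult:
    """PCA by singular value decomposition of the centered matrix."""
    A = np.asarray(X, dtype=float)
    if np.isnan(A).any():
        raise ValueError("PCA requires a complete matrix; run bpca_impute first")
    A = A - A.mean(axis=0)
    if scale:
        sd = A.std(axis=0, ddof=1)
        A = A / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    n = A.shape[0]
    lam = s ** 2 / (n - 1)
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="PCA",
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        eigenvalues=lam[:k],
        explained_variance=lam[:k] / lam.sum(),
        extras={"loadings": pd.DataFrame(Vt[:k].T, index=X.columns, columns=cols)},
    )


def plsda(X: pd.DataFrame, groups: dict[str, str],
          n_latent: int = 2, scale: bool = False) -> OrdinationResult:
    """PLS discriminant analysis: NIPALS latent variables against one-hot
    group indicators (via scikit-learn's PLS regression)."""
    from sklearn.cross_decomposition import PLSRegression

    A = np.asarray(X, dtype=float)
    if np.isnan(A).any():
        raise ValueError("PLS-DA requires a complete matrix; run bpca_impute first")
    labels = [groups[s] for s in X.index]
    cats = sorted(set(labels))
    Y = np.array([[1.0 if g == c else 0.0 for c in cats] for g in labels])
    Ac0 = A - A.mean(axis=0)
    sv = np.linalg.svd(Ac0, compute_uv=False)
    # effective rank with an absolute floor: near-constant matrices make
    # the NIPALS inner loop divide by ~0
    rank = int(np.sum(sv > max(1e-8 * (sv[0] if sv.size else 0.0), 1e-9)))
    if rank == 0:
        raise ValueError("PLS-DA requires variation in X")
    if n_latent > rank:
        logger.warning("plsda: n_latent %d exceeds rank %d; truncating",
                       n_latent, rank)
        n_latent = rank
    pls = PLSRegression(n_components=n_latent, scale=scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        pls.fit(A, Y)
    T = pls.x_scores_
    if not np.isfinite(T).all():
        raise ValueError("PLS-DA failed: degenerate score estimates "
                         "(X nearly constant or Y uninformative)")
    Ac = A - A.mean(axis=0)
    total = (Ac ** 2).sum()
    # per-component X variance captured by the rank-1 reconstructions
    expl = np.array([
        ((np.outer(T[:, a], pls.x_loadings_[:, a])) ** 2).sum() / total
        for a in range(n_latent)])
    cols = [f"LV{i + 1}" for i in range(n_latent)]
    return OrdinationResult(
        method="PLSDA",
        scores=pd.DataFrame(T, index=X.index, columns=cols),
        eigenvalues=(T ** 2).sum(axis=0),
        explained_variance=expl,
        extras={"classes": cats,
                "loadings": pd.DataFrame(pls.x_loadings_, index=X.columns,
                                         columns=cols),
                "rotations": pd.DataFrame(pls.x_rotations_, index=X.columns,
                                          columns=cols)},
    )


# ---------------------------------------------------------------------------
# cross-block correlation and clustering


def pco_correlate(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                  report_min_abs_r: float = 0.2, alpha: float = 0.05,
                  n_axes: int = 3) -> list[CorrelationResult]:
    """Spearman correlations between the top axes of two sample-score
    blocks, aligned on shared sample ids.

    A pair is flagged ``reported`` iff |R| > ``report_min_abs_r`` and
    p < ``alpha``.
    """
    shared = scores_a.index.intersection(scores_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    a = scores_a.loc[shared].iloc[:, :n_axes]
    b = scores_b.loc[shared].iloc[:, :n_axes]
    out = []
    for ca in a.columns:
        for cb in b.columns:
            r, p = sps.spearmanr(a[ca], b[cb])
            out.append(CorrelationResult(
                str(ca), str(cb), float(r), float(p), len(shared),
                reported=bool(abs(r) > report_min_abs_r and p < alpha)))
    return out


def hierarchical_cluster(group_means: pd.DataFrame, linkage: str = "average",
                         metric: str = "euclidean") -> dict:
    """Agglomerative clustering of group-mean feature profiles (rows).

    Returns the scipy linkage matrix, merge heights and leaf order
    (the ordering used for heatmap display).
    """
    if group_means.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = sph.linkage(np.asarray(group_means, dtype=float), method=linkage,
                    metric=metric)
    order = sph.leaves_list(Z)
    return {"linkage": Z,
            "merge_heights": Z[:, 2].copy(),
            "leaf_order": [group_means.index[i] for i in order]}


def jaccard_dissimilarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence Jaccard dissimilarity between samples (rows);
    alternative metric to Bray-Curtis."""
    X = np.nan_to_num(np.asarray(matrix, dtype=float)) > 0
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        inter = (X[i] & X[i + 1:]).sum(axis=1)
        union = (X[i] | X[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, 1.0 - inter / np.where(union > 0, union, 1), 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    ids = matrix.index if isinstance(matrix, pd.DataFrame) else range(n)
    return pd.DataFrame(D, index=ids, columns=ids)
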