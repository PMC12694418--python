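"""Study-level multivariate statistics.

The metric and environmental blocks are 0-1 normalized, screened for
collinearity with Spearman correlation (|r| >= 0.6 drops one member of each
offending pair), and then ordinated: PCA (Euclidean) for the environmental
block, PCoA on Bray-Curtis dissimilarity for the metric block, PERMANOVA for
group effects, and a PLS2 regression (environment -> metrics) whose
standardized coefficients and VIP scores identify the drivers of the
fingerprint.  VIP uses the standard Y-variance-weighted squared-weight
formulation, so sum(VIP^2) equals the number of predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression


def minmax_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Map every column to [0, 1] via (x - min)/(max - min).

    Constant columns map to all-zero and are returned in the flag list.
    """
    out = {}
    constant: list[str] = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        lo, hi = np.min(x), np.max(x)
        if hi == lo:
            out[col] = np.zeros_like(x)
            constant.append(col)
        else:
            out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index), constant


def spearman_filter(
    table: pd.DataFrame, threshold: float = 0.6
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Iteratively drop collinear variables (Spearman |r| >= threshold).

    While any retained pair is at or above the threshold, the pair with the
    largest |r| is located and the member with the larger mean |r| against
    all currently retained variables is dropped (ties drop the variable
    later in input order).  Returns (retained, dropped, full |r| matrix).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols, [], pd.DataFrame(np.ones((len(cols),) * 2), index=cols, columns=cols)
    rho = stats.spearmanr(table.to_numpy(dtype=float), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)
    corr = pd.DataFrame(rho, index=cols, columns=cols)

    retained = list(cols)
    dropped: list[str] = []
    while len(retained) > 1:
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] < threshold:
            break
        a, b = retained[worst[0]], retained[worst[1]]
        mean_r = {
            v: (sub[retained.index(v)].sum() / (len(retained) - 1))
            for v in (a, b)
        }
        if mean_r[a] > mean_r[b]:
            victim = a
        elif mean_r[b] > mean_r[a]:
            victim = b
        else:  # tie: drop the variable later in input order
            victim = a if cols.index(a) > cols.index(b) else b
        retained.remove(victim)
        dropped.append(victim)
    return retained, dropped, corr


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (p, k)
    explained: np.ndarray  # (k,), fractions summing to 1
    columns: list[str]


def pca(table: pd.DataFrame) -> PCAResult:
    """Column-centered SVD principal components.

    Component sign is fixed by making the largest-magnitude loading of each
    component positive.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    return PCAResult(
        scores=U * S,
        loadings=Vt.T,
        explained=explained,
        columns=list(table.columns),
    )


def bray_curtis(matrix) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix of a non-negative sample table.

    d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk); a pair of all-zero rows is
    defined as distance 0 (with a warning).
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if np.any(np.isnan(D)):
        warnings.warn("all-zero row pair: Bray-Curtis distance set to 0")
        D = np.nan_to_num(D, nan=0.0)
    return D


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (n, k), from positive eigenvalues only
    eigenvalues: np.ndarray  # all eigenvalues, descending
    relative_eigenvalues: np.ndarray  # positive lambda / sum(positive lambda)


def pcoa(distances: np.ndarray) -> PCoAResult:
    """Principal coordinate analysis (classical MDS, Gower centering).

    Coordinates come from positive eigenvalues only; no negative-eigenvalue
    correction is applied.  Axis sign is fixed by making the largest-
    magnitude coordinate of each axis positive.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    G = _gower_center(D)
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-8 * max(evals.max(), 0.0))
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] *= -1.0
    rel = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(coordinates=coords, eigenvalues=evals, relative_eigenvalues=rel)


def _permanova_ss(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = D2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def permanova(
    distances: np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F, R^2 and a permutation p-value.

    R^2 = SS_between / SS_total from the distance matrix (Anderson's
    sums-of-squared-distances formulation); the p-value counts permuted
    pseudo-F values at least as large as the observed one, with the
    observed configuration included ((1 + #extreme) / (1 + n_permutations)).
    """
    D = np.asarray(distances, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    a = len(uniques)
    n = D.shape[0]
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if len(codes) != n:
        raise ValueError("group labels must match the distance matrix size")
    D2 = D**2
    ss_total, ss_within = _permanova_ss(D2, codes)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        _, ss_w = _permanova_ss(D2, perm)
        ss_b = ss_total - ss_w
        f_perm = (ss_b / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
    )


def _standardize(X: np.ndarray, what: str) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"constant column in {what}: cannot standardize")
    return (X - mu) / sd


@dataclass
class PLSResult:
    n_components: int
    x_scores: np.ndarray  # (n, A)
    y_scores: np.ndarray
    x_weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray
    y_loadings: np.ndarray  # (m, A)
    coefficients: np.ndarray  # (p, m), standardized X -> standardized Y
    explained_y: np.ndarray  # (A,), fraction of Y variance per component
    predictors: list[str]
    responses: list[str]


def pls_regression(
    X: pd.DataFrame, Y: pd.DataFrame, n_components: int = 2
) -> PLSResult:
    """NIPALS PLS2 of standardized Y on standardized X.

    Both blocks are z-standardized internally, so the coefficient matrix is
    in standardized units (directions and magnitudes comparable across
    predictors).  ``explained_y[a]`` is the fraction of total Y variance
    captured by component a (||t_a||^2 ||q_a||^2 / ||Y||^2).
    """
    Xs = _standardize(X.to_numpy(dtype=float), "X")
    Ys = _standardize(Y.to_numpy(dtype=float), "Y")
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Ys)
    T = pls.x_scores_
    Q = pls.y_loadings_
    ssy_total = float(np.sum(Ys**2))
    ssy_comp = np.array(
        [float(T[:, a] @ T[:, a]) * float(Q[:, a] @ Q[:, a]) for a in range(n_components)]
    )
    return PLSResult(
        n_components=n_components,
        x_scores=T,
        y_scores=pls.y_scores_,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=Q,
        coefficients=pls.coef_.T,  # sklearn coef_ is (n_targets, n_features)
        explained_y=ssy_comp / ssy_total,
        predictors=list(X.columns),
        responses=list(Y.columns),
    )


def vip(result: PLSResult) -> np.ndarray:
    """Variable importance in projection, one value per predictor.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), with
    SSY_a the Y variance explained by component a; sum(VIP^2) = p.
    """
    W = result.x_weights
    p = W.shape[0]
    ssy = result.explained_y
    if ssy.sum() <= 0:
        raise ValueError("PLS model explains no Y variance: VIP undefined")
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())
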