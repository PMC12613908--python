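"""Sparse Gaussian graphical model estimation on Spearman correlations.

The network over the 37 questionnaire nodes is a regularized partial
correlation matrix: pairwise Spearman rank correlations feed an
l1-penalized Gaussian log-likelihood (graphical lasso), the penalty is
chosen on a log-spaced grid by the extended BIC

    EBIC(lambda) = -2 loglik + E log n + 4 E gamma log p,

with E the number of nonzero off-diagonal edges, and edge weights are
read off the selected precision matrix kappa as
w_ij = -kappa_ij / sqrt(kappa_ii kappa_jj).

The solver is the standard block coordinate descent of the graphical
lasso (row/column subproblems solved by coordinate-descent lasso),
jit-compiled and warm-started along the penalty path so that the
resampling stages (bootstrap, permutation tests) can re-estimate the
network tens of thousands of times.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.base import BaseEstimator

from .scales import DEFAULT_SCALE_MAP

EDGE_THRESHOLD = 1e-8  # below this, an edge is a structural zero


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# correlation input


def spearman_matrix(X, labels=None) -> pd.DataFrame:
    """Pairwise Spearman correlations (average ranks for ties).

    Zero-variance columns raise a ValueError naming the node. If the rank
    correlation matrix is not positive semidefinite it is replaced by the
    nearest PSD correlation matrix (eigenvalue clipping at 1e-6, then
    re-standardized) and a warning is emitted.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.columns) if labels is None else list(labels)
        arr = X.to_numpy(float)
    else:
        arr = np.asarray(X, float)
        labels = labels or [f"V{i}" for i in range(arr.shape[1])]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance node(s): {bad}; rank correlation undefined")
    R = stats.spearmanr(arr).statistic
    if arr.shape[1] == 2:  # spearmanr returns a scalar for p=2
        R = np.array([[1.0, float(R)], [float(R), 1.0]])
    R = np.asarray(R, float)
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < 0:
        R = nearest_psd_correlation(R)
        warnings.warn(
            "Spearman matrix not PSD; replaced by nearest PSD correlation",
            stacklevel=2,
        )
    return pd.DataFrame(R, index=labels, columns=labels)


def nearest_psd_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping at ``floor`` followed by re-standardization."""
    w, V = np.linalg.eigh(np.asarray(R, float))
    w = np.clip(w, floor, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2


# ---------------------------------------------------------------------------
# graphical lasso solver


@njit(cache=True)
def _lasso_cd(W11, s12, beta, rho, tol, max_iter):
    """Coordinate-descent lasso for one glasso row subproblem."""
    q = s12.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(q):
            r = s12[k] + W11[k, k] * beta[k]
            for l in range(q):
                r -= W11[k, l] * beta[l]
            old = beta[k]
            if r > rho:
                b = (r - rho) / W11[k, k]
            elif r < -rho:
                b = (r + rho) / W11[k, k]
            else:
                b = 0.0
            beta[k] = b
            d = abs(b - old)
            if d > dmax:
                dmax = d
        if dmax < tol:
            break


@njit(cache=True)
def _glasso_solve(S, rho, W, B, tol, max_sweeps, inner_tol, inner_max):
    """Block coordinate descent; W and B are warm-start state (updated
    in place). Returns the precision matrix."""
    p = S.shape[0]
    # diagonal is unpenalized: W_ii stays at S_ii
    for i in range(p):
        W[i, i] = S[i, i]
    off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                off += abs(S[i, j])
    off /= p * (p - 1)
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    w12 = np.empty(p - 1)
    for _sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            # gather the (p-1)x(p-1) block excluding j
            a = 0
            for r in range(p):
                if r == j:
                    continue
                s12[a] = S[r, j]
                b = 0
                for c in range(p):
                    if c == j:
                        continue
                    W11[a, b] = W[r, c]
                    b += 1
                a += 1
            beta = B[:, j]
            _lasso_cd(W11, s12, beta, rho, inner_tol, inner_max)
            for a in range(p - 1):
                acc = 0.0
                for b in range(p - 1):
                    acc += W11[a, b] * beta[b]
                w12[a] = acc
            a = 0
            for r in range(p):
                if r == j:
                    continue
                delta += abs(W[r, j] - w12[a])
                W[r, j] = w12[a]
                W[j, r] = w12[a]
                a += 1
        if delta / (p * (p - 1)) < tol * max(off, 1e-12):
            break
    # recover the precision matrix from the final regressions
    K = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        a = 0
        for r in range(p):
            if r == j:
                continue
            acc += W[r, j] * B[a, j]
            a += 1
        k22 = 1.0 / max(W[j, j] - acc, 1e-12)
        K[j, j] = k22
        a = 0
        for r in range(p):
            if r == j:
                continue
            K[r, j] = -B[a, j] * k22
            a += 1
    # symmetrize (support is symmetric up to solver tolerance)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K


def graphical_lasso_precision(
    S: np.ndarray,
    rho: float,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-4,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Solve one graphical lasso problem; returns (precision, warm_state).

    ``rho == 0`` falls back to the unpenalized MLE (matrix inversion).
    """
    S = np.asarray(S, float)
    p = S.shape[0]
    if rho <= 0:
        try:
            K = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            K = np.linalg.pinv(S)
        return K, warm if warm is not None else _init_warm(S)
    if warm is None:
        warm = _init_warm(S)
    W, B = warm
    K = _glasso_solve(S, rho, W, B, tol, max_sweeps, tol * 1e-2, 100)
    if not np.all(np.isfinite(K)):
        raise EstimationError(f"graphical lasso diverged at rho={rho:g}")
    return K, (W, B)


def _init_warm(S):
    p = S.shape[0]
    W = S.copy().astype(float)
    B = np.zeros((p - 1, p))
    return W, B


def partial_corr_from_precision(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < EDGE_THRESHOLD] = 0.0
    return (W + W.T) / 2


def ebic_score(K, R, n, gamma, edge_threshold=EDGE_THRESHOLD) -> tuple[float, int]:
    """Extended BIC of a fitted precision matrix against correlation R."""
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf, -1
    ll = 0.5 * n * (logdet - np.trace(R @ K))
    off = K[np.triu_indices(p, 1)]
    E = int(np.sum(np.abs(off) > edge_threshold))
    return float(-2 * ll + E * np.log(n) + 4 * E * gamma * np.log(p)), E


# ---------------------------------------------------------------------------
# estimator


class GaussianGraphicalModel(BaseEstimator):
    """EBIC-tuned graphical lasso network on Spearman correlations.

    Parameters
    ----------
    gamma : float, default 0.5
        EBIC sparsity weight (0 = plain BIC).
    n_lambdas : int, default 100
        Size of the log-spaced penalty grid.
    lambda_min_ratio : float, default 0.01
        lambda_min / lambda_max; lambda_max is max |off-diagonal R|.
    tol : float, default 1e-4
        Relative convergence tolerance of the block coordinate descent.
    max_iter : int, default 200
        Maximum outer sweeps per penalty value.

    Attributes (after fit)
    ----------------------
    corr_ : Spearman correlation matrix used (DataFrame).
    precision_ : selected precision matrix.
    partial_corr_ : selected signed edge-weight matrix W (zero diagonal).
    alpha_ : selected penalty; alphas_ : the grid (descending).
    ebic_, ebics_, edge_counts_ : selection diagnostics.
    n_samples_ : sample size used in the EBIC.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        tol: float = 1e-4,
        max_iter: int = 200,
    ):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        """Estimate the network from a participants x nodes matrix."""
        R = spearman_matrix(X)
        n = np.asarray(X).shape[0]
        if n <= R.shape[0]:
            warnings.warn(
                f"n={n} not larger than p={R.shape[0]}; estimates unstable",
                stacklevel=2,
            )
        return self.fit_correlation(R, n)

    def fit_correlation(self, R, n_samples: int):
        """Estimate the network from a correlation matrix directly."""
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if isinstance(R, pd.DataFrame):
            labels = list(R.columns)
            Rm = R.to_numpy(float)
        else:
            Rm = np.asarray(R, float)
            labels = [f"V{i}" for i in range(Rm.shape[0])]
        if np.linalg.eigvalsh(Rm).min() < -1e-10:
            raise EstimationError(
                "correlation matrix is not PSD; repair it first "
                "(see nearest_psd_correlation)"
            )
        p = Rm.shape[0]
        off = np.abs(Rm - np.eye(p))
        lam_max = float(off.max())
        if lam_max < EDGE_THRESHOLD:  # independent nodes: empty network
            lam_max = 1e-3
        grid = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)
        warm = None
        best = None
        ebics, edge_counts, kept = [], [], []
        for lam in grid:
            try:
                K, warm = graphical_lasso_precision(
                    Rm, float(lam), warm, tol=self.tol, max_sweeps=self.max_iter
                )
            except EstimationError:
                warm = None
                continue
            score, E = ebic_score(K, Rm, n_samples, self.gamma)
            ebics.append(score)
            edge_counts.append(E)
            kept.append(float(lam))
            if np.isfinite(score) and (best is None or score < best[0]):
                best = (score, float(lam), K.copy(), E)
        if best is None:
            raise EstimationError("no penalty value produced a valid model")
        score, lam, K, E = best
        self.feature_names_in_ = labels
        self.n_features_in_ = p
        self.corr_ = pd.DataFrame(Rm, index=labels, columns=labels)
        self.n_samples_ = int(n_samples)
        self.alphas_ = np.asarray(kept)
        self.ebics_ = np.asarray(ebics)
        self.edge_counts_ = np.asarray(edge_counts)
        self.alpha_ = lam
        self.ebic_ = score
        self.n_edges_ = E
        self.precision_ = K
        self.partial_corr_ = partial_corr_from_precision(K)
        return self

    @property
    def weights_(self) -> pd.DataFrame:
        """Edge-weight matrix as a labelled DataFrame."""
        return pd.DataFrame(
            self.partial_corr_,
            index=self.feature_names_in_,
            columns=self.feature_names_in_,
        )

    def edge_list(self) -> pd.DataFrame:
        """Long-format nonzero edges: node_i, node_j, weight."""
        W = self.partial_corr_
        labels = self.feature_names_in_
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if abs(W[i, j]) > EDGE_THRESHOLD:
                    rows.append((labels[i], labels[j], W[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def predictability(self, X, constructs: dict[str, str] | None = None):
        """Per-node R^2 from its directly connected neighbors.

        For each node, ordinary least squares of the standardized node on
        its standardized neighbors (nodes with a nonzero edge to it);
        isolated nodes get R^2 = 0. Returns (per-node Series,
        per-construct mean Series).
        """
        W = self.partial_corr_
        labels = self.feature_names_in_
        arr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        n = arr.shape[0]
        Z = (arr - arr.mean(0)) / arr.std(0)
        r2 = {}
        for i, lab in enumerate(labels):
            nb = np.flatnonzero(np.abs(W[i]) > EDGE_THRESHOLD)
            if nb.size == 0:
                r2[lab] = 0.0
                continue
            A = Z[:, nb]
            y = Z[:, i]
            if nb.size > n - 2:
                coef = np.linalg.pinv(A) @ y
            else:
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            r2[lab] = float(max(0.0, 1.0 - resid @ resid / (y @ y)))
        per_node = pd.Series(r2, name="R2")
        if constructs is None:
            constructs = DEFAULT_SCALE_MAP.node_construct()
        if all(l in constructs for l in labels):
            grp = per_node.groupby(pd.Series({l: constructs[l] for l in labels}))
            per_construct = grp.mean()
        else:
            per_construct = pd.Series(dtype=float)
        return per_node, per_construct


def estimate_network(X, **params) -> GaussianGraphicalModel:
    """Fit a :class:`GaussianGraphicalModel` on a node matrix."""
    return GaussianGraphicalModel(**params).fit(X)
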