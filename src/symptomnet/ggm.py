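"""Regularized partial-correlation network estimation.

Pipeline per group: Pearson correlation of residualized items -> graphical
LASSO over a log-spaced penalty path -> extended BIC (EBIC) model selection
-> partial-correlation weight matrix.

The graphical LASSO solver is a Friedman-style block coordinate descent on
the penalized covariance, compiled with numba: the permutation comparison
test and the bootstrap stages refit the full path many thousands of times,
so per-fit overhead matters. Off-diagonal precision entries produced by the
inner soft-thresholding are exact zeros; after symmetrization any residual
numerical dust below 1e-10 is hard-thresholded, which makes "nonzero edge"
well-defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import EstimationError
from .residualize import ResidualMatrix

__all__ = [
    "CorrelationMatrix",
    "SymptomNetwork",
    "sample_correlation",
    "glasso_fit",
    "partials_from_precision",
    "ebic_score",
    "estimate_network",
]

HARD_ZERO = 1e-10


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation matrix with the sample size that produced it."""

    R: np.ndarray
    n: int

    @property
    def p(self) -> int:
        return self.R.shape[0]


@dataclass
class SymptomNetwork:
    """EBIC-selected regularized partial-correlation network.

    ``W`` is the symmetric p x p edge-weight matrix (partial correlations,
    zero diagonal); path metadata records every penalty tried and its EBIC.
    """

    W: np.ndarray
    precision: np.ndarray
    lambda_selected: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    edge_count_path: np.ndarray
    gamma: float
    n: int

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def nonzero_edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.W[iu]))

    def edges(self) -> list:
        """Nonzero edges as (i, j, weight) with 0-based i < j."""
        iu, ju = np.triu_indices(self.p, k=1)
        return [(int(i), int(j), float(self.W[i, j]))
                for i, j in zip(iu, ju) if self.W[i, j] != 0.0]


def sample_correlation(resid) -> CorrelationMatrix:
    """Pearson product-moment correlations of residual columns."""
    X = resid.values if isinstance(resid, ResidualMatrix) else np.asarray(resid, dtype=float)
    n, p = X.shape
    if n < 3:
        raise EstimationError(f"need at least 3 rows to correlate, got {n}")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise EstimationError(f"zero-variance column: item {bad + 1}")
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R=R, n=n)


@njit(cache=True)
def _lasso_cd(W11, s12, beta, lam, tol, max_iter):
    # minimize 0.5 b'W11 b - s12'b + lam*|b|_1 by cyclic coordinate descent
    m = s12.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(m):
            r = s12[k]
            for l in range(m):
                if l != k:
                    r -= W11[k, l] * beta[l]
            old = beta[k]
            if r > lam:
                new = (r - lam) / W11[k, k]
            elif r < -lam:
                new = (r + lam) / W11[k, k]
            else:
                new = 0.0
            beta[k] = new
            d = abs(new - old)
            if d > dmax:
                dmax = d
        if dmax < tol:
            break


@njit(cache=True)
def _glasso(S, lam, tol, max_iter, W, B):
    # Block coordinate descent over columns of the covariance estimate W.
    # W and B (per-column lasso coefficients) are warm-start state.
    # diagonal is not penalized (the convention of the field's EBIC-glasso
    # implementations, and of sklearn's solver used as cross-check)
    p = S.shape[0]
    for i in range(p):
        W[i, i] = S[i, i]
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    converged = False
    sweeps = 0
    for _ in range(max_iter):
        sweeps += 1
        delta = 0.0
        for j in range(p):
            a = 0
            for i in range(p):
                if i == j:
                    continue
                s12[a] = S[i, j]
                beta[a] = B[i, j]
                b = 0
                for k in range(p):
                    if k == j:
                        continue
                    W11[a, b] = W[i, k]
                    b += 1
                a += 1
            _lasso_cd(W11, s12, beta, lam, tol * 0.1, 1000)
            a = 0
            for i in range(p):
                if i == j:
                    continue
                B[i, j] = beta[a]
                a += 1
            a = 0
            for i in range(p):
                if i == j:
                    continue
                w = 0.0
                for b in range(p - 1):
                    w += W11[a, b] * beta[b]
                delta += abs(W[i, j] - w)
                W[i, j] = w
                W[j, i] = w
                a += 1
        if delta / (p * (p - 1)) < tol:
            converged = True
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for i in range(p):
            if i != j:
                dot += W[i, j] * B[i, j]
        tjj = 1.0 / (W[j, j] - dot)
        Theta[j, j] = tjj
        for i in range(p):
            if i != j:
                Theta[i, j] = -B[i, j] * tjj
    return Theta, sweeps, converged


@njit(cache=True)
def _symmetrize_threshold(Theta):
    # average the two column-wise estimates; kill numerical dust
    p = Theta.shape[0]
    E = 0
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (Theta[i, j] + Theta[j, i])
            if abs(v) < HARD_ZERO:
                v = 0.0
            else:
                E += 1
            Theta[i, j] = v
            Theta[j, i] = v
    return E


@njit(cache=True)
def _ebic_path(S, n, lambdas, gamma, tol, max_iter):
    # lambdas must be sorted descending so warm starts carry forward
    p = S.shape[0]
    nlam = lambdas.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    ebics = np.empty(nlam)
    counts = np.zeros(nlam, dtype=np.int64)
    best = -1
    best_ebic = np.inf
    best_theta = np.zeros((p, p))
    for li in range(nlam):
        Theta, sweeps, conv = _glasso(S, lambdas[li], tol, max_iter, W, B)
        if not conv:
            return best_theta, -2 - li, ebics, counts
        E = _symmetrize_threshold(Theta)
        L = np.linalg.cholesky(Theta)
        logdet = 0.0
        for i in range(p):
            logdet += 2.0 * np.log(L[i, i])
        tr = 0.0
        for i in range(p):
            for j in range(p):
                tr += S[i, j] * Theta[j, i]
        ll = 0.5 * n * (logdet - tr)
        ebic = -2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p)
        ebics[li] = ebic
        counts[li] = E
        if ebic < best_ebic:
            best_ebic = ebic
            best = li
            best_theta[:, :] = Theta
    return best_theta, best, ebics, counts


def glasso_fit(R, lam: float, tol: float = 1e-4, max_iter: int = 10_000) -> np.ndarray:
    """L1-penalized Gaussian ML precision estimate at a single penalty.

    Returns the symmetrized precision matrix with exact off-diagonal zeros
    (entries below 1e-10 are set to 0). Raises :class:`EstimationError` on
    non-convergence.
    """
    S = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    Theta, sweeps, conv = _glasso(S, float(lam), tol, max_iter, W, B)
    if not conv:
        raise EstimationError(
            f"graphical lasso did not converge at lam={lam:g} within {sweeps} sweeps"
        )
    _symmetrize_threshold(Theta)
    return Theta


def partials_from_precision(Theta: np.ndarray) -> np.ndarray:
    """Partial correlations: W[i,j] = -Theta[i,j]/sqrt(Theta[i,i]*Theta[j,j]).

    Zeros in the precision propagate to exact zeros in W; the diagonal is 0.
    """
    Theta = np.asarray(Theta, dtype=float)
    d = np.diag(Theta)
    if (d <= 0).any():
        raise EstimationError("precision matrix has a nonpositive diagonal entry")
    W = np.where(Theta == 0.0, 0.0, -Theta / np.sqrt(np.outer(d, d)))
    np.fill_diagonal(W, 0.0)
    return W + 0.0


def ebic_score(Theta: np.ndarray, R, n: int, gamma: float = 0.5) -> float:
    """EBIC = -2*ll + E*log(n) + 4*gamma*E*log(p).

    ``ll = (n/2)(log det Theta - trace(R @ Theta))`` is the multivariate
    Gaussian profile log-likelihood; ``E`` counts nonzero pairs i < j.
    """
    S = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise EstimationError("precision estimate is not positive-definite")
    p = Theta.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(Theta[iu]))
    ll = 0.5 * n * (logdet - np.trace(S @ Theta))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def _lambda_path(R: np.ndarray, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    p = R.shape[0]
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.max(np.abs(R[iu]))) if len(iu[0]) else 0.0
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def estimate_network(
    resid,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> SymptomNetwork:
    """Estimate the EBIC-selected regularized partial-correlation network.

    Fits the graphical LASSO along a log-spaced penalty path from
    ``lam_max`` (the largest absolute correlation, where the graph is empty)
    down to ``lambda_min_ratio * lam_max``, scores each solution by EBIC and
    returns the minimizer with full path metadata.
    """
    corr = sample_correlation(resid)
    lambdas = _lambda_path(corr.R, n_lambda, lambda_min_ratio)
    Theta, best, ebics, counts = _ebic_path(
        corr.R, corr.n, lambdas, float(gamma), float(tol), int(max_iter)
    )
    if best < 0:
        bad = -best - 2
        raise EstimationError(
            f"graphical lasso did not converge at lam={lambdas[bad]:g} "
            f"(path index {bad}, cap {max_iter} sweeps)"
        )
    W = partials_from_precision(Theta)
    return SymptomNetwork(
        W=W,
        precision=Theta,
        lambda_selected=float(lambdas[best]),
        lambda_path=lambdas,
        ebic_path=ebics,
        edge_count_path=counts,
        gamma=float(gamma),
        n=corr.n,
    )
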