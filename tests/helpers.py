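"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: distances and
betweenness come from exhaustive simple-path enumeration, suitable only
for tiny graphs (p <= 7).
"""
from __future__ import annotations

import numpy as np


def enumerate_simple_paths(A: np.ndarray, s: int, t: int):
    """All simple paths s -> t in the weighted adjacency matrix A (|w| > 0)."""
    p = A.shape[0]
    out = []

    def dfs(node, visited, path):
        if node == t:
            out.append(list(path))
            return
        for nxt in range(p):
            if A[node, nxt] > 0 and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, [s])
    return out


def path_length(A: np.ndarray, path) -> float:
    return sum(1.0 / A[a, b] for a, b in zip(path, path[1:]))


def brute_force_distances(W: np.ndarray) -> np.ndarray:
    A = np.abs(np.asarray(W, dtype=float))
    p = A.shape[0]
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for s in range(p):
        for t in range(s + 1, p):
            paths = enumerate_simple_paths(A, s, t)
            if paths:
                D[s, t] = D[t, s] = min(path_length(A, q) for q in paths)
    return D


def brute_force_closeness(W: np.ndarray) -> np.ndarray:
    D = brute_force_distances(W)
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = D[i, np.arange(p) != i]
        d = d[np.isfinite(d)]
        if d.size:
            out[i] = 1.0 / d.mean()
    return out


def brute_force_betweenness(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fractional (Brandes-style) betweenness over unordered pairs."""
    A = np.abs(np.asarray(W, dtype=float))
    p = A.shape[0]
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = enumerate_simple_paths(A, s, t)
            if not paths:
                continue
            lengths = [path_length(A, q) for q in paths]
            dmin = min(lengths)
            shortest = [q for q, l in zip(paths, lengths) if l <= dmin + tol]
            for q in shortest:
                for v in q[1:-1]:
                    out[v] += 1.0 / len(shortest)
    return out


def random_sparse_weights(p: int, rng: np.random.Generator, density: float = 0.4) -> np.ndarray:
    """Random symmetric weight matrix with signed weights and zero diagonal."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w = rng.uniform(0.1, 0.9) * (1 if rng.random() < 0.7 else -1)
                W[i, j] = W[j, i] = w
    return W


def chain_model(p: int = 6, partial: float = 0.4):
    """Tridiagonal partial-correlation chain; returns (precision, partials)."""
    P = np.zeros((p, p))
    for i in range(p - 1):
        P[i, i + 1] = P[i + 1, i] = partial
    K = -P.copy()
    np.fill_diagonal(K, 1.0)
    assert np.linalg.eigvalsh(K).min() > 0
    d = np.sqrt(np.diag(K))
    partials = -K / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return K, partials


def sample_gaussian(K: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows from N(0, K^-1), unit-standardized columns."""
    cov = np.linalg.inv(K)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, K.shape[0])) @ L.T
    return X / np.sqrt(np.diag(cov))


def path_drops_only_boundary_edges(net, R, boundary: float = 1e-3) -> bool:
    """Check the corrected lasso-path property: as lambda decreases the
    nonzero-edge count may only drop when the departing edge had boundary
    magnitude (|w| < ``boundary``) at the previous path point. Lasso active
    sets are not strictly monotone (edges can exit, as in LARS drop steps)."""
    from symptomnet import glasso_fit, partials_from_precision

    counts = np.asarray(net.edge_count_path)
    for k in np.flatnonzero(np.diff(counts) < 0):
        W_hi = partials_from_precision(glasso_fit(R, float(net.lambda_path[k])))
        W_lo = partials_from_precision(glasso_fit(R, float(net.lambda_path[k + 1])))
        gone = (W_hi != 0) & (W_lo == 0)
        if np.any(np.abs(W_hi[gone]) >= boundary):
            return False
    return True
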