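"""Unregularised Gaussian graphical models with stepwise BIC selection.

A GGM's edges are the nonzero entries of the concentration (inverse
covariance) matrix, reported as partial correlations
``w_ij = -K_ij / sqrt(K_ii K_jj)``. For a fixed zero pattern the
maximum-likelihood fit matches the input correlation matrix on every linked
pair and on the diagonal; it is computed by edge-wise iterative proportional
scaling (see :mod:`famnet._ips`). Model search is greedy stepwise: from a
start graph, repeatedly apply the single-edge addition or removal with the
largest BIC decrease until no change helps.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import _ips
from .datatypes import CorrMatrix, FamnetError, GGMNetwork, SymptomTable
from .preprocessing import spearman_matrix


class ConvergenceError(RuntimeError):
    """IPS or stepwise search failed to stabilise."""


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a concentration matrix."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise FamnetError("precision matrix has non-positive diagonal entries")
    s = 1.0 / np.sqrt(d)
    W = -K * s[:, None] * s[None, :]
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def repair_correlation(R: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Nearest-PD adjustment by eigenvalue clipping, re-standardised.

    Spearman matrices on ordinal data can be indefinite; clip eigenvalues at
    ``min_eig`` and rescale to unit diagonal.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh(R)
    if w.min() >= min_eig:
        return R
    w = np.clip(w, min_eig, None)
    R2 = (V * w) @ V.T
    d = 1.0 / np.sqrt(np.diag(R2))
    R2 = R2 * d[:, None] * d[None, :]
    R2 = (R2 + R2.T) / 2.0
    np.fill_diagonal(R2, 1.0)
    return R2


def fit_constrained_ggm(
    corr: CorrMatrix,
    adjacency: np.ndarray,
    tol: float = _ips.IPS_TOL,
    max_iter: int = _ips.IPS_MAX_SWEEPS,
) -> tuple[np.ndarray, float]:
    """ML concentration matrix with zeros fixed off ``adjacency``.

    Returns ``(K, loglik)`` with ``loglik = (n/2)(log det K - tr(R K))`` up
    to an additive constant shared by all models on the same data. Converged
    when the implied covariance matches ``corr`` on every linked pair and on
    the diagonal to within ``tol``.
    """
    A = np.asarray(adjacency)
    if A.shape != corr.values.shape:
        raise FamnetError("adjacency shape does not match correlation matrix")
    if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
        raise FamnetError("adjacency must be symmetric with zero diagonal")
    S = np.ascontiguousarray(corr.values, dtype=float)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise FamnetError("correlation matrix is not positive definite; repair it first")
    A = np.ascontiguousarray(A, dtype=np.int64)
    if np.all(A[~np.eye(A.shape[0], dtype=bool)] == 1):
        # saturated model: the MLE is the plain inverse
        K = np.linalg.inv(S)
        K = (K + K.T) / 2.0
        change = 0.0
    else:
        K = _ips.diag_start(S)
        _sweeps, change = _ips.ips_fit(S, A, K, tol, max_iter)
    if change >= tol:
        raise ConvergenceError(
            f"IPS did not converge in {max_iter} sweeps (last change {change:.3e})"
        )
    loglik = 0.5 * corr.n_effective * (_ips.logdet_chol(K) - float(np.sum(S * K)))
    return K, float(loglik)


def bic(loglik: float, n_edges: int, n: int) -> float:
    """BIC with one free parameter per edge (diagonal not counted)."""
    if n < 2:
        raise FamnetError("n must be at least 2")
    return -2.0 * loglik + n_edges * np.log(n)


def significance_start(corr: CorrMatrix, alpha: float = 0.01) -> np.ndarray:
    """Start graph: saturated-model partials significant by Fisher's z.

    The saturated partial correlation conditions on p-2 other variables, so
    the z statistic is atanh(r) * sqrt(n - p - 1).
    """
    S = repair_correlation(corr.values)
    W = precision_to_partial(np.linalg.inv(S))
    df = corr.n_effective - corr.p - 1
    if df < 1:
        return np.zeros_like(W, dtype=np.int64)
    z = np.arctanh(np.clip(W, -0.999999, 0.999999)) * np.sqrt(df)
    crit = stats.norm.ppf(1 - alpha / 2)
    A = (np.abs(z) > crit).astype(np.int64)
    np.fill_diagonal(A, 0)
    return A


def select_ggm(
    corr: CorrMatrix,
    communities: dict[str, str] | None = None,
    start: str = "sig",
    start_alpha: float = 0.01,
    max_sweeps: int = 500,
    tol: float = _ips.IPS_TOL,
) -> GGMNetwork:
    """Greedy stepwise BIC search over single-edge changes.

    ``start`` is ``"sig"`` (edges whose saturated-model partial correlations
    pass a Fisher-z test at ``start_alpha``) or ``"empty"``. Ties in BIC
    within 1e-10 prefer removal over addition, then lexicographic edge order,
    so the search is deterministic.
    """
    p = corr.p
    n = corr.n_effective
    S = np.ascontiguousarray(repair_correlation(corr.values))
    rcorr = CorrMatrix(values=S, labels=list(corr.labels), n_effective=n)
    if start == "sig":
        A = significance_start(corr, start_alpha)
    elif start == "empty":
        A = np.zeros((p, p), dtype=np.int64)
    else:
        raise FamnetError(f"unknown start graph {start!r}")
    A = np.ascontiguousarray(A, dtype=np.int64)

    K, loglik = fit_constrained_ggm(rcorr, A, tol=tol)
    m = int(np.triu(A, 1).sum())
    cur_bic = bic(loglik, m, n)
    trace = [cur_bic]
    stabilised = False
    for _ in range(max_sweeps):
        found, i, j, _delta = _ips.score_all_moves(S, A, K, m, n, cur_bic, tol, _ips.IPS_MAX_SWEEPS)
        if not found:
            stabilised = True
            break
        A[i, j] = 1 - A[i, j]
        A[j, i] = A[i, j]
        K, loglik = fit_constrained_ggm(rcorr, A, tol=tol)
        m = int(np.triu(A, 1).sum())
        cur_bic = bic(loglik, m, n)
        trace.append(cur_bic)
    if not stabilised:
        raise ConvergenceError(
            f"stepwise search did not stabilise in {max_sweeps} steps; BIC trace: {trace}"
        )
    W = precision_to_partial(K)
    W[A == 0] = 0.0
    return GGMNetwork(
        weights=W,
        adjacency=A,
        labels=list(corr.labels),
        communities=dict(communities) if communities else {lab: "all" for lab in corr.labels},
        loglik=loglik,
        bic=cur_bic,
        n=n,
    )


def density_stats(net: GGMNetwork) -> dict:
    """Edge-count summary: density and absolute-weight statistics."""
    p = net.p
    if p < 2:
        raise FamnetError("need at least 2 nodes")
    n_possible = p * (p - 1) // 2
    m = net.n_edges
    iu = np.triu_indices(p, 1)
    absw = np.abs(net.weights[iu])
    nonzero = absw[absw > 0]
    empty = nonzero.size == 0
    return {
        "n_edges": m,
        "n_possible": n_possible,
        "density": m / n_possible,
        "mean_abs_weight": 0.0 if empty else float(nonzero.mean()),
        "min_abs_nonzero": 0.0 if empty else float(nonzero.min()),
        "max_abs": float(absw.max()) if absw.size else 0.0,
        "empty": empty,
    }


def estimate_network(
    table: SymptomTable,
    columns: list[str] | None = None,
    start: str = "sig",
    start_alpha: float = 0.01,
    max_sweeps: int = 500,
) -> GGMNetwork:
    """Spearman correlations (complete cases) then stepwise GGM selection."""
    cols = columns if columns is not None else table.node_labels
    corr = spearman_matrix(table, columns=cols)
    communities = {c: table.communities[c] for c in cols}
    return select_ggm(
        corr, communities=communities, start=start, start_alpha=start_alpha, max_sweeps=max_sweeps
    )
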