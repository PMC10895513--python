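"""Numba kernels: iterative proportional scaling for covariance selection.

The maximum-likelihood concentration matrix of a GGM with a fixed zero
pattern matches the sample correlation matrix on every linked pair and on the
diagonal. Edge-wise IPS enforces each of those marginal constraints in turn:
a 2x2 (edge) or 1x1 (diagonal) block of K is adjusted so the implied
covariance block equals the sample block, and the running inverse is kept in
sync with low-rank Woodbury updates. Each full sweep re-inverts K once to
cancel accumulated drift.

These kernels are the inner loop of stepwise BIC model search and of the
bootstrap/permutation suites, hence the compiled implementation.
"""

import numpy as np
from numba import njit

IPS_TOL = 1e-8
IPS_MAX_SWEEPS = 2000


@njit(cache=True)
def logdet_chol(K):
    L = np.linalg.cholesky(K)
    s = 0.0
    for i in range(L.shape[0]):
        s += np.log(L[i, i])
    return 2.0 * s


@njit(cache=True)
def _trace_prod(S, K):
    p = S.shape[0]
    t = 0.0
    for i in range(p):
        for j in range(p):
            t += S[i, j] * K[j, i]
    return t


@njit(cache=True)
def ips_fit(S, adj, K, tol, max_sweeps):
    """Run IPS sweeps in place on K. Returns (sweeps_used, last_residual).

    K must be symmetric positive definite with zeros off the support of adj.
    Converged when the constraint residual — the largest deviation of the
    implied covariance from S over linked pairs and the diagonal — is < tol.
    (A scale-free criterion: an entrywise-change test on K itself is
    unattainable in float64 when S is near-singular and K has huge norm.)
    """
    p = S.shape[0]
    resid = np.inf
    for sweep in range(1, max_sweeps + 1):
        Sig = np.linalg.inv(K)
        resid = 0.0
        for i in range(p):
            r = abs(Sig[i, i] - S[i, i])
            if r > resid:
                resid = r
        for i in range(p - 1):
            for j in range(i + 1, p):
                if adj[i, j] == 1:
                    r = abs(Sig[i, j] - S[i, j])
                    if r > resid:
                        resid = r
        if resid < tol:
            return sweep, resid
        # diagonal (singleton-clique) constraints: Sig_ii = S_ii
        for i in range(p):
            d = 1.0 / S[i, i] - 1.0 / Sig[i, i]
            if d != 0.0:
                K[i, i] += d
                coef = d / (1.0 + d * Sig[i, i])
                si = Sig[:, i].copy()
                for a in range(p):
                    va = coef * si[a]
                    for b in range(p):
                        Sig[a, b] -= va * si[b]
        # edge-clique constraints: Sig block = S block
        for i in range(p - 1):
            for j in range(i + 1, p):
                if adj[i, j] == 0:
                    continue
                w11 = Sig[i, i]
                w12 = Sig[i, j]
                w22 = Sig[j, j]
                s11 = S[i, i]
                s12 = S[i, j]
                s22 = S[j, j]
                detw = w11 * w22 - w12 * w12
                dets = s11 * s22 - s12 * s12
                d11 = s22 / dets - w22 / detw
                d12 = -s12 / dets + w12 / detw
                d22 = s11 / dets - w11 / detw
                K[i, i] += d11
                K[j, j] += d22
                K[i, j] += d12
                K[j, i] += d12
                # rank-2 Woodbury: Sig <- inv(K + U D U^T)
                m11 = 1.0 + w11 * d11 + w12 * d12
                m12 = w11 * d12 + w12 * d22
                m21 = w12 * d11 + w22 * d12
                m22 = 1.0 + w12 * d12 + w22 * d22
                detm = m11 * m22 - m12 * m21
                im11 = m22 / detm
                im12 = -m12 / detm
                im21 = -m21 / detm
                im22 = m11 / detm
                c11 = d11 * im11 + d12 * im21
                c12 = d11 * im12 + d12 * im22
                c21 = d12 * im11 + d22 * im21
                c22 = d12 * im12 + d22 * im22
                ui = Sig[:, i].copy()
                uj = Sig[:, j].copy()
                for a in range(p):
                    fa = ui[a] * c11 + uj[a] * c21
                    ga = ui[a] * c12 + uj[a] * c22
                    for b in range(p):
                        Sig[a, b] -= fa * ui[b] + ga * uj[b]
    return max_sweeps, resid


@njit(cache=True)
def diag_start(S):
    p = S.shape[0]
    K = np.zeros((p, p))
    for i in range(p):
        K[i, i] = 1.0 / S[i, i]
    return K


@njit(cache=True)
def _bic_of(S, K, n, m, logn):
    # -2 * loglik + m * log(n), loglik = (n/2)(logdet K - tr(S K))
    return n * (_trace_prod(S, K) - logdet_chol(K)) + m * logn


@njit(cache=True)
def score_all_moves(S, adj, K, n_edges, n, cur_bic, tol, max_sweeps):
    """Evaluate every single-edge addition/removal; return the best move.

    Returns (found, i, j, delta_bic). Ties within 1e-10 prefer removal over
    addition, then lexicographic (i, j) order (first seen wins).
    """
    p = S.shape[0]
    logn = np.log(n)
    found = False
    best_delta = 0.0
    best_i = -1
    best_j = -1
    best_removal = False
    for i in range(p - 1):
        for j in range(i + 1, p):
            is_removal = adj[i, j] == 1
            adj[i, j] = 1 - adj[i, j]
            adj[j, i] = adj[i, j]
            Kc = K.copy()
            if is_removal:
                Kc[i, j] = 0.0
                Kc[j, i] = 0.0
                evals, _ = np.linalg.eigh(Kc)
                if evals[0] <= 1e-10:
                    Kc = diag_start(S)
            ips_fit(S, adj, Kc, tol, max_sweeps)
            m_new = n_edges - 1 if is_removal else n_edges + 1
            delta = _bic_of(S, Kc, n, m_new, logn) - cur_bic
            adj[i, j] = 1 - adj[i, j]
            adj[j, i] = adj[i, j]
            take = False
            if not found:
                if delta < -1e-10:
                    take = True
            elif delta < best_delta - 1e-10:
                take = True
            elif abs(delta - best_delta) <= 1e-10 and is_removal and not best_removal:
                take = True
            if take:
                found = True
                best_delta = delta
                best_i = i
                best_j = j
                best_removal = is_removal
    return found, best_i, best_j, best_delta
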