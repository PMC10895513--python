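"""Symptom selection, rank correlations and the child factor model.

Covers the steps that precede network estimation: Spearman correlation
matrices on complete cases (the items are ordinal and right-skewed, so
product-moment correlations of raw scores are inappropriate), a
goldbricker-style redundancy screen that flags item pairs whose correlation
profiles with the remaining items are statistically indistinguishable, and a
congeneric one-factor model summarising the three child emotional-difficulty
waves into a single factor-score node, with KMO sampling adequacy and
Cronbach's alpha reported alongside.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CorrMatrix,
    FactorResult,
    FamnetError,
    RedundancyResult,
    SymptomTable,
)


def spearman_matrix(
    table: SymptomTable | pd.DataFrame, columns: Sequence[str] | None = None
) -> CorrMatrix:
    """Spearman rank-correlation matrix on complete cases.

    Columns are rank-transformed with average ranks for ties, then the
    product-moment correlation of the ranks is taken. ``n_effective`` is the
    number of complete rows.
    """
    if isinstance(table, SymptomTable):
        df = table.complete_cases(columns)
    else:
        df = (table[list(columns)] if columns is not None else table).dropna()
    labels = list(df.columns)
    if len(df) < 3:
        raise FamnetError("need at least 3 complete rows")
    X = df.to_numpy(dtype=float)
    for k, lab in enumerate(labels):
        if np.all(X[:, k] == X[0, k]):
            raise FamnetError(f"column {lab!r} is constant on complete cases")
    ranks = stats.rankdata(X, axis=0, method="average")
    R = np.corrcoef(ranks, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrMatrix(values=R, labels=labels, n_effective=len(df))


def dependent_corr_test(
    r_jk: float, r_jh: float, r_kh: float, n: int, method: str = "hittner"
) -> float:
    """Two-sided p for H0: rho_jk = rho_jh (correlations sharing variable j).

    Fisher-z difference with the Dunn & Clark pooled covariance; ``method``
    chooses the averaged correlation plugged into the covariance term:
    ``"hittner"`` back-transforms the mean Fisher z, ``"steiger"`` averages
    the raw correlations.
    """
    if n < 10:
        raise FamnetError("n must be at least 10")
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise FamnetError("correlations must satisfy |r| < 1 (Fisher z undefined at 1)")
    if r_jk == r_jh:
        return 1.0
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    if method == "hittner":
        rm = np.tanh((z_jk + z_jh) / 2.0)
    elif method == "steiger":
        rm = (r_jk + r_jh) / 2.0
    else:
        raise FamnetError(f"unknown method {method!r}")
    rm2 = rm * rm
    cov = (r_kh * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r_kh * r_kh)) / (1 - rm2) ** 2
    denom = 2.0 - 2.0 * cov
    if denom <= 0:
        # overlap so extreme the contrast carries no information
        return 1.0
    z = (z_jk - z_jh) * np.sqrt((n - 3) / denom)
    return float(2.0 * stats.norm.sf(abs(z)))


def find_redundant_pairs(
    table: SymptomTable,
    corr_min: float = 0.50,
    prop_threshold: float = 0.25,
    alpha: float = 0.05,
    communities_to_screen: Sequence[str] = ("mother", "father"),
    method: str = "hittner",
) -> RedundancyResult:
    """Goldbricker-style redundancy screen, run per community.

    A within-community pair correlated at least ``corr_min`` is flagged when
    fewer than ``prop_threshold`` of its dependent-correlation tests against
    the community's remaining items reach ``alpha`` — i.e. its two profiles
    are statistically indistinguishable.
    """
    if not (0 < corr_min < 1) or not (0 < prop_threshold < 1):
        raise FamnetError("corr_min and prop_threshold must lie in (0, 1)")
    candidates: list[tuple[str, str, float, float]] = []
    for comm in communities_to_screen:
        cols = table.columns_in(comm)
        if len(cols) < 3:
            raise FamnetError(f"community {comm!r} has fewer than 3 nodes")
        corr = spearman_matrix(table, columns=cols)
        R, n = corr.values, corr.n_effective
        idx = {c: i for i, c in enumerate(cols)}
        for a, b in combinations(cols, 2):
            i, j = idx[a], idx[b]
            if R[i, j] < corr_min:
                continue
            pvals = [
                dependent_corr_test(R[i, h], R[j, h], R[i, j], n, method=method)
                for h in range(len(cols))
                if h not in (i, j)
            ]
            prop = float(np.mean([p < alpha for p in pvals]))
            if prop < prop_threshold:
                candidates.append((a, b, float(R[i, j]), prop))
    return RedundancyResult(
        candidate_pairs=candidates,
        threshold_config={
            "corr_min": corr_min,
            "prop_threshold": prop_threshold,
            "alpha": alpha,
            "method": method,
        },
    )


def kmo(corr: CorrMatrix | np.ndarray) -> float:
    """Kaiser-Meyer-Olkin overall measure of sampling adequacy.

    Ratio of summed squared correlations to summed squared correlations plus
    summed squared anti-image partial correlations.
    """
    R = corr.values if isinstance(corr, CorrMatrix) else np.asarray(corr, dtype=float)
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    if r2 == 0:
        raise FamnetError("all off-diagonal correlations are zero; KMO undefined")
    try:
        Kinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise FamnetError("correlation matrix is singular; KMO undefined") from exc
    d = np.sqrt(np.diag(Kinv))
    Q = -Kinv / np.outer(d, d)
    q2 = float(np.sum(Q[off] ** 2))
    return r2 / (r2 + q2)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) (1 - sum item variances / total variance)."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise FamnetError("need at least 2 columns and 3 rows")
    k = X.shape[1]
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var == 0:
        raise FamnetError("zero total variance; alpha undefined")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _closed_form_loadings(S: np.ndarray) -> np.ndarray:
    """Exact ML loadings for the just-identified 3-indicator factor model.

    With covariances s_ij = l_i l_j the model has zero degrees of freedom and
    lambda_1 = sqrt(s12 s13 / s23) (and cyclic permutations).
    """
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    if s12 * s13 * s23 <= 0:
        raise FamnetError(
            "indicator covariances do not admit a positive one-factor solution"
        )
    return np.array(
        [
            np.sqrt(s12 * s13 / s23),
            np.sqrt(s12 * s23 / s13),
            np.sqrt(s13 * s23 / s12),
        ]
    )


def fit_one_factor(
    wave_scores: pd.DataFrame, scoring: str = "regression"
) -> FactorResult:
    """Congeneric one-factor model of three wave scores, with factor scores.

    Maximum-likelihood loadings/uniquenesses (closed form: three indicators
    exactly identify the model); scores by the regression method
    ``f = L' S^{-1} (x - mean)`` (or Bartlett). A Heywood (negative
    uniqueness) solution raises a warning and clamps the uniqueness at 1e-6.
    Also reports KMO, Cronbach's alpha, and pairwise Spearman wave
    correlations.
    """
    if wave_scores.shape[1] != 3:
        raise FamnetError("exactly 3 indicator columns are required")
    df = wave_scores.dropna()
    if len(df) < 10:
        raise FamnetError("need at least 10 complete rows")
    X = df.to_numpy(dtype=float)
    S = np.cov(X, rowvar=False, ddof=1)
    lam = _closed_form_loadings(S)
    psi = np.diag(S) - lam**2
    heywood = bool(np.any(psi < 0))
    if heywood:
        warnings.warn("Heywood case: uniqueness clamped at 1e-6", stacklevel=2)
        psi = np.clip(psi, 1e-6, None)

    centred = X - X.mean(axis=0)
    if scoring == "regression":
        w = np.linalg.solve(S, lam)
    elif scoring == "bartlett":
        Pinv = np.diag(1.0 / psi)
        w = (Pinv @ lam) / float(lam @ Pinv @ lam)
    else:
        raise FamnetError(f"unknown scoring method {scoring!r}")
    scores = pd.Series(centred @ w, index=df.index, name="factor_score")

    ranks = stats.rankdata(X, axis=0, method="average")
    Rw = np.corrcoef(ranks, rowvar=False)
    wave_corrs = np.array([Rw[0, 1], Rw[0, 2], Rw[1, 2]])
    d = 1.0 / np.sqrt(np.diag(S))
    Rp = S * np.outer(d, d)
    np.fill_diagonal(Rp, 1.0)
    return FactorResult(
        loadings=lam,
        uniquenesses=psi,
        scores=scores,
        kmo=kmo(Rp),
        alpha=cronbach_alpha(X),
        wave_correlations=wave_corrs,
        heywood=heywood,
    )
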