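"""Permutation network comparison and split-half replication.

Two estimated networks are compared on global strength (the sum of absolute
edge weights) and structure (the maximum absolute edge-weight difference over
all node pairs). The null distribution reassigns rows at random to two groups
of the original sizes and re-estimates both networks per permutation, so the
test accounts for model-search variability. p-values use the add-one
formula (1 + #{perm >= observed}) / (1 + n_perm) and are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import FamnetError, GGMNetwork

Estimator = Callable[[pd.DataFrame], GGMNetwork]


@dataclass
class NCTResult:
    """Observed differences and permutation p-values for the two invariance tests."""

    observed_strength_diff: float
    observed_max_edge_diff: float
    p_strength: float
    p_structure: float
    n_perm: int
    seed: int
    perm_strength: np.ndarray = field(repr=False, default=None)
    perm_structure: np.ndarray = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "observed_strength_diff": float(self.observed_strength_diff),
            "observed_max_edge_diff": float(self.observed_max_edge_diff),
            "p_strength": float(self.p_strength),
            "p_structure": float(self.p_structure),
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
        }


def global_strength(net: GGMNetwork) -> float:
    """Sum of absolute weights over unique edges."""
    return float(np.abs(np.triu(net.weights, 1)).sum())


def _diffs(net_a: GGMNetwork, net_b: GGMNetwork) -> tuple[float, float]:
    s = abs(global_strength(net_a) - global_strength(net_b))
    m = float(np.max(np.abs(net_a.weights - net_b.weights)))
    return s, m


def nct(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    estimator: Estimator,
    n_perm: int = 1000,
    seed: int = 0,
) -> NCTResult:
    """Permutation test of global-strength and structure invariance."""
    if list(table_a.columns) != list(table_b.columns):
        raise FamnetError("the two tables must share an identical column set")
    if n_perm < 100:
        raise FamnetError("n_perm must be at least 100")
    net_a = estimator(table_a)
    net_b = estimator(table_b)
    if net_a.labels != net_b.labels:
        raise FamnetError("estimated networks have mismatched node sets")
    obs_s, obs_m = _diffs(net_a, net_b)

    pooled = pd.concat([table_a, table_b], ignore_index=True)
    n_a = len(table_a)
    n_total = len(pooled)
    rng = np.random.default_rng(seed)
    perm_s = np.empty(n_perm)
    perm_m = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(n_total)
        ga = pooled.iloc[order[:n_a]].reset_index(drop=True)
        gb = pooled.iloc[order[n_a:]].reset_index(drop=True)
        pa = estimator(ga)
        pb = estimator(gb)
        perm_s[b], perm_m[b] = _diffs(pa, pb)

    p_strength = (1.0 + np.sum(perm_s >= obs_s)) / (1.0 + n_perm)
    p_structure = (1.0 + np.sum(perm_m >= obs_m)) / (1.0 + n_perm)
    return NCTResult(
        observed_strength_diff=obs_s,
        observed_max_edge_diff=obs_m,
        p_strength=float(p_strength),
        p_structure=float(p_structure),
        n_perm=n_perm,
        seed=seed,
        perm_strength=perm_s,
        perm_structure=perm_m,
    )


def split_half_replication(
    table: pd.DataFrame,
    estimator: Estimator,
    n_perm: int = 1000,
    seed: int = 0,
) -> NCTResult:
    """Random half-split of the sample followed by the permutation comparison."""
    n = len(table)
    if n < 40:
        raise FamnetError("need at least 40 rows for a split-half comparison")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    half_a = table.iloc[order[: n // 2]].reset_index(drop=True)
    half_b = table.iloc[order[n // 2 :]].reset_index(drop=True)
    return nct(half_a, half_b, estimator, n_perm=n_perm, seed=seed + 1)
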