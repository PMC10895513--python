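"""Bootstrap accuracy and case-dropping stability of the estimated network.

Edge accuracy uses a nonparametric row bootstrap with full re-estimation
(Spearman correlations and stepwise BIC selection) per replicate, so the
intervals reflect model-search variability, not just sampling noise around a
fixed structure. Centrality stability uses case-dropping subset bootstraps:
for each drop proportion, subsamples without replacement are re-estimated and
their centralities correlated with the full-sample values; the CS coefficient
is the largest drop proportion at which that correlation stays above 0.7 in
at least 95% of subsamples (> 0.25 acceptable, > 0.5 preferred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .centrality import bridge_centrality, node_centrality
from .datatypes import FamnetError, GGMNetwork

logger = logging.getLogger(__name__)

Estimator = Callable[[pd.DataFrame], GGMNetwork]

DEFAULT_DROP_GRID = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)
_MAX_FAILURE_SHARE = 0.10


def _edge_key(a: str, b: str) -> str:
    return f"{a}~{b}"


def _centrality_of(net: GGMNetwork, kind: str) -> pd.Series:
    if kind == "strength":
        return node_centrality(net, signed=False)
    if kind == "expected_influence":
        return node_centrality(net, signed=True)
    if kind == "bridge_strength":
        return bridge_centrality(net, signed=False)
    if kind == "bridge_expected_influence":
        return bridge_centrality(net, signed=True)
    raise FamnetError(f"unknown centrality kind {kind!r}")


@dataclass
class EdgeBootstrap:
    """Percentile bootstrap summary of edge weights (and node strength)."""

    summary: pd.DataFrame
    edge_replicates: pd.DataFrame = field(repr=False)
    strength_replicates: pd.DataFrame = field(repr=False)
    B: int
    n_failed: int
    seed: int

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.summary.to_csv(fh, index=False)


@dataclass
class CaseDropResult:
    """Correlations between full-sample and subsampled centralities."""

    centrality_kind: str
    correlations: pd.DataFrame  # columns = drop proportions, rows = replicates
    B: int
    seed: int

    @property
    def drop_proportions(self) -> list[float]:
        return [float(c) for c in self.correlations.columns]


def _resample_loop(n_rep: int, fit_one: Callable[[int], object], what: str):
    """Run replicate fits, tolerating up to 10% labelled failures."""
    out, n_failed = [], 0
    for b in range(n_rep):
        try:
            out.append(fit_one(b))
        except (FamnetError, RuntimeError) as exc:
            n_failed += 1
            logger.info("%s replicate %d failed: %s", what, b, exc)
        if (b + 1) % 100 == 0:
            logger.info("%s: %d/%d replicates (%d failed)", what, b + 1, n_rep, n_failed)
    if n_failed > _MAX_FAILURE_SHARE * n_rep:
        raise FamnetError(
            f"{what}: {n_failed}/{n_rep} replicates failed (> {_MAX_FAILURE_SHARE:.0%})"
        )
    return out, n_failed


def bootstrap_edges(
    table: pd.DataFrame,
    estimator: Estimator,
    B: int = 1000,
    seed: int = 0,
) -> EdgeBootstrap:
    """Nonparametric bootstrap of edge weights with full re-estimation.

    Every node pair contributes a row (absent edges have weight 0), so the
    intervals also capture edge-selection uncertainty.
    """
    if B < 100:
        raise FamnetError("B must be at least 100")
    full = estimator(table)
    labels = full.labels
    p = len(labels)
    iu = np.triu_indices(p, 1)
    edge_names = [_edge_key(labels[i], labels[j]) for i, j in zip(*iu)]

    rng = np.random.default_rng(seed)
    n = len(table)

    def fit_one(_b: int):
        idx = rng.integers(0, n, size=n)
        net = estimator(table.iloc[idx].reset_index(drop=True))
        if net.labels != labels:
            raise FamnetError("replicate produced a different node set")
        return net.weights[iu], node_centrality(net, signed=False).to_numpy()

    reps, n_failed = _resample_loop(B, fit_one, "edge bootstrap")
    edge_mat = np.array([r[0] for r in reps])
    strength_mat = np.array([r[1] for r in reps])

    lo, hi = np.percentile(edge_mat, [2.5, 97.5], axis=0)
    summary = pd.DataFrame(
        {
            "node1": [labels[i] for i in iu[0]],
            "node2": [labels[j] for j in iu[1]],
            "observed": full.weights[iu],
            "boot_mean": edge_mat.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    return EdgeBootstrap(
        summary=summary,
        edge_replicates=pd.DataFrame(edge_mat, columns=edge_names),
        strength_replicates=pd.DataFrame(strength_mat, columns=labels),
        B=B,
        n_failed=n_failed,
        seed=seed,
    )


def casedrop_bootstrap(
    table: pd.DataFrame,
    estimator: Estimator,
    drop_proportions: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 500,
    centrality_kind: str = "strength",
    seed: int = 0,
) -> CaseDropResult:
    """Case-dropping subset bootstrap of a centrality index."""
    if B < 100:
        raise FamnetError("B must be at least 100")
    props = [float(x) for x in drop_proportions]
    if any(not (0 < x <= 0.95) for x in props):
        raise FamnetError("drop proportions must lie in (0, 0.95]")
    full = estimator(table)
    c0 = _centrality_of(full, centrality_kind)
    n = len(table)
    rng = np.random.default_rng(seed)

    cols = {}
    for prop in props:
        keep = int(round((1.0 - prop) * n))
        if keep < 10:
            raise FamnetError(f"drop proportion {prop} leaves fewer than 10 rows")

        def fit_one(_b: int, keep=keep):
            idx = rng.choice(n, size=keep, replace=False)
            net = estimator(table.iloc[idx].reset_index(drop=True))
            c_sub = _centrality_of(net, centrality_kind).reindex(c0.index)
            r = np.corrcoef(c_sub.to_numpy(), c0.to_numpy())[0, 1]
            return 0.0 if np.isnan(r) else float(r)

        corrs, _ = _resample_loop(B, fit_one, f"case-drop {prop:.2f}")
        cols[prop] = pd.Series(corrs)
    return CaseDropResult(
        centrality_kind=centrality_kind,
        correlations=pd.DataFrame(cols),
        B=B,
        seed=seed,
    )


def cs_coefficient(
    result: CaseDropResult, cor_floor: float = 0.7, certainty: float = 0.95
) -> float:
    """Correlation-stability coefficient from a case-dropping result.

    The largest tested drop proportion at which at least ``certainty`` of the
    replicate correlations stay at or above ``cor_floor``; 0 if none does.
    """
    if result.correlations.empty:
        raise FamnetError("case-drop result is empty")
    qualifying = [
        prop
        for prop in result.drop_proportions
        if (result.correlations[prop].dropna() >= cor_floor).mean() >= certainty
    ]
    return max(qualifying) if qualifying else 0.0


def difference_test(
    replicates: pd.DataFrame | EdgeBootstrap,
    item_a: str,
    item_b: str,
    ci: float = 0.95,
    use: str = "edges",
) -> bool:
    """Bootstrapped difference test between two edges or two nodes.

    Significant when the percentile CI of (value_a - value_b) across
    replicates excludes 0. For an :class:`EdgeBootstrap`, ``use`` selects the
    edge-weight (``"edges"``) or strength (``"strength"``) replicates; edge
    items are named ``"node1~node2"`` in estimation label order.
    """
    if isinstance(replicates, EdgeBootstrap):
        reps = replicates.edge_replicates if use == "edges" else replicates.strength_replicates
    else:
        reps = replicates
    for item in (item_a, item_b):
        if item not in reps.columns:
            raise FamnetError(f"item {item!r} not present in the bootstrap replicates")
    if item_a == item_b:
        return False
    diff = reps[item_a].to_numpy() - reps[item_b].to_numpy()
    tail = (1.0 - ci) / 2.0 * 100
    lo, hi = np.percentile(diff, [tail, 100 - tail])
    return bool(lo > 0 or hi < 0)
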