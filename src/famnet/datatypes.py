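"""Core containers shared across the estimation pipeline.

The analysis operates on three kinds of objects: per-family symptom tables
(ordinal parent depression items plus continuous child subscale scores), a
ground-truth partial-correlation network used by the synthetic generator, and
estimated Gaussian-graphical-model networks with partial-correlation edge
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MOTHER = "mother"
FATHER = "father"
CHILD = "child"

#: ordinal EPDS-style item scale (integers 1..4)
ORDINAL_1_4 = "ordinal_1_4"
#: SDQ-style subscale scores bounded in [0, 10]
SUBSCALE_0_10 = "subscale_0_10"
#: unbounded continuous column (e.g. a factor score or covariate)
CONTINUOUS = "continuous"


class FamnetError(ValueError):
    """Base class for labelled input/validation errors."""


@dataclass
class TrueNetwork:
    """Population partial-correlation network with community annotations.

    ``pcor`` is the symmetric matrix of true partial correlations (zero
    diagonal); ``bridge_edges`` lists the node pairs that cross community
    boundaries by construction.
    """

    pcor: np.ndarray
    node_labels: list[str]
    communities: dict[str, str]
    bridge_edges: list[tuple[str, str]]
    seed: int

    def __post_init__(self) -> None:
        self.pcor = np.asarray(self.pcor, dtype=float)
        p = len(self.node_labels)
        if self.pcor.shape != (p, p):
            raise FamnetError(
                f"pcor shape {self.pcor.shape} does not match {p} node labels"
            )
        if not np.allclose(self.pcor, self.pcor.T, atol=1e-12):
            raise FamnetError("pcor must be symmetric")
        if np.any(np.abs(np.diag(self.pcor)) > 0):
            raise FamnetError("pcor diagonal must be exactly zero")
        if np.any(np.abs(self.pcor) >= 1):
            raise FamnetError("all |pcor| must be < 1")
        missing = [n for n in self.node_labels if n not in self.communities]
        if missing:
            raise FamnetError(f"nodes without a community: {missing}")
        idx = {n: i for i, n in enumerate(self.node_labels)}
        for a, b in self.bridge_edges:
            if self.communities[a] == self.communities[b]:
                raise FamnetError(f"bridge edge ({a}, {b}) is within one community")
            if self.pcor[idx[a], idx[b]] == 0:
                raise FamnetError(f"bridge edge ({a}, {b}) has zero weight")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index(self, label: str) -> int:
        return self.node_labels.index(label)

    def adjacency(self) -> np.ndarray:
        """0/1 support of the true network."""
        return (self.pcor != 0).astype(int)

    def to_json_dict(self) -> dict:
        edges = []
        p = self.n_nodes
        for i in range(p - 1):
            for j in range(i + 1, p):
                if self.pcor[i, j] != 0:
                    edges.append(
                        {
                            "node1": self.node_labels[i],
                            "node2": self.node_labels[j],
                            "weight": float(self.pcor[i, j]),
                        }
                    )
        return {
            "labels": list(self.node_labels),
            "communities": dict(self.communities),
            "edges": edges,
            "bridge_edges": [list(e) for e in self.bridge_edges],
            "seed": self.seed,
        }


@dataclass
class SymptomTable:
    """Rectangular per-family symptom data with node metadata.

    ``data`` holds one row per family; missing entries are NaN. ``scales``
    maps every column to one of :data:`ORDINAL_1_4`, :data:`SUBSCALE_0_10`
    or :data:`CONTINUOUS`.
    """

    data: pd.DataFrame
    communities: dict[str, str]
    scales: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise FamnetError("node labels must be unique")
        for col in cols:
            if col not in self.communities:
                raise FamnetError(f"column {col!r} has no community")
            if col not in self.scales:
                raise FamnetError(f"column {col!r} has no scale")
        for col, scale in self.scales.items():
            if col not in cols:
                continue
            vals = self.data[col].dropna().to_numpy()
            if scale == ORDINAL_1_4:
                if vals.size and not np.isin(vals, [1, 2, 3, 4]).all():
                    raise FamnetError(f"ordinal column {col!r} outside {{1,2,3,4}}")
            elif scale == SUBSCALE_0_10:
                if vals.size and (vals.min() < 0 or vals.max() > 10):
                    raise FamnetError(f"subscale column {col!r} outside [0, 10]")

    @property
    def node_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_families(self) -> int:
        return len(self.data)

    def columns_in(self, community: str) -> list[str]:
        return [c for c in self.data.columns if self.communities[c] == community]

    def complete_cases(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(columns) if columns is not None else list(self.data.columns)
        return self.data[cols].dropna()

    def subset(self, columns: Sequence[str]) -> "SymptomTable":
        cols = list(columns)
        return SymptomTable(
            data=self.data[cols].copy(),
            communities={c: self.communities[c] for c in cols},
            scales={c: self.scales[c] for c in cols},
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        communities: Mapping[str, str],
        scales: Mapping[str, str] | None = None,
    ) -> "SymptomTable":
        df = pd.read_csv(path, comment="#")
        if scales is None:
            scales = {}
            for col in df.columns:
                vals = df[col].dropna().to_numpy()
                if vals.size and np.isin(vals, [1, 2, 3, 4]).all():
                    scales[col] = ORDINAL_1_4
                elif vals.size and vals.min() >= 0 and vals.max() <= 10:
                    scales[col] = SUBSCALE_0_10
                else:
                    scales[col] = CONTINUOUS
        return cls(data=df, communities=dict(communities), scales=dict(scales))


@dataclass
class CorrMatrix:
    """Spearman correlation matrix with its effective (complete-case) n."""

    values: np.ndarray
    labels: list[str]
    n_effective: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise FamnetError("correlation matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise FamnetError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise FamnetError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise FamnetError("correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.labels)


@dataclass
class GGMNetwork:
    """Estimated Gaussian graphical model.

    ``weights`` are partial correlations (zero diagonal); ``adjacency`` is the
    selected 0/1 edge pattern. ``loglik``/``bic`` refer to the constrained
    maximum-likelihood fit on ``n`` effective observations.
    """

    weights: np.ndarray
    adjacency: np.ndarray
    labels: list[str]
    communities: dict[str, str]
    loglik: float
    bic: float
    n: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        p = len(self.labels)
        if self.weights.shape != (p, p) or self.adjacency.shape != (p, p):
            raise FamnetError("matrix shapes do not match labels")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise FamnetError("weights must be symmetric")
        if np.any(np.abs(np.diag(self.weights)) > 0):
            raise FamnetError("weights diagonal must be zero")
        if np.any(np.abs(self.weights) >= 1):
            raise FamnetError("all |weights| must be < 1")
        mismatch = (np.abs(self.weights) > 1e-10) != (self.adjacency == 1)
        np.fill_diagonal(mismatch, False)
        if mismatch.any():
            raise FamnetError("adjacency and nonzero weights disagree")

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p - 1):
            for j in range(i + 1, self.p):
                if self.adjacency[i, j]:
                    out.append((self.labels[i], self.labels[j], float(self.weights[i, j])))
        return out

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "communities": dict(self.communities),
            "edges": [
                {"node1": a, "node2": b, "weight": w} for a, b, w in self.edge_list()
            ],
            "n": int(self.n),
            "loglik": float(self.loglik),
            "bic": float(self.bic),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GGMNetwork":
        labels = list(d["labels"])
        idx = {lab: i for i, lab in enumerate(labels)}
        p = len(labels)
        W = np.zeros((p, p))
        A = np.zeros((p, p), dtype=int)
        for e in d["edges"]:
            i, j = idx[e["node1"]], idx[e["node2"]]
            W[i, j] = W[j, i] = e["weight"]
            A[i, j] = A[j, i] = 1
        return cls(
            weights=W,
            adjacency=A,
            labels=labels,
            communities=dict(d["communities"]),
            loglik=float(d["loglik"]),
            bic=float(d["bic"]),
            n=int(d["n"]),
        )


@dataclass
class FactorResult:
    """One-factor model of the three child emotional-difficulty waves."""

    loadings: np.ndarray
    uniquenesses: np.ndarray
    scores: pd.Series
    kmo: float
    alpha: float
    wave_correlations: np.ndarray
    heywood: bool = False

    def to_json_dict(self) -> dict:
        return {
            "loadings": [float(x) for x in self.loadings],
            "uniquenesses": [float(x) for x in self.uniquenesses],
            "kmo": float(self.kmo),
            "alpha": float(self.alpha),
            "wave_correlations": [float(x) for x in self.wave_correlations],
            "heywood": bool(self.heywood),
            "score_range": [float(self.scores.min()), float(self.scores.max())],
        }


@dataclass
class RedundancyResult:
    """Goldbricker-style screen for overlapping (redundant) item pairs."""

    candidate_pairs: list[tuple[str, str, float, float]]
    threshold_config: dict = field(default_factory=dict)

    @property
    def flagged(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _, _ in self.candidate_pairs]

    def to_json_dict(self) -> dict:
        return {
            "candidate_pairs": [
                {
                    "node1": a,
                    "node2": b,
                    "correlation": float(r),
                    "prop_significantly_different": float(prop),
                }
                for a, b, r, prop in self.candidate_pairs
            ],
            "threshold_config": dict(self.threshold_config),
        }
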