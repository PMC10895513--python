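"""Synthetic mother-father-child symptom data with a known network.

Real postnatal-depression cohorts are access-restricted, so every estimation
stage here is validated against data drawn from a latent multivariate normal
whose sparse partial-correlation structure is known exactly: two parent
communities of EPDS-style items, designated cross-parent bridge edges, and
optionally a continuous child emotional-difficulties factor tied to selected
parent symptoms. Parent items are discretised to an ordinal 1-4 scale with
right-skewed endorsement; the child factor is emitted as three noisy wave
scores on a 0-10 subscale.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CHILD,
    CONTINUOUS,
    FATHER,
    MOTHER,
    ORDINAL_1_4,
    SUBSCALE_0_10,
    FamnetError,
    SymptomTable,
    TrueNetwork,
)

# EPDS-style symptom short names, ordered so that the clinically salient
# bridge candidates (guilt, self-harm ideation) survive truncation to < 10.
EPDS_ITEMS = (
    "sad",
    "cry",
    "guilt",
    "selfharm",
    "insomnia",
    "worry",
    "panic",
    "overwhelm",
    "enjoy",
    "funny",
)

CHILD_NODE = "child_emot"
CHILD_WAVES = ("emot_9y", "emot_11y", "emot_13y")

#: latent-scale cutpoints producing right-skewed 1-4 endorsement
DEFAULT_CUTPOINTS = (0.25, 1.0, 1.9)
#: wave measurement model: score = offset + scale * (loading * factor + noise)
DEFAULT_CHILD_LOADINGS = (0.75, 0.75, 0.75)
DEFAULT_CHILD_NOISE_SD = 0.62
_CHILD_WAVE_OFFSET = 1.5
_CHILD_WAVE_SCALE = 2.0

_MIN_EIG = 1e-6
_SHRINK_FACTOR = 0.95
_MAX_SHRINK_STEPS = 100


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named sub-stream of the single master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def parent_labels(n_mother: int, n_father: int) -> tuple[list[str], dict[str, str]]:
    def names(prefix: str, n: int) -> list[str]:
        if n <= len(EPDS_ITEMS):
            return [f"{prefix}_{s}" for s in EPDS_ITEMS[:n]]
        extra = [f"{prefix}_sym{k:02d}" for k in range(len(EPDS_ITEMS) + 1, n + 1)]
        return [f"{prefix}_{s}" for s in EPDS_ITEMS] + extra

    mothers = names("m", n_mother)
    fathers = names("f", n_father)
    communities = {lab: MOTHER for lab in mothers}
    communities.update({lab: FATHER for lab in fathers})
    return mothers + fathers, communities


def partial_to_covariance(pcor: np.ndarray) -> np.ndarray:
    """Correlation-scale covariance implied by a partial-correlation matrix.

    Builds the precision matrix K = I - P (P the partial correlations with
    zero diagonal), for which -K_ij / sqrt(K_ii K_jj) = P_ij, inverts it and
    standardises to unit diagonal. Partial correlations are invariant to the
    rescaling, so the returned covariance round-trips to ``pcor``.
    """
    P = np.asarray(pcor, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise FamnetError("pcor must be a square matrix")
    if not np.allclose(P, P.T, atol=1e-12):
        raise FamnetError("pcor must be symmetric")
    if np.any(np.abs(np.diag(P)) > 0):
        raise FamnetError("pcor diagonal must be zero")
    if np.any(np.abs(P) >= 1):
        raise FamnetError("all |pcor| must be < 1")
    K = np.eye(P.shape[0]) - P
    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin <= 0:
        raise FamnetError(
            f"implied precision is not positive definite (min eigenvalue {eigmin:.3e})"
        )
    cov = np.linalg.inv(K)
    d = 1.0 / np.sqrt(np.diag(cov))
    cov = cov * d[:, None] * d[None, :]
    cov = (cov + cov.T) / 2.0
    np.fill_diagonal(cov, 1.0)
    return cov


def build_true_network(
    n_mother: int,
    n_father: int,
    within_density: float,
    bridge_pairs: Sequence[tuple[str, str]],
    weight_low: float = 0.05,
    weight_high: float = 0.4,
    seed: int = 0,
    child_links: Sequence[str] | None = None,
) -> TrueNetwork:
    """Construct a two-community parent network with designated bridges.

    Within-community edges are sampled independently at ``within_density``;
    cross-community edges are exactly ``bridge_pairs``. All edge weights are
    drawn uniformly in [weight_low, weight_high] (positive, matching the
    all-positive networks typical of depression symptom data). If
    ``child_links`` is given, a continuous child factor node is appended and
    connected to the listed parent nodes; those links count as bridge edges.
    The matrix is shrunk uniformly (off-diagonals only) until the implied
    precision is positive definite.
    """
    if n_mother < 3 or n_father < 3:
        raise FamnetError("need at least 3 nodes per parent community")
    if not 0 <= within_density <= 1:
        raise FamnetError("within_density must lie in [0, 1]")
    if not (0 < weight_low <= weight_high < 1):
        raise FamnetError("need 0 < weight_low <= weight_high < 1")
    labels, communities = parent_labels(n_mother, n_father)
    if child_links:
        for lab in child_links:
            if lab not in labels:
                raise FamnetError(f"child link target {lab!r} is not a parent node")
        labels = labels + [CHILD_NODE]
        communities[CHILD_NODE] = CHILD
    idx = {lab: i for i, lab in enumerate(labels)}

    for a, b in bridge_pairs:
        if a not in idx or b not in idx:
            raise FamnetError(f"bridge pair ({a}, {b}) names an unknown node")
        if communities[a] == communities[b]:
            raise FamnetError(f"bridge pair ({a}, {b}) lies within one community")

    rng = _rng(seed, 0)
    p = len(labels)
    P = np.zeros((p, p))

    def draw() -> float:
        return float(rng.uniform(weight_low, weight_high))

    for comm_labels in (labels[:n_mother], labels[n_mother : n_mother + n_father]):
        for i in range(len(comm_labels) - 1):
            for j in range(i + 1, len(comm_labels)):
                if rng.uniform() < within_density:
                    a, b = idx[comm_labels[i]], idx[comm_labels[j]]
                    P[a, b] = P[b, a] = draw()

    bridges = [tuple(pair) for pair in bridge_pairs]
    for a, b in bridges:
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = draw()
    if child_links:
        for lab in child_links:
            P[idx[lab], idx[CHILD_NODE]] = P[idx[CHILD_NODE], idx[lab]] = draw()
            bridges.append((lab, CHILD_NODE))

    # uniform off-diagonal shrinkage until I - P is comfortably PD
    for _ in range(_MAX_SHRINK_STEPS):
        if np.linalg.eigvalsh(np.eye(p) - P).min() >= _MIN_EIG:
            break
        P *= _SHRINK_FACTOR
    else:
        raise FamnetError("could not reach positive definiteness by shrinkage")

    return TrueNetwork(
        pcor=P, node_labels=labels, communities=communities, bridge_edges=bridges, seed=seed
    )


def _normalise_cutpoints(
    ordinal_thresholds, parent_cols: list[str]
) -> dict[str, tuple[float, float, float]]:
    if ordinal_thresholds is None:
        ordinal_thresholds = DEFAULT_CUTPOINTS
    if isinstance(ordinal_thresholds, Mapping):
        per_node = {c: tuple(ordinal_thresholds[c]) for c in parent_cols}
    else:
        per_node = {c: tuple(ordinal_thresholds) for c in parent_cols}
    for col, cuts in per_node.items():
        if len(cuts) != 3 or not (cuts[0] < cuts[1] < cuts[2]):
            raise FamnetError(
                f"cutpoints for {col!r} must be 3 strictly increasing values, got {cuts}"
            )
    return per_node


def sample_family_data(
    truth: TrueNetwork,
    n_families: int,
    ordinal_thresholds=None,
    child_loadings: Sequence[float] = DEFAULT_CHILD_LOADINGS,
    child_noise_sd: float = DEFAULT_CHILD_NOISE_SD,
    seed: int = 0,
) -> SymptomTable:
    """Draw per-family symptom data from the latent Gaussian model.

    Latent vectors come from the multivariate normal implied by
    ``truth.pcor``; parent nodes are discretised to 1-4 by the cutpoints, and
    a child factor node (if present in ``truth``) is expanded into three wave
    scores ``offset + scale * (loading * factor + noise)``, rounded and
    clipped into [0, 10].
    """
    if n_families < 10:
        raise FamnetError("n_families must be at least 10")
    cov = partial_to_covariance(truth.pcor)
    parent_cols = [lab for lab in truth.node_labels if truth.communities[lab] != CHILD]
    per_node_cuts = _normalise_cutpoints(ordinal_thresholds, parent_cols)
    has_child = CHILD_NODE in truth.node_labels
    if has_child and len(child_loadings) != 3:
        raise FamnetError("child_loadings must have exactly 3 values")

    latent = _rng(seed, 0).multivariate_normal(
        np.zeros(truth.n_nodes), cov, size=n_families, method="cholesky"
    )
    columns: dict[str, np.ndarray] = {}
    communities: dict[str, str] = {}
    scales: dict[str, str] = {}
    for lab in parent_cols:
        z = latent[:, truth.index(lab)]
        columns[lab] = (np.digitize(z, per_node_cuts[lab]) + 1).astype(float)
        communities[lab] = truth.communities[lab]
        scales[lab] = ORDINAL_1_4
    if has_child:
        f = latent[:, truth.index(CHILD_NODE)]
        noise_rng = _rng(seed, 1)
        for w, (wave, lam) in enumerate(zip(CHILD_WAVES, child_loadings)):
            raw = lam * f + noise_rng.normal(0.0, child_noise_sd, size=n_families)
            score = np.clip(
                np.rint(_CHILD_WAVE_OFFSET + _CHILD_WAVE_SCALE * raw), 0, 10
            )
            columns[wave] = score
            communities[wave] = CHILD
            scales[wave] = SUBSCALE_0_10

    return SymptomTable(
        data=pd.DataFrame(columns), communities=communities, scales=scales
    )


def sample_latent_data(
    truth: TrueNetwork, n_families: int, seed: int = 0
) -> "pd.DataFrame":
    """Continuous draws from the latent Gaussian implied by ``truth``.

    Skips the ordinal measurement model entirely: used to benchmark the
    network estimator under correct specification, where the sparse
    partial-correlation structure holds exactly on the sampled scale.
    """
    if n_families < 10:
        raise FamnetError("n_families must be at least 10")
    cov = partial_to_covariance(truth.pcor)
    Z = _rng(seed, 0).multivariate_normal(
        np.zeros(truth.n_nodes), cov, size=n_families, method="cholesky"
    )
    return pd.DataFrame(Z, columns=truth.node_labels)


def write_true_network_json(truth: TrueNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
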