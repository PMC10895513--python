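"""Strength, expected influence and bridge centrality over communities.

Strength is the absolute sum of a node's incident edge weights; expected
influence keeps the signs. The bridge variants restrict the sum to edges
leaving the node's own community, quantifying how strongly a symptom
transmits activation to the other parent's (or the child's) symptom set.
"""

from __future__ import annotations

from math import ceil
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import CHILD, FamnetError, GGMNetwork


def node_centrality(net: GGMNetwork, signed: bool = False) -> pd.Series:
    """Strength (``signed=False``) or expected influence (``signed=True``)."""
    W = net.weights if signed else np.abs(net.weights)
    name = "expected_influence" if signed else "strength"
    return pd.Series(W.sum(axis=1), index=net.labels, name=name)


def bridge_centrality(
    net: GGMNetwork,
    communities: Mapping[str, str] | None = None,
    signed: bool = False,
) -> pd.Series:
    """Cross-community strength (or signed expected influence) per node."""
    comms = communities if communities is not None else net.communities
    missing = [lab for lab in net.labels if lab not in comms]
    if missing:
        raise FamnetError(f"nodes without a community: {missing}")
    member = np.array([comms[lab] for lab in net.labels])
    cross = member[:, None] != member[None, :]
    W = (net.weights if signed else np.abs(net.weights)) * cross
    name = "bridge_expected_influence" if signed else "bridge_strength"
    return pd.Series(W.sum(axis=1), index=net.labels, name=name)


def flag_bridges(values: pd.Series, top_prop: float = 0.30) -> pd.Series:
    """Flag the ceil(top_prop * n) highest-scoring nodes, ties inclusive.

    Nodes scoring exactly zero are never flagged: a symptom with no
    cross-community connectivity cannot act as a bridge, however short the
    ranking is.
    """
    if not (0 < top_prop < 1):
        raise FamnetError("top_prop must lie in (0, 1)")
    n = len(values)
    k = ceil(top_prop * n)
    cutoff = values.sort_values(ascending=False).iloc[k - 1]
    return ((values >= cutoff) & (values > 0)).rename("is_bridge")


def centrality_table(
    net: GGMNetwork,
    top_prop: float = 0.30,
    flag_parent_only: bool = True,
) -> pd.DataFrame:
    """Full per-node centrality table with bridge flags.

    When a child factor node is present and ``flag_parent_only`` is set, the
    top-proportion bridge flag is computed over the parent nodes only (the
    child node is excluded from the denominator and never flagged).
    """
    comms = net.communities
    df = pd.DataFrame(
        {
            "community": pd.Series({lab: comms[lab] for lab in net.labels}),
            "strength": node_centrality(net, signed=False),
            "expected_influence": node_centrality(net, signed=True),
            "bridge_strength": bridge_centrality(net, signed=False),
            "bridge_expected_influence": bridge_centrality(net, signed=True),
        }
    )
    df.index.name = "node"
    eligible = df.index.to_series().map(lambda lab: comms[lab] != CHILD)
    if flag_parent_only and not eligible.all():
        flags = flag_bridges(df.loc[eligible, "bridge_strength"], top_prop)
        df["is_bridge"] = flags.reindex(df.index, fill_value=False)
    else:
        df["is_bridge"] = flag_bridges(df["bridge_strength"], top_prop)
    return df
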