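"""Configuration-driven three-step analysis driver.

Step 1 estimates the parent symptom network (redundancy screen, Spearman
correlations, stepwise BIC selection) with centrality and stability
artifacts; step 2 flags bridge symptoms across the mother/father communities;
step 3 summarises the child emotional-difficulty waves into a factor-score
node, appends it, and re-estimates the enlarged network. Every output file
carries a header recording the configuration hash and seed, so runs are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import stability as stab
from .centrality import bridge_centrality, centrality_table, flag_bridges
from .comparison import NCTResult, split_half_replication
from .datatypes import CHILD, CONTINUOUS, FamnetError, GGMNetwork, SymptomTable
from .ggm import estimate_network
from .preprocessing import find_redundant_pairs, fit_one_factor

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, validated analysis configuration (YAML on disk)."""

    input: str
    outdir: str
    seed: int
    communities: dict[str, str]
    drop_items: list[str] = field(default_factory=list)
    redundancy_enabled: bool = True
    redundancy_corr_min: float = 0.50
    redundancy_prop_threshold: float = 0.25
    redundancy_alpha: float = 0.05
    selection_start: str = "sig"
    selection_alpha: float = 0.01
    selection_max_sweeps: int = 500
    bridge_top_prop: float = 0.30
    bootstrap_edges_B: int = 1000
    casedrop_B: int = 500
    casedrop_grid: list[float] = field(default_factory=lambda: list(stab.DEFAULT_DROP_GRID))
    casedrop_centrality: str = "strength"
    nct_n_perm: int = 1000
    factor_waves: list[str] = field(default_factory=list)
    factor_scoring: str = "regression"
    factor_score_column: str = "child_emot"
    covariate_columns: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FamnetError(f"unknown config keys: {sorted(unknown)}")
        missing = {"input", "outdir", "seed", "communities"} - set(d)
        if missing:
            raise FamnetError(f"missing required config keys: {sorted(missing)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def load_table(config: PipelineConfig) -> SymptomTable:
    table = SymptomTable.from_csv(config.input, communities=config.communities)
    for col in config.covariate_columns + config.factor_waves + config.drop_items:
        if col not in table.data.columns:
            raise FamnetError(f"configured column {col!r} not present in the input table")
    return table


def _parent_columns(table: SymptomTable, config: PipelineConfig) -> list[str]:
    dropped = set(config.drop_items)
    return [
        c
        for c in table.node_labels
        if table.communities[c] != CHILD
        and c not in dropped
        and c not in config.covariate_columns
        and c not in config.factor_waves
    ]


class _Writer:
    """Writes artifacts stamped with the config hash and seed."""

    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.stamp = f"config={config.config_hash()} seed={config.seed}"

    def csv(self, name: str, df: pd.DataFrame, index: bool = False, note: str = "") -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(f"# {self.stamp}\n")
            if note:
                fh.write(f"# {note}\n")
            df.to_csv(fh, index=index)
        return path

    def json(self, name: str, payload: dict) -> Path:
        path = self.outdir / name
        payload = {"_meta": self.stamp, **payload}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        return path


def make_estimator(config: PipelineConfig, columns: list[str], communities: dict[str, str]):
    """Estimator closure used by the stability and comparison suites."""

    def estimate(df: pd.DataFrame) -> GGMNetwork:
        net = estimate_network(
            _as_table(df, communities),
            columns=columns,
            start=config.selection_start,
            start_alpha=config.selection_alpha,
            max_sweeps=config.selection_max_sweeps,
        )
        return net

    return estimate


def _as_table(df: pd.DataFrame, communities: dict[str, str]) -> SymptomTable:
    scales = {c: CONTINUOUS for c in df.columns}
    return SymptomTable(
        data=df, communities={c: communities.get(c, "covariate") for c in df.columns},
        scales=scales,
    )


def layout_coordinates(
    net: GGMNetwork, iterations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Fruchterman-Reingold coordinates, attraction by absolute edge weight.

    Initial positions lie on a circle; an edgeless network keeps them. The
    result is normalised to the unit bounding box.
    """
    G = nx.Graph()
    G.add_nodes_from(net.labels)
    for a, b, w in net.edge_list():
        G.add_edge(a, b, weight=abs(w))
    init = nx.circular_layout(G)
    if net.n_edges == 0:
        pos = init
    else:
        pos = nx.spring_layout(
            G, pos=init, iterations=iterations, seed=seed, weight="weight"
        )
    xy = np.array([pos[lab] for lab in net.labels], dtype=float)
    xy = xy - xy.min(axis=0)
    scale = xy.max() if xy.max() > 0 else 1.0
    xy = xy / scale  # isotropic: shapes are preserved inside the unit box
    xy = xy + (1.0 - xy.max(axis=0)) / 2.0
    out = pd.DataFrame(xy, columns=["x", "y"])
    out.insert(0, "node", net.labels)
    return out


def _write_network(writer: _Writer, net: GGMNetwork, top_prop: float, seed: int) -> None:
    writer.json("network.json", net.to_json_dict())
    edges = pd.DataFrame(net.edge_list(), columns=["node1", "node2", "weight"])
    writer.csv("edges.csv", edges)
    writer.csv("centrality.csv", centrality_table(net, top_prop=top_prop), index=True)
    writer.csv("layout.csv", layout_coordinates(net, seed=seed))


def _write_stability(
    writer: _Writer, df: pd.DataFrame, estimator, config: PipelineConfig
) -> None:
    if config.bootstrap_edges_B:
        boot = stab.bootstrap_edges(
            df, estimator, B=config.bootstrap_edges_B, seed=config.seed + 100
        )
        writer.csv("bootstrap_edges.csv", boot.summary)
    if config.casedrop_B:
        cd = stab.casedrop_bootstrap(
            df,
            estimator,
            drop_proportions=config.casedrop_grid,
            B=config.casedrop_B,
            centrality_kind=config.casedrop_centrality,
            seed=config.seed + 200,
        )
        cs = stab.cs_coefficient(cd)
        writer.csv(
            "casedrop.csv", cd.correlations, note=f"cs_{cd.centrality_kind}={cs}"
        )


def run_step1(config: PipelineConfig) -> GGMNetwork:
    """Parent symptom network: screen, estimate, centrality, stability."""
    table = load_table(config)
    writer = _Writer(Path(config.outdir) / "step1", config)
    if config.redundancy_enabled:
        red = find_redundant_pairs(
            table,
            corr_min=config.redundancy_corr_min,
            prop_threshold=config.redundancy_prop_threshold,
            alpha=config.redundancy_alpha,
        )
        writer.json("redundancy.json", red.to_json_dict())
    cols = _parent_columns(table, config)
    df = table.complete_cases(cols)
    estimator = make_estimator(config, cols, table.communities)
    net = estimator(df)
    _write_network(writer, net, config.bridge_top_prop, config.seed)
    _write_stability(writer, df, estimator, config)
    logger.info("step1: %d nodes, %d edges", net.p, net.n_edges)
    return net


def run_step2(config: PipelineConfig, net: GGMNetwork | None = None) -> pd.DataFrame:
    """Bridge symptoms between the parent communities of the step-1 network."""
    writer = _Writer(Path(config.outdir) / "step2", config)
    if net is None:
        path = Path(config.outdir) / "step1" / "network.json"
        if not path.exists():
            raise FamnetError("step1 artifacts not found; run step1 first")
        with open(path) as fh:
            net = GGMNetwork.from_json_dict(json.load(fh))
    bs = bridge_centrality(net, signed=False)
    out = pd.DataFrame(
        {
            "community": pd.Series(net.communities),
            "bridge_strength": bs,
            "is_bridge": flag_bridges(bs, config.bridge_top_prop),
        }
    )
    out.index.name = "node"
    all_positive = bool((net.weights >= 0).all())
    if all_positive:
        note = "all edges non-negative: bridge expected influence equals bridge strength; signed table omitted"
    else:
        out["bridge_expected_influence"] = bridge_centrality(net, signed=True)
        note = "negative edges present: signed bridge expected influence reported"
    writer.csv("centrality.csv", out, index=True, note=note)
    return out


def run_step3(config: PipelineConfig) -> GGMNetwork:
    """Re-estimate with the child emotional-difficulties factor node appended."""
    table = load_table(config)
    if len(config.factor_waves) < 3:
        raise FamnetError("step3 requires 3 child wave columns (factor_waves)")
    writer = _Writer(Path(config.outdir) / "step3", config)
    fac = fit_one_factor(
        table.data[config.factor_waves], scoring=config.factor_scoring
    )
    writer.json("factor.json", fac.to_json_dict())

    cols = _parent_columns(table, config)
    child_col = config.factor_score_column
    df = table.data[cols + config.covariate_columns].copy()
    df[child_col] = fac.scores
    df = df.dropna()
    communities = {c: table.communities[c] for c in cols}
    communities[child_col] = CHILD
    for cov in config.covariate_columns:
        communities[cov] = "covariate"
    node_cols = cols + config.covariate_columns + [child_col]
    estimator = make_estimator(config, node_cols, communities)
    net = estimator(df)
    _write_network(writer, net, config.bridge_top_prop, config.seed)

    child_edges = [
        {"node1": a, "node2": b, "weight": w}
        for a, b, w in net.edge_list()
        if child_col in (a, b)
    ]
    writer.json("child_edges.json", {"edges": child_edges})
    logger.info("step3: %d nodes, %d child edges", net.p, len(child_edges))
    return net


def run_compare(config: PipelineConfig) -> NCTResult:
    """Split-half replication of the parent network."""
    table = load_table(config)
    cols = _parent_columns(table, config)
    df = table.complete_cases(cols)
    estimator = make_estimator(config, cols, table.communities)
    res = split_half_replication(
        df, estimator, n_perm=config.nct_n_perm, seed=config.seed + 300
    )
    writer = _Writer(Path(config.outdir) / "compare", config)
    writer.json("nct.json", res.to_json_dict())
    return res


def run_all(config: PipelineConfig) -> None:
    net1 = run_step1(config)
    run_step2(config, net1)
    if config.factor_waves:
        run_step3(config)
    run_compare(config)
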