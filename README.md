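# famnet

Family symptom-network analysis: partial-correlation networks over mother
and father depression symptoms, identification of the symptoms that *bridge*
the two parents' symptom sets, and association of the parent network with a
child emotional-difficulties factor score.

The package is aimed at researchers in network psychometrics and
psychiatric epidemiology who work with item-level symptom data from family
cohorts (e.g. ten EPDS depression items per parent on an ordinal 1–4 scale,
plus a 0–10 child emotional-difficulties subscale measured at three waves).
Because such cohort data are typically access-restricted, `famnet` ships a
synthetic family generator with a known network structure, so the entire
pipeline is validated by parameter recovery.

## The model

Symptoms are nodes of an unregularised Gaussian graphical model. Edges are
partial correlations derived from the concentration matrix K:

    w_ij = -K_ij / sqrt(K_ii K_jj)

i.e. the association between symptoms *i* and *j* conditional on all other
symptoms. Estimation proceeds from Spearman rank correlations (the items
are ordinal and right-skewed), fits the constrained maximum likelihood for a
given edge pattern by iterative proportional scaling, and selects the
pattern by greedy stepwise search over single-edge changes under BIC with
one parameter per edge. On top of the selected network the package computes:

* **strength** `s_i = Σ_j |w_ij|` and expected influence `Σ_j w_ij`;
* **bridge strength** — the same sum restricted to edges leaving node *i*'s
  community (mother / father / child), with top-30% bridge flagging;
* **stability** — nonparametric edge bootstraps with percentile CIs,
  case-dropping subset bootstraps and the correlation-stability (CS)
  coefficient (> 0.25 acceptable, > 0.5 preferred);
* **replication** — a permutation network comparison test of global
  strength (sum of absolute edge weights) and structure (maximum absolute
  edge-weight difference), including a split-half driver;
* **preprocessing** — a goldbricker-style redundancy screen based on
  dependent-correlation tests, and a closed-form one-factor model of the
  three child waves with KMO and Cronbach's alpha.

See `docs/methods.md` for assumptions, defaults and known limitations.

## Worked example

```python
import numpy as np
import famnet as fn

truth = fn.build_true_network(
    9, 9, within_density=0.2,
    bridge_pairs=[("m_guilt", "f_guilt"), ("m_selfharm", "f_selfharm")],
    weight_low=0.18, weight_high=0.35, seed=7,
    child_links=["m_guilt", "m_sad", "m_panic"],
)
table = fn.sample_family_data(truth, n_families=4000, seed=11)

# Step 1: parent symptom network
parents = [c for c in table.node_labels if table.communities[c] != "child"]
net = fn.estimate_network(table, columns=parents)
stats = fn.density_stats(net)
print(f"parent network: {stats['n_edges']}/{stats['n_possible']} edges "
      f"(density {stats['density']:.2f}), mean |weight| {stats['mean_abs_weight']:.3f}")

# Step 2: bridge symptoms between the parent communities
cent = fn.centrality_table(net, top_prop=0.30)
print("flagged bridge symptoms:", ", ".join(cent.index[cent.is_bridge]))

# Step 3: child emotional-difficulties factor appended as a node
fac = fn.fit_one_factor(table.data[["emot_9y", "emot_11y", "emot_13y"]])
print(f"child factor: loadings {np.round(fac.loadings, 2)}, "
      f"KMO {fac.kmo:.2f}, alpha {fac.alpha:.2f}")
df = table.data[parents].copy()
df["child_emot"] = fac.scores
net2 = fn.select_ggm(fn.spearman_matrix(df.dropna()),
                     communities=dict(table.communities, child_emot="child"))
print("edges to the child factor:",
      [(a, b, round(w, 3)) for a, b, w in net2.edge_list() if "child_emot" in (a, b)])
```

Output:

```
parent network: 20/153 edges (density 0.13), mean |weight| 0.175
flagged bridge symptoms: m_guilt, m_selfharm, f_guilt, f_selfharm
child factor: loadings [1.21 1.22 1.19], KMO 0.71, alpha 0.79
edges to the child factor: [('m_sad', 'child_emot', 0.174), ('m_guilt', 'child_emot', 0.204), ('m_worry', 'child_emot', 0.046), ('m_panic', 'child_emot', 0.242), ('m_overwhelm', 'child_emot', 0.044)]
```

The estimator recovers the planted structure: the only flagged bridge
symptoms are the two designated cross-parent pairs (guilt and self-harm
ideation), and the strongest child edges are the three mother symptoms the
generator linked to the child factor (`m_guilt`, `m_sad`, `m_panic`); the
two additional small child edges (≈ 0.05) are selection noise at this
sample size.

There is also a thin CLI over the same pipeline
(`famnet simulate|step1|step2|step3|stability|compare|all`), driven by a
YAML configuration; every output file is stamped with the configuration
hash and seed so runs are byte-reproducible.

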