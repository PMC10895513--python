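# Methods

`famnet` implements a family symptom-network analysis: partial-correlation
networks over mother and father depression items, identification of the
symptoms that bridge the two parents' symptom sets, and the association of
the parent network with a child emotional-difficulties factor. Because
per-family cohort data of this kind are access-restricted, the package pairs
every estimation stage with a synthetic generator whose network structure is
known exactly, so each stage is validated by parameter recovery rather than
by comparison to withheld data.

## Model

Symptoms are nodes of a Gaussian graphical model (GGM). An edge between
nodes *i* and *j* is the partial correlation

    w_ij = -K_ij / sqrt(K_ii K_jj),

where `K` is the concentration (inverse covariance) matrix: the association
between two symptoms after conditioning on every other symptom in the
network. Input correlations are Spearman rank correlations computed on
complete cases, because the parent items are ordinal (1–4) and strongly
right-skewed; indefinite rank-correlation matrices are repaired by
eigenvalue clipping at 1e-6 followed by re-standardisation.

### Constrained maximum likelihood

For a fixed edge pattern, the ML concentration matrix matches the input
correlation matrix on every linked pair and on the diagonal, with `K_ij = 0`
elsewhere. It is computed by edge-wise iterative proportional scaling (IPS):
each 2×2 edge block (and each diagonal element) of `K` is adjusted so the
implied covariance block equals the sample block, with the running inverse
maintained by rank-1/rank-2 Woodbury updates and re-inverted once per sweep.
Convergence is declared when the largest constraint deviation
`max |Sigma_ij − S_ij|` over linked pairs and the diagonal falls below 1e-8.
This scale-free residual is used instead of an entrywise-change test on `K`
because `K`'s norm grows like the reciprocal of the smallest eigenvalue of
`S`, making an absolute change threshold unattainable in double precision on
poorly conditioned inputs. Saturated models shortcut to `K = S^{-1}`.

### Model selection

Structure search is greedy stepwise BIC: starting from the set of edges
whose saturated-model partial correlations pass a Fisher-z test at α = 0.01
(configurable; an empty start is also available), every single-edge addition
and removal is scored and the change with the largest BIC decrease applied,
until no change decreases BIC. BIC counts one free parameter per edge; the
diagonal is not counted, which is constant across models and cannot change
rankings. Ties within 1e-10 prefer removal over addition, then lexicographic
edge order, so the search is fully deterministic. On 3-node problems the
stepwise search provably reaches the exhaustive-search optimum in the test
suite's 50 random datasets; on 4-node problems it agrees in ≥ 95% of
datasets (greedy search has no global guarantee).

The inner IPS/scoring loops are compiled with numba; a full stepwise fit of
an 18-node network at n = 4000 takes ~50 ms, which is what makes the
bootstrap and permutation suites (thousands of full re-selections) practical.

### Centrality and bridge symptoms

Strength is the sum of absolute incident edge weights; expected influence is
the signed sum. Bridge strength restricts the sum to edges leaving the
node's community (mother items, father items, child factor); on an
all-positive network the signed and unsigned bridge variants coincide, and
the pipeline reports only bridge strength in that case. Bridge flagging
marks the top 30% of nodes by bridge strength, with ⌈0.3·n⌉ rounding and
inclusive ties; nodes with exactly zero bridge strength are never flagged (a
symptom with no cross-community edges cannot bridge, and without this rule a
sparse cross-community structure would flag every node through the tie at
zero). When the child factor node is present, flagging is computed
over the parent nodes only (the child node is a criterion variable, not a
candidate bridge) — both choices are configurable.

### Stability and comparison

Edge accuracy uses a nonparametric row bootstrap with **full re-estimation**
(Spearman + stepwise selection) per replicate and percentile 2.5/97.5
intervals over all node pairs, absent edges contributing 0. Re-running the
selection, rather than refitting fixed weights, makes the intervals reflect
model-search variability; it also means replicate distributions can have a
point mass at zero, so the intervals are guaranteed to bracket the replicate
median but not necessarily the mean. Centrality stability uses case-dropping
subset bootstraps over the drop grid {0.05, 0.15, …, 0.75}; the CS
coefficient is the largest drop proportion at which ≥ 95% of subsample
centralities correlate ≥ 0.7 with the full-sample values (> 0.25 acceptable,
> 0.5 preferred). Defaults are B = 1000 (edges) and B = 500 (case-dropping).

The network comparison test permutes group labels (groups keep their
original sizes) and re-estimates both networks per permutation. Global
strength invariance compares the absolute difference in summed absolute edge
weights; structure invariance compares the maximum absolute edge-weight
difference over all pairs. p-values use the add-one formula
`(1 + #{perm ≥ obs}) / (1 + n_perm)` and are never exactly zero. Split-half
replication halves the sample at random (sizes differing by at most 1) and
runs the same test.

### Redundancy screen and child factor

Before estimation, within-community item pairs with Spearman r ≥ 0.50 are
tested for redundant correlation profiles: for every remaining item the two
correlations are compared with a dependent-correlation z test (Fisher-z
difference with the Dunn–Clark pooled covariance, back-transformed-mean
variant by default; the raw-average variant is available), and a pair is
flagged when fewer than 25% of those tests reject at α = 0.05. Flagged pairs
are reported for review; the items actually dropped are taken from the
configuration, mirroring expert adjudication rather than automating it.

The three child emotional-difficulty waves (0–10 subscale scores) are
summarised by a congeneric one-factor model. With exactly three indicators
the ML solution is closed-form (`λ1 = sqrt(s12·s13/s23)` and cyclic
permutations); negative uniquenesses (Heywood cases) raise a warning and are
clamped at 1e-6. Factor scores use the regression method (Bartlett
available). KMO sampling adequacy, Cronbach's alpha and pairwise Spearman
wave correlations are reported alongside, and the score enters the step-3
network as a single continuous node.

## Synthetic generator

Families are drawn from a latent multivariate normal whose correlation
matrix is implied by a known sparse partial-correlation matrix: two parent
communities with within-community edges sampled at a chosen density,
designated cross-parent bridge edges (by default guilt–guilt and
self-harm–self-harm, the clinically salient pairs), and optionally a child
factor node linked to selected mother symptoms. Edge weights are drawn
uniformly (default range 0.05–0.40, matching the magnitude range typical of
published symptom networks); the matrix is shrunk uniformly (factor 0.95 per
step) until `I − P` is positive definite with minimum eigenvalue ≥ 1e-6,
which preserves the sparsity pattern.

Parent items are discretised to 1–4 by latent cutpoints, default
(0.25, 1.0, 1.9), giving the right-skewed endorsement characteristic of
postnatal depression items (about 60/24/12/3% per category). The child
factor is emitted as three wave scores
`round(clip(1.5 + 2.0·(0.75·f + ε), 0, 10))` with ε ~ N(0, 0.62²); the
offset/scale/noise were calibrated once so that the three waves correlate at
rs ≈ 0.49–0.59 with plausibly skewed 0–10 scores, and are not revisited.
All randomness flows from a single integer seed through named sub-streams.

What the generator does **not** emulate: item-level measurement structure of
the child subscale (waves are generated directly), informative missingness
(complete data are generated; the pipeline's complete-case handling is
exercised by tests, not by a missingness model), and any non-Gaussian latent
dependence. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the latent-Gaussian ordinal model, not robustness
to arbitrary real-data violations.

### Discretisation and the recovery benchmark

Discretising to four skewed categories does more than attenuate
correlations: the matrix of rank correlations of the ordinal items is not
exactly generated by the sparse latent precision, so at large n the BIC
search correctly picks up small rank-scale partials that have no latent
counterpart (measured here as ~0.86 support precision at n = 4000, with
sensitivity 1.0). For this reason the edge-recovery benchmark draws data on
the latent Gaussian scale, where the sparse structure holds exactly and the
numbers measure the estimator itself (sensitivity 1.0, precision ≈ 0.95–0.98
at n = 4000); the bridge-recovery, stability and calibration experiments all
run on the full ordinal pipeline, where ranking-based quantities are robust
to the distortion. A polychoric-correlation front end would remove the
mismatch and is a known limitation/extension point.

## Validation experiment sizes

The `famnet.benchmarks` module fixes the validation designs: edge/bridge
recovery use 20 replications of an 18-node two-community truth with all
|pcor| ≥ 0.15 at n = 4000; permutation-test calibration uses 200 simulated
null datasets (6-node truth, n = 300 per group) with 200 permutations each;
CI coverage uses a 6-node chain calibrated so the designated edge has a
rank-scale partial correlation of exactly 0.3 (the estimand of the
Spearman-based pipeline), at n = 2000 with B = 200 over 100 replications; the CS regime uses a dense 10-node truth with
weights 0.2–0.35 at n = 4000 and B = 100. These sizes keep each experiment
to seconds–minutes on one core while leaving the measured rates well away
from their pass thresholds.

## Known limitations

* Spearman-on-ordinal misspecification (above); no polychoric option yet.
* Greedy stepwise search can miss the global BIC optimum for p ≥ 4
  (quantified at ≥ 95% agreement on 4-node problems).
* The goldbricker screen tests within-community profiles only, mirroring the
  per-parent screening design; cross-community profile redundancy is not
  screened.
* Percentile bootstrap intervals for edges are median- not mean-bracketing
  when selection produces a point mass at zero.
* No missing-data machinery beyond complete-case analysis; imputation is out
  of scope.
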