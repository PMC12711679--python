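# Methods

## The model

`binet` infers *Boolean implication networks* from log2-scale gene-by-sample
expression matrices. The underlying model is that many gene pairs obey
invariant logical constraints — "A high implies B high", "A low implies B
low", and so on — that hold across every sample of a heterogeneous cohort
regardless of condition or treatment. Such constraints appear in the joint
scatter of two discretized genes as a *sparsely populated quadrant*.

### StepMiner discretization

Each gene's values are sorted ascending and a one-step function is fitted:
for every split position k in 1..n−1 the series is modelled by two constant
segments (their means), and the split minimizing the residual sum of squares
(SSE) is selected. The adaptive-regression test statistic

    F = [Σ (x̂ᵢ − x̄)² / (m − 1)] / [Σ (xᵢ − x̂ᵢ)² / (n − m)]

with m = 3 model degrees of freedom (two segment means plus the step
position) quantifies step sharpness; it is exposed but not used as a gate by
default. The *threshold* is the midpoint of the two segment means. Values
within ±0.5 log2 units of the threshold (a 2-fold band in linear scale) are
called *intermediate* and ignored by all downstream Boolean analysis; values
beyond the band are LOW or HIGH.

Numerical choices: fitting is order-free (the sort is internal), so
permuting a gene's samples never changes its threshold; SSE is computed by
prefix sums and clipped at zero; exact fits (SSE = 0) report F = +inf rather
than failing; exact SSE ties break toward the smallest step index, with a
relative tolerance of 1e-9 so that floating-point noise cannot override the
tie rule; constant series raise a degenerate-fit error and are excluded
downstream. The per-gene standard deviation stored with each threshold is
the sample SD (ddof = 1) across all samples of the dataset, not per class.

Genes enter network analysis only if at least 5% of samples sit in each of
the LOW and HIGH states and the 10th–90th percentile spread is at least
1.0 log2 unit (the dynamic-range filter; both cutoffs configurable — the
percentile rule is stated only qualitatively in the field, so the 1.0
default is a named parameter rather than a claim).

### Sparse-quadrant implication statistics

For a gene pair (A, B), non-intermediate samples fall into quadrants
a00, a01, a10, a11 (first index = state of A; 0 = LOW, 1 = HIGH). With
row/column marginals and total t, the expected count under independence is
n̂ᵢⱼ = (rowᵢ · colⱼ) / t, and a quadrant is *sparse* when

    Sᵢⱼ = (n̂ᵢⱼ − aᵢⱼ) / √n̂ᵢⱼ  >  s_min     and
    pᵢⱼ = ½ (aᵢⱼ/rowᵢ + aᵢⱼ/colⱼ)  <  p_max.

p is the mean of the two conditional error rates; this is exactly the
printed low-low form generalized to every quadrant. One sparse quadrant
yields an asymmetric implication ((0,0) → A-low⇒B-high, (0,1) → A-low⇒B-low,
(1,0) → A-high⇒B-high, (1,1) → A-high⇒B-low); sparse off-diagonal (resp.
diagonal) pairs yield the symmetric *equivalent* (resp. *opposite*)
relation. Any other sparse pattern (adjacent pair, three or more) falls
outside the six-type taxonomy and is logged and reported as NONE.

Two named presets exist: `network` (s_min = 10, p_max = 0.15), the setting
for building implication networks on large cohorts, and `screen`
(s_min = 3, p_max = 0.1), the more permissive candidate screen. Note a hard
scale fact: when a quadrant is empty, S = √n̂ ≤ √(n/4), so the `network`
gate can only ever fire with ≳400 jointly-counted samples. This matches the
field's experience that implication relations need cohorts of several
hundred samples, and it is why the permutation-FDR demonstrations in the
test-suite run the 300-sample planted cohort under `screen`.

Discovery evaluates every unordered pair once; asymmetric relations are
emitted in both directions with converse types (A-low⇒B-low and
B-high⇒A-high are the same sparse quadrant read from either end). The
permutation FDR shuffles every gene independently across samples —
destroying inter-gene structure, preserving marginals and hence thresholds
(the fit is order-free) — re-runs the entire pipeline per permutation, and
reports mean permuted discoveries / observed discoveries.

### Clustering and the clustered network

Equivalence edges are collapsed into clusters: each equivalence edge gets a
Jaccard similarity computed over *closed* equivalence neighborhoods (each
gene included in its own set, so a mutually-equivalent pendant pair scores
1); a minimum spanning forest is built with edge weight 1 − Jaccard (the
forest prefers strong links; Kruskal with lexicographic insertion makes
ties deterministic); forest edges with Jaccard < 0.7 are removed; connected
components of the remainder are the clusters. Pruning is applied to the
forest edges (the literal procedure); an `--all-edges` variant prunes every
equivalence edge instead, for sensitivity checks. Each cluster's
representative is the member with the most within-cluster equivalence
edges, ties lexicographic.

Clusters are linked by pairing the representative of cluster A with
min(6, |B|) members of B (seeded random sample, or the highest-degree
members in the deterministic `top-degree` variant) and keeping a directed
typed edge iff a single non-NONE relation type accounts for at least 2/3 of
the sampled pairs. "Overwhelming majority" has no published value; 2/3 is
the package default and configurable. Boolean paths are simple directed
paths over asymmetric edges only, enumerated depth-first in lexicographic
order from a seed cluster, optionally constrained to a terminal cluster
(the two-seed mode used to mine intermediate regulators).

### Composite scores, classification, survival, power

Per signature gene, z = (expr − SThr) / (3·stddev); per cluster the mean z
over its genes; the composite score is the ±1-weighted sum of cluster
means (+1 for clusters elevated in disease, −1 otherwise — weights are
supplied by the caller, since elevation direction is a biological judgment).
Scores order samples (stable ascending sort), classify groups (ROC-AUC, the
Mann–Whitney probability with ties counted ½), and stratify survival: the
score vector is split at its own StepMiner threshold and the arms compared
with the standard two-group log-rank test (chi-square, 1 df). Events at
time zero are retained. Signature refinement intersects two
differential-expression screens (defaults |log2FC| > 10, padj < 0.05 — the
printed gate, kept verbatim although a 1024-fold cutoff is suspiciously
strict; both are flags) and keeps candidates whose single-gene
treated-vs-control ROC-AUC, direction-agnostic max(AUC, 1−AUC), reaches 0.9
(unpublished cutoff; exposed as a flag).

The sample-size operation searches n = 2, 3, ... for the smallest per-group
size at which an equal-n two-sample t test (df = 2n−2, noncentrality
d·√(n/2)) reaches the target power, via the noncentral t distribution.
Two-sided by default, which reproduces the documented reference sizes
(17 per group at d = 1.0; 4 at d = 2.5; α = 0.05, power = 0.80).

## The synthetic generator

`synthetic.generate_dataset` emulates the assumed data-generating process:
latent binary cluster states drive bimodal log2 expression. Defaults model
a moderately sized curated cohort: n = 500 samples, three clusters of 10
genes on the chain 0 —high⇒high→ 1 —high⇒low→ 2, state means 4.0/8.0 log2
(a 16-fold gap), within-state noise σ = 0.2, root marginal P(high) = 0.5.
States propagate in topological order: a parent in an edge's antecedent
state forces the child's state (forbidden quadrant mass is exactly zero);
contradictory forcings raise an infeasibility error.

Two deliberate choices shape the plant:

- **Balanced state assignment.** A root cluster is high in exactly
  round(f·n) samples (random which ones), and a child's unconstrained
  samples are split the same way. At n = 500 the sparse-quadrant expected
  count peaks near 110 against the S > 10 ⇒ n̂ > 100 requirement; with iid
  Bernoulli states the binomial fluctuation of the marginals (≈10 counts)
  would make planted edges flicker in and out of detectability. Balanced
  assignment realizes the configured composition exactly — emulating a
  curated compendium with a designed class mix — and makes the
  configuration's ground truth sharp.
- **`free_agree_frac` = 0.12.** In unconstrained samples a child adopts the
  state its edges would force with this probability (otherwise the
  opposite). Small values keep the implication asymmetric — at 0.12 the
  forbidden quadrant scores S ≈ 10.5 while the opposing off-quadrant stays
  at S ≈ 9.3, safely below the gate; larger values drift the pair toward
  equivalence, smaller ones starve the forbidden quadrant's expectation.

Ground-truth relations (`SimTruth.relations`) are derived from zero-mass
quadrants of the *realized* latent states, so transitive consequences of
the planted DAG (the chain above implies 0-high ⇒ 2-low) are recorded as
true relations; recovery metrics therefore count them as correct rather
than as false positives. Treatment labels split samples in half; responder
genes (cluster 0 by default) gain a 2.0 log2 shift when treated. Survival
is exponential with hazard base·exp(log HR · group), group = the root
cluster's latent state, default HR = 3; censoring is administrative-uniform
on a horizon solved (Brent) to censor ≈20% of baseline-arm samples.

What the generator does **not** emulate: platform/batch effects, probe
saturation, heavy-tailed or count-based noise, correlated noise between
clusters, gene-specific variances, dropout, or informative censoring.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated model, not robustness on real cohorts.

## Problem sizes in the test suite

The suite exercises the documented calibration conditions directly: step
fits against an exhaustive-scan oracle on 1,000 random series; sparsity
arithmetic and classification symmetries on every quadrant 4-tuple with
entries 0–10 and valid marginals; planted-chain recovery (30 genes,
n = 500, σ = 0.2, preset `network`) over 20 seeds requiring exact partition
recovery, ≥0.95 edge sensitivity and ≤0.05 edge false positives; null
calibration (n = 100, 20 genes) over 50 seeds; permutation FDR (n = 300,
10 permutations) under `screen`; survival power (HR 3, n = 200) over 100
seeds. The whole suite runs in well under a minute on one CPU.

## Known limitations

- The `network` preset is physically inert below ~400 samples (see above);
  the package does not warn about this, it simply discovers nothing.
- Inter-cluster links depend on the representative gene only; a cluster
  whose representative is atypical can mis-type an edge even when most
  member pairs agree.
- The log-rank p-value uses the chi-square approximation; no exact or
  permutation variant is provided for very small arms.
- Cluster weights (+1/−1) along a Boolean path are caller-supplied; the
  package does not infer disease direction.
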