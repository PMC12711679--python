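# binet — Boolean implication networks for transcriptomics

`binet` builds Boolean implication networks from gene-by-sample log2
expression matrices and uses them to chart differentiation-like
trajectories and score samples. It is aimed at computational biologists
working with bulk transcriptomic compendia (microarray or RNA-seq derived)
who want *invariant logical relationships* between genes — constraints such
as "CDX2 high ⇒ partner high" that hold across every sample of a
heterogeneous cohort — rather than correlation networks.

## What it computes

1. **StepMiner discretization.** Each gene's sorted values get a one-step
   fit; the split minimizing the residual sum of squares defines a
   threshold at the midpoint of the two segment means. Values within ±0.5
   log2 units of the threshold (a 2-fold noise band) are *intermediate* and
   excluded from Boolean analysis; the rest are low/high. Genes with <5% of
   samples in either state, or a narrow 10th–90th percentile range, are
   filtered out.
2. **Implication discovery.** For a gene pair, non-intermediate samples
   fall into four quadrants a00, a01, a10, a11. With expected count
   n̂ᵢⱼ = rowᵢ·colⱼ/total under independence, a quadrant is *sparse* when
   Sᵢⱼ = (n̂ᵢⱼ − aᵢⱼ)/√n̂ᵢⱼ > s_min and
   pᵢⱼ = ½(aᵢⱼ/rowᵢ + aᵢⱼ/colⱼ) < p_max.
   One sparse quadrant ⇒ an asymmetric implication (low⇒low, low⇒high,
   high⇒high, high⇒low); two diagonal/off-diagonal sparse quadrants ⇒ the
   symmetric *opposite*/*equivalent* types. Presets: `network`
   (s_min=10, p_max=0.15) and `screen` (s_min=3, p_max=0.1). A permutation
   FDR (per-gene shuffling, full pipeline re-run) calibrates discoveries.
3. **Clustered network (CBIN).** Equivalence edges are weighted by
   1 − Jaccard (closed equivalence neighborhoods), a minimum spanning
   forest is pruned at Jaccard < 0.7, and components become clusters.
   Clusters are linked by sampling 6 members of the target cluster against
   the source cluster's representative and keeping a ≥2/3-majority type.
   Asymmetric edges are traversed depth-first to chart **Boolean paths**
   from a seed gene's cluster.
4. **Composite scores.** Per gene z = (expr − SThr)/(3·stddev); per path
   cluster the mean z; the score is the ±1-weighted sum. Scores order
   samples, classify groups (ROC-AUC), and stratify survival by splitting
   the score vector at its own StepMiner threshold (two-group log-rank).
5. **Synthetic cohorts.** A generator plants a cluster-level implication
   DAG in bimodal log2 data with coupled treatment labels and survival, so
   the whole pipeline is testable with known ground truth.

## Worked example

Simulate a cohort (500 samples; three 10-gene clusters on the chain
cluster0 —high⇒high→ cluster1 —high⇒low→ cluster2) and run the full
pipeline:

```sh
binet simulate --seed 7 --out-dir demo/sim
binet run --matrix demo/sim/matrix.tsv --out-dir demo/net --seed 7 --seed-gene G0_00
binet paths --cbin demo/net/cbin.json --seed-gene G0_00 --max-len 4
```

prints

```
C1 -[high=>high]-> C2
C1 -[high=>high]-> C2 -[high=>low]-> C3
2 paths
```

— the three planted clusters are recovered exactly (C1–C3, ten genes each)
and the only Boolean paths out of the seed cluster retrace the planted
chain. Scoring the longest path and stratifying the simulated survival
(which is coupled to the seed cluster's latent state):

```sh
binet survive --scores demo/net/scores.tsv --surv demo/sim/surv.tsv
```

```
threshold	-0.036092
logrank_statistic	97.593509
p_value	5.13721e-23
```

The score vector splits at its StepMiner threshold into high/low arms whose
survival differs at chi-square 97.6 (1 df) — the planted hazard ratio of 3
is detected decisively. The permutation FDR on the same matrix
(`binet fdr --in demo/sim/matrix.tsv --preset screen --perm 5 --seed 7`)
prints `fdr_ratio 0.000000`: shuffled data yield no discoveries at the
thresholds that find the planted structure.

The same operations are available as a library (`binet.fit_step`,
`binet.discover_implications`, `binet.cluster_equivalences`,
`binet.composite_score`, `binet.stratify_survival`,
`binet.generate_dataset`, ...); see `docs/methods.md` for the model, the
defaults, and their rationale.

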