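"""Synthetic log2 expression with planted Boolean implication structure.

The generator emulates the data model assumed throughout the analysis:
each gene is bimodal on the log2 scale, driven by a latent binary state
shared by all genes of its cluster, and cluster states obey a planted
implication DAG with zero violations.  Gene values are the state mean plus
Gaussian noise.  Treatment labels shift responder genes in treated samples,
and survival times are exponential with a log-hazard coupled to the true
high/low group, censored administratively.

Latent states use balanced assignment: a root cluster is high in exactly
``round(frac_high * n)`` samples (random which ones), and a child cluster's
unconstrained samples are split the same way.  This plants an exact
marginal composition, so the ground-truth relations of a configuration are
sharp rather than fluctuating with the state draw.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .booleannet import Relation
from .errors import InfeasibleError, InvalidInputError

#: forced child state when the parent is in the edge's antecedent state:
#: (antecedent parent state, forced child state)
_EDGE_RULES = {
    Relation.HIGH_HIGH: (1, 1),
    Relation.HIGH_LOW: (1, 0),
    Relation.LOW_LOW: (0, 0),
    Relation.LOW_HIGH: (0, 1),
}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Planted-structure simulation settings.

    ``dag`` lists directed cluster edges ``(parent, child, Relation)`` with
    asymmetric types; equivalence is planted implicitly by cluster
    co-membership.  ``free_agree_frac`` is the fraction of unconstrained
    samples in which a child nevertheless adopts the state its incoming
    edges would force — kept small so the implication stays asymmetric
    (large values drift toward equivalence) while the forbidden quadrant's
    expected count stays high enough to register as sparse.
    """

    n_samples: int = 500
    cluster_sizes: tuple = (10, 10, 10)
    dag: tuple = (
        (0, 1, Relation.HIGH_HIGH),
        (1, 2, Relation.HIGH_LOW),
    )
    mu_low: float = 4.0  # log2 mean of the low state
    mu_high: float = 8.0  # log2 mean of the high state
    sigma: float = 0.2  # within-state noise SD, log2 units
    mid_gap: float = 0.5  # noise-margin half-width the modes must clear
    frac_high: float = 0.5  # marginal P(high) for root clusters
    free_agree_frac: float = 0.12
    responder_clusters: tuple = (0,)
    treatment_effect: float = 2.0  # log2 shift of responder genes when treated
    surv_base_rate: float = 0.1  # baseline exponential hazard
    surv_log_hr: float = float(np.log(3.0))
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4 or not self.cluster_sizes:
            raise InvalidInputError("need >= 4 samples and >= 1 cluster")
        if any(s < 1 for s in self.cluster_sizes):
            raise InvalidInputError("cluster sizes must be >= 1")
        if self.mu_high <= self.mu_low:
            raise InvalidInputError("mu_high must exceed mu_low")
        if not (0.0 < self.frac_high < 1.0) or not (0.0 <= self.free_agree_frac < 0.5):
            raise InvalidInputError("frac_high in (0,1); free_agree_frac in [0, 0.5)")
        if not (0.0 <= self.censor_rate < 1.0):
            raise InvalidInputError("censor_rate must lie in [0, 1)")
        for e in self.dag:
            if len(e) != 3 or Relation(e[2]) not in _EDGE_RULES:
                raise InvalidInputError(f"dag edge {e!r} must carry an asymmetric type")

    @property
    def separable(self) -> bool:
        """Whether states clear the noise margin at ~3 sigma."""
        return (self.mu_high - self.mu_low) > 2.0 * (self.mid_gap + 3.0 * self.sigma)


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a generated dataset.

    ``relations`` maps every ordered cluster pair to the relation implied by
    the realized latent states (including transitive consequences of the
    planted DAG), derived from the zero-mass quadrants of the joint state
    table; pairs with no implied relation map to NONE.
    """

    latent_states: pd.DataFrame  # clusters x samples, {0, 1}
    gene_cluster: dict  # gene id -> cluster index
    relations: dict  # (ci, cj) -> Relation
    responder_genes: tuple
    surv_group: pd.Series  # 1 = high-hazard arm


@dataclasses.dataclass(frozen=True)
class SimResult:
    matrix: pd.DataFrame
    truth: SimTruth
    labels: pd.Series  # 1 = treated
    survival: pd.DataFrame  # columns: time, event


def _balanced_states(n: int, frac: float, rng) -> np.ndarray:
    """0/1 vector with exactly round(frac*n) ones, randomly placed."""
    k = int(round(frac * n))
    out = np.zeros(n, dtype=np.int8)
    if k > 0:
        out[rng.choice(n, size=min(k, n), replace=False)] = 1
    return out


def _latent_states(cfg: SimConfig, rng) -> pd.DataFrame:
    n_clusters = len(cfg.cluster_sizes)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_clusters))
    for u, v, _ in cfg.dag:
        if not (0 <= u < n_clusters and 0 <= v < n_clusters):
            raise InvalidInputError(f"dag references unknown cluster in ({u}, {v})")
        g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise InvalidInputError("planted dag must be acyclic")

    states = np.zeros((n_clusters, cfg.n_samples), dtype=np.int8)
    for c in nx.topological_sort(g):
        in_edges = [(u, Relation(t)) for u, v, t in cfg.dag if v == c]
        if not in_edges:
            states[c] = _balanced_states(cfg.n_samples, cfg.frac_high, rng)
            continue
        forced = np.full(cfg.n_samples, -1, dtype=np.int8)
        for u, rel in in_edges:
            ante, target = _EDGE_RULES[rel]
            mask = states[u] == ante
            clash = mask & (forced != -1) & (forced != target)
            if clash.any():
                raise InfeasibleError(
                    f"contradictory forced states for cluster {c} "
                    f"in {int(clash.sum())} samples"
                )
            forced[mask] = target
        # unconstrained samples mostly take the opposite of the forced state
        targets = set(forced[forced != -1].tolist())
        agree_state = targets.pop() if len(targets) == 1 else 1
        free_p = cfg.free_agree_frac if agree_state == 1 else 1.0 - cfg.free_agree_frac
        free_idx = np.flatnonzero(forced == -1)
        vals = forced.copy()
        if free_idx.size:
            vals[free_idx] = _balanced_states(free_idx.size, free_p, rng)
        states[c] = np.where(vals == -1, 0, vals)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    return pd.DataFrame(states, index=[f"K{c}" for c in range(n_clusters)], columns=samples)


def _implied_relations(latent: pd.DataFrame) -> dict:
    """Cluster-pair relations implied by zero-mass quadrants of the plant."""
    rels = {}
    n = latent.shape[0]
    vals = latent.to_numpy()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = vals[i], vals[j]
            zero = {
                (0, 0): not np.any((a == 0) & (b == 0)),
                (0, 1): not np.any((a == 0) & (b == 1)),
                (1, 0): not np.any((a == 1) & (b == 0)),
                (1, 1): not np.any((a == 1) & (b == 1)),
            }
            empty = {q for q, z in zero.items() if z}
            if empty == {(0, 1), (1, 0)}:
                rel = Relation.EQUIVALENT
            elif empty == {(0, 0), (1, 1)}:
                rel = Relation.OPPOSITE
            elif len(empty) == 1:
                rel = {
                    (0, 0): Relation.LOW_HIGH,
                    (0, 1): Relation.LOW_LOW,
                    (1, 0): Relation.HIGH_HIGH,
                    (1, 1): Relation.HIGH_LOW,
                }[next(iter(empty))]
            else:
                rel = Relation.NONE
            rels[(i, j)] = rel
    return rels


def _censor_horizon(base_rate: float, censor_rate: float) -> float:
    """Uniform(0, u) horizon giving ~censor_rate censoring under Exp(base)."""
    # P(C < T) for C ~ U(0, u), T ~ Exp(lam):  (1 - exp(-lam u)) / (lam u)
    def frac(u):
        return (1.0 - np.exp(-base_rate * u)) / (base_rate * u) - censor_rate

    return brentq(frac, 1e-9, 1e9)


def survival_table(groups, base_rate: float, log_hr: float, censor_rate: float, rng) -> pd.DataFrame:
    """Exponential survival with group-proportional log hazard.

    ``groups`` is a 0/1 series; hazard = ``base_rate * exp(log_hr * group)``.
    Censoring is administrative-uniform on a horizon solved to censor about
    ``censor_rate`` of baseline-arm samples.
    """
    g = pd.Series(groups)
    hazard = base_rate * np.exp(log_hr * g.to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        horizon = _censor_horizon(base_rate, censor_rate)
        t_cens = rng.uniform(0.0, horizon, size=len(g))
    else:
        t_cens = np.full(len(g), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=g.index)


def generate_dataset(cfg: SimConfig = SimConfig()) -> SimResult:
    """Generate an expression matrix, labels, and survival from a plant.

    Latent cluster states are drawn root-first and propagated so every
    planted edge's forbidden quadrant has zero latent mass; genes take the
    state mean (``mu_low`` / ``mu_high``) plus Gaussian noise; half the
    samples (balanced, random which) are labelled treated, and responder
    genes gain ``treatment_effect`` log2 units in those samples.  Survival
    is coupled to the root cluster's latent state.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    latent = _latent_states(cfg, rng)
    samples = list(latent.columns)

    gene_cluster = {}
    gene_ids = []
    for c, size in enumerate(cfg.cluster_sizes):
        for k in range(size):
            gid = f"G{c}_{k:02d}"
            gene_ids.append(gid)
            gene_cluster[gid] = c

    lat = latent.to_numpy()
    rows = np.empty((len(gene_ids), cfg.n_samples))
    for r, gid in enumerate(gene_ids):
        st = lat[gene_cluster[gid]]
        mu = np.where(st == 1, cfg.mu_high, cfg.mu_low)
        rows[r] = mu + rng.normal(0.0, cfg.sigma, size=cfg.n_samples)

    labels = pd.Series(
        _balanced_states(cfg.n_samples, 0.5, rng), index=samples, name="treated"
    )
    responders = tuple(
        g for g in gene_ids if gene_cluster[g] in set(cfg.responder_clusters)
    )
    treated_mask = labels.to_numpy() == 1
    for r, gid in enumerate(gene_ids):
        if gid in set(responders):
            rows[r, treated_mask] += cfg.treatment_effect

    matrix = pd.DataFrame(rows, index=gene_ids, columns=samples)
    surv_group = pd.Series(lat[0], index=samples, name="group")
    survival = survival_table(
        surv_group, cfg.surv_base_rate, cfg.surv_log_hr, cfg.censor_rate, rng
    )
    truth = SimTruth(
        latent_states=latent,
        gene_cluster=gene_cluster,
        relations=_implied_relations(latent),
        responder_genes=responders,
        surv_group=surv_group,
    )
    return SimResult(matrix=matrix, truth=truth, labels=labels, survival=survival)


def null_dataset(
    n_samples: int,
    n_genes: int,
    seed: int = 0,
    frac_high: float = 0.5,
    mu_low: float = 4.0,
    mu_high: float = 8.0,
    sigma: float = 0.2,
) -> pd.DataFrame:
    """Independent bimodal genes with no implication structure.

    Every gene's latent state is drawn independently (balanced to the
    configured marginal), so any discovered relation is a chance artifact.
    """
    if n_samples < 1 or n_genes < 1:
        raise InvalidInputError("sizes must be positive")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    genes = [f"N{i:03d}" for i in range(n_genes)]
    rows = np.empty((n_genes, n_samples))
    for r in range(n_genes):
        st = _balanced_states(n_samples, frac_high, rng)
        mu = np.where(st == 1, mu_high, mu_low)
        rows[r] = mu + rng.normal(0.0, sigma, size=n_samples)
    return pd.DataFrame(rows, index=genes, columns=samples)
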