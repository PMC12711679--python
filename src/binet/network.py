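"""Boolean implication network assembly, clustering, and path charting.

The Boolean Implication Network (BIN) has genes as nodes and the six
relation types as edges.  Equivalence edges are collapsed into clusters:
a minimum spanning forest is built over the equivalence subgraph (edge
weight 1 - Jaccard similarity of the closed equivalence neighborhoods),
forest edges below the Jaccard cutoff are dropped, and the connected
components of what remains become the clusters of the Clustered BIN (CBIN).
Clusters are then linked by sampling member pairs and keeping the
overwhelming-majority relation type.  Asymmetric CBIN edges are traversed
to chart Boolean paths — candidate differentiation trajectories — from a
seed cluster.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .booleannet import ASYMMETRIC, CONVERSE, ImplicationRecord, Relation, SYMMETRIC
from .errors import InconsistencyError, InvalidInputError


class BIN:
    """Boolean Implication Network: genes plus typed pairwise relations.

    Relations are stored for both directions of each pair (asymmetric types
    via their converse), so ``relation(a, b)`` is always answerable.
    """

    def __init__(self):
        self._genes: set = set()
        self._rel: dict = {}  # (a, b) -> Relation, both directions

    @classmethod
    def from_records(cls, records, genes=()) -> "BIN":
        """Build a BIN from implication records plus optional isolated genes.

        Raises
        ------
        InconsistencyError
            Two records assign conflicting types to the same directed pair.
        """
        bin_ = cls()
        for g in genes:
            bin_._genes.add(g)
        for rec in records:
            bin_._add(rec)
        return bin_

    def _add(self, rec: ImplicationRecord):
        a, b = rec.gene_a, rec.gene_b
        if a == b:
            raise InvalidInputError("self-relation records are not allowed")
        self._genes.update((a, b))
        for key, rel in (((a, b), rec.relation), ((b, a), CONVERSE[rec.relation])):
            prev = self._rel.get(key)
            if prev is not None and prev is not rel:
                raise InconsistencyError(
                    f"conflicting relations for {key}: {prev.value} vs {rel.value}"
                )
            self._rel[key] = rel

    @property
    def genes(self) -> list:
        return sorted(self._genes)

    def relation(self, a, b) -> Relation:
        """Stored relation from a to b (NONE if absent)."""
        return self._rel.get((a, b), Relation.NONE)

    def edges(self) -> list:
        """All stored relations, one entry per unordered pair per type.

        Symmetric edges appear once (lexicographic order); asymmetric edges
        appear once per direction-defining pair (the lexicographically
        smaller endpoint first, with its own type).
        """
        out = []
        for (a, b), rel in self._rel.items():
            if a < b:
                out.append((a, b, rel))
        return sorted(out, key=lambda e: (e[0], e[1], e[2].value))

    def equivalence_neighbors(self, g) -> set:
        """Closed equivalence neighborhood N[g]: g plus its equivalents."""
        if g not in self._genes:
            raise InvalidInputError(f"unknown gene {g!r}")
        nbrs = {
            b
            for (a, b), rel in self._rel.items()
            if a == g and rel is Relation.EQUIVALENT
        }
        nbrs.add(g)
        return nbrs

    def equivalence_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._genes)
        for (a, b), rel in self._rel.items():
            if a < b and rel is Relation.EQUIVALENT:
                g.add_edge(a, b)
        return g


def jaccard_similarity(u, v, bin_: BIN) -> float:
    """Jaccard coefficient of the closed equivalence neighborhoods of u, v.

    Closed neighborhoods (each gene included in its own set) make a
    mutually-equivalent pendant pair score 1 rather than 0.
    """
    if u == v:
        raise InvalidInputError("jaccard_similarity needs two distinct genes")
    nu = bin_.equivalence_neighbors(u)
    nv = bin_.equivalence_neighbors(v)
    union = nu | nv
    return len(nu & nv) / len(union)


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Knobs for equivalence clustering and inter-cluster linking."""

    jaccard_min: float = 0.7
    sample_size: int = 6
    majority_frac: float = 2.0 / 3.0
    rng_seed: int = 0
    prune_all_edges: bool = False  # prune every equivalence edge, not just MST edges
    sample_mode: str = "random"  # or "top-degree"

    def __post_init__(self):
        if not (0.0 <= self.jaccard_min <= 1.0):
            raise InvalidInputError("jaccard_min must lie in [0, 1]")
        if self.sample_size < 1:
            raise InvalidInputError("sample_size must be >= 1")
        if not (0.5 < self.majority_frac <= 1.0):
            raise InvalidInputError("majority_frac must lie in (0.5, 1]")
        if self.sample_mode not in ("random", "top-degree"):
            raise InvalidInputError("sample_mode must be 'random' or 'top-degree'")


@dataclasses.dataclass(frozen=True)
class ClusterEdge:
    cluster_a: str
    cluster_b: str
    relation: Relation
    support: int  # sampled pairs carrying the majority type
    n_sampled: int


@dataclasses.dataclass(frozen=True)
class CBIN:
    """Clustered Boolean Implication Network.

    ``clusters`` maps cluster id -> sorted member genes; ``representatives``
    maps cluster id -> the member with the most within-cluster equivalence
    edges (ties lexicographic); ``edges`` are typed directed links.
    """

    clusters: dict
    representatives: dict
    edges: tuple

    def members(self, cid) -> list:
        return self.clusters[cid]

    def successors(self, cid, types=ASYMMETRIC):
        return sorted(
            (e.cluster_b, e.relation) for e in self.edges
            if e.cluster_a == cid and e.relation in types
        )

    def cluster_of(self, gene):
        for cid, members in self.clusters.items():
            if gene in members:
                return cid
        raise InvalidInputError(f"gene {gene!r} not in any cluster")


def cluster_equivalences(bin_: BIN, params: ClusterParams = ClusterParams()) -> dict:
    """Partition genes into equivalence clusters.

    Restrict to the equivalence subgraph, weight each edge by
    ``1 - jaccard`` so the spanning forest prefers strong links, build a
    minimum spanning forest, delete forest edges whose Jaccard similarity
    falls below ``jaccard_min``, and take connected components.  Genes with
    no surviving edge become singletons.  With ``prune_all_edges`` the
    Jaccard cutoff is applied to every equivalence edge before taking
    components (a sensitivity variant).

    Returns cluster id -> sorted member list; ids are ``C1, C2, ...``
    assigned in lexicographic order of each cluster's smallest member.
    """
    eq = bin_.equivalence_graph()
    jac = {}
    for u, v in sorted(tuple(sorted(e)) for e in eq.edges()):
        jac[(u, v)] = jaccard_similarity(u, v, bin_)

    pruned = nx.Graph()
    pruned.add_nodes_from(eq.nodes())
    if params.prune_all_edges:
        kept = [(u, v) for (u, v), j in jac.items() if j >= params.jaccard_min]
    else:
        weighted = nx.Graph()
        weighted.add_nodes_from(eq.nodes())
        # insertion in sorted order + stable Kruskal sort -> deterministic ties
        for (u, v), j in jac.items():
            weighted.add_edge(u, v, weight=1.0 - j)
        forest = nx.minimum_spanning_edges(weighted, algorithm="kruskal", data=False)
        kept = [
            (u, v)
            for u, v in forest
            if jac.get((min(u, v), max(u, v)), 0.0) >= params.jaccard_min
        ]
    pruned.add_edges_from(kept)

    comps = [sorted(c) for c in nx.connected_components(pruned)]
    comps.sort(key=lambda c: c[0])
    return {f"C{i + 1}": members for i, members in enumerate(comps)}


def _representative(members, bin_: BIN):
    """Member with the most equivalence edges inside the cluster."""
    member_set = set(members)

    def degree(g):
        return len((bin_.equivalence_neighbors(g) - {g}) & member_set)

    return max(sorted(members), key=degree)


def link_clusters(clusters: dict, bin_: BIN, params: ClusterParams = ClusterParams()) -> CBIN:
    """Infer typed directed edges between clusters.

    For each ordered cluster pair (A, B), the representative of A is paired
    with ``min(sample_size, |B|)`` members of B — drawn without replacement
    with a seeded RNG, or the highest-equivalence-degree members in
    ``top-degree`` mode — and the stored relations of those pairs are
    tallied.  An edge A -> B is emitted iff a single non-NONE type accounts
    for at least ``majority_frac`` of the sampled pairs.
    """
    reps = {cid: _representative(members, bin_) for cid, members in clusters.items()}
    rng = np.random.default_rng(params.rng_seed)
    edges = []
    for ca in sorted(clusters):
        rep = reps[ca]
        for cb in sorted(clusters):
            if ca == cb:
                continue
            members = clusters[cb]
            k = min(params.sample_size, len(members))
            if params.sample_mode == "top-degree":
                ranked = sorted(
                    members,
                    key=lambda g: (-len(bin_.equivalence_neighbors(g) - {g}), g),
                )
                sample = ranked[:k]
            else:
                sample = [members[i] for i in rng.choice(len(members), size=k, replace=False)]
            tally = {}
            for g in sample:
                rel = bin_.relation(rep, g)
                tally[rel] = tally.get(rel, 0) + 1
            tally.pop(Relation.NONE, None)
            if not tally:
                continue
            best = max(sorted(tally, key=lambda r: r.value), key=lambda r: tally[r])
            if tally[best] / k >= params.majority_frac:
                edges.append(ClusterEdge(ca, cb, best, tally[best], k))
    return CBIN(clusters=dict(clusters), representatives=reps, edges=tuple(edges))


@dataclasses.dataclass(frozen=True)
class BooleanPath:
    """A simple directed path through asymmetric CBIN edges.

    ``weights`` carry the +1/-1 orientation of each cluster along the path
    (disease-high side +1); they default to +1 and are assigned by the
    caller, not inferred.
    """

    clusters: tuple
    edge_types: tuple
    weights: tuple

    def __post_init__(self):
        if len(self.clusters) != len(self.edge_types) + 1:
            raise InvalidInputError("path needs exactly one edge type per hop")
        if len(self.weights) != len(self.clusters):
            raise InvalidInputError("one weight per cluster required")
        if len(set(self.clusters)) != len(self.clusters):
            raise InvalidInputError("a simple path repeats no cluster")


def chart_paths(cbin: CBIN, seed_cluster, end_cluster=None, max_len: int = 4) -> list:
    """Enumerate simple Boolean paths from a seed cluster.

    Only asymmetric edge types are traversed.  With ``end_cluster`` given,
    only paths terminating there are returned (the two-seed mode used to
    mine intermediate regulators).  Paths have between 1 and ``max_len``
    edges and are returned in lexicographic order of their cluster sequence.
    """
    if seed_cluster not in cbin.clusters:
        raise LookupError(f"unknown cluster {seed_cluster!r}")
    if end_cluster is not None and end_cluster not in cbin.clusters:
        raise LookupError(f"unknown cluster {end_cluster!r}")
    adj = {}
    for e in cbin.edges:
        if e.relation in ASYMMETRIC:
            adj.setdefault(e.cluster_a, []).append((e.cluster_b, e.relation))
    for v in adj.values():
        v.sort()

    paths = []

    def dfs(node, seq, types):
        if len(types) >= 1 and (end_cluster is None or node == end_cluster):
            paths.append(
                BooleanPath(tuple(seq), tuple(types), tuple(1 for _ in seq))
            )
        if len(types) == max_len:
            return
        for nxt, rel in adj.get(node, []):
            if nxt in seq:
                continue
            dfs(nxt, seq + [nxt], types + [rel])

    dfs(seed_cluster, [seed_cluster], [])
    paths.sort(key=lambda p: p.clusters)
    return paths
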