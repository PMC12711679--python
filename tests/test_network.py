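"""BIN assembly, Jaccard clustering, cluster linking, and path charting."""

import itertools

import pytest

from binet import booleannet, network
from binet.booleannet import QuadrantCounts, Relation
from binet.errors import InconsistencyError, InvalidInputError
from binet.network import BIN, ClusterParams


def record(a, b, rel):
    counts = QuadrantCounts(1, 1, 1, 1)
    return booleannet.ImplicationRecord(
        a, b, counts, booleannet.implication_stats(counts), rel
    )


def equivalence_bin(edges, genes=()):
    return BIN.from_records(
        [record(a, b, Relation.EQUIVALENT) for a, b in edges], genes=genes
    )


def clique_edges(genes):
    return list(itertools.combinations(genes, 2))


class TestBuildBIN:
    def test_explicit_isolated_genes(self):
        b = BIN.from_records([], genes=["x", "y", "z"])
        assert b.genes == ["x", "y", "z"]
        assert b.edges() == []

    def test_single_equivalence_edge(self):
        b = equivalence_bin([("a", "b")])
        assert b.edges() == [("a", "b", Relation.EQUIVALENT)]
        assert b.relation("a", "b") is Relation.EQUIVALENT
        assert b.relation("b", "a") is Relation.EQUIVALENT

    def test_asymmetric_edge_and_converse(self):
        b = BIN.from_records([record("a", "b", Relation.HIGH_HIGH)])
        assert b.relation("a", "b") is Relation.HIGH_HIGH
        assert b.relation("b", "a") is Relation.LOW_LOW

    def test_conflicting_records_rejected(self):
        with pytest.raises(InconsistencyError):
            BIN.from_records(
                [record("a", "b", Relation.EQUIVALENT),
                 record("a", "b", Relation.OPPOSITE)]
            )

    def test_counts_from_planted_run(self, planted_bin, planted_pipeline):
        assert len(planted_bin.genes) == len(planted_pipeline["kept"])
        sym = sum(
            1 for r in planted_pipeline["records"]
            if r.relation in booleannet.SYMMETRIC and r.gene_a < r.gene_b
        )
        asym = sum(
            1 for r in planted_pipeline["records"]
            if r.relation in booleannet.ASYMMETRIC
        )
        assert len(planted_bin.edges()) == sym + asym // 2


class TestJaccard:
    def test_identical_closed_neighborhoods(self):
        b = equivalence_bin(clique_edges(["u", "v", "a", "b", "c"]))
        assert network.jaccard_similarity("u", "v", b) == 1.0

    def test_hand_enumeration(self):
        # N[u] = {u, v, a, b}, N[v] = {u, v, a, c}
        b = equivalence_bin(
            [("u", "v"), ("u", "a"), ("u", "b"), ("v", "a"), ("v", "c")]
        )
        assert network.jaccard_similarity("u", "v", b) == pytest.approx(3 / 5)

    def test_disjoint_neighborhoods(self):
        b = equivalence_bin([("u", "a"), ("v", "b")])
        assert network.jaccard_similarity("u", "v", b) == 0.0

    def test_same_gene_rejected(self):
        b = equivalence_bin([("u", "v")])
        with pytest.raises(InvalidInputError):
            network.jaccard_similarity("u", "u", b)


class TestClusterEquivalences:
    def test_single_clique_is_one_cluster(self):
        b = equivalence_bin(clique_edges(["a", "b", "c", "d"]))
        clusters = network.cluster_equivalences(b)
        assert list(clusters.values()) == [["a", "b", "c", "d"]]

    def test_bridged_cliques_split(self):
        left = ["a1", "a2", "a3", "a4"]
        right = ["b1", "b2", "b3", "b4"]
        edges = clique_edges(left) + clique_edges(right) + [("a1", "b1")]
        b = equivalence_bin(edges)
        # bridge jaccard = |{a1,b1}| / |{a1..a4,b1..b4}| = 2/8 < 0.7
        assert network.jaccard_similarity("a1", "b1", b) == pytest.approx(0.25)
        clusters = network.cluster_equivalences(b)
        assert sorted(map(tuple, clusters.values())) == [tuple(left), tuple(right)]

    def test_isolated_gene_is_singleton(self):
        b = equivalence_bin([("a", "b")], genes=["solo"])
        clusters = network.cluster_equivalences(b)
        assert ["solo"] in clusters.values()

    def test_raising_jaccard_min_only_refines(self):
        edges = clique_edges(["a", "b", "c"]) + [("c", "d"), ("d", "e")]
        b = equivalence_bin(edges)
        previous = None
        for jmin in (0.0, 0.3, 0.6, 0.9):
            clusters = network.cluster_equivalences(
                b, ClusterParams(jaccard_min=jmin)
            )
            membership = {
                g: cid for cid, members in clusters.items() for g in members
            }
            if previous is not None:
                # every new cluster must sit inside one previous cluster
                for members in clusters.values():
                    assert len({previous[g] for g in members}) == 1
            previous = membership

    def test_non_forest_edge_removal_is_invisible(self):
        genes = ["a", "b", "c", "d"]
        full = equivalence_bin(clique_edges(genes))
        # drop one chord; the clique stays connected with jaccard-1 edges
        reduced = equivalence_bin([e for e in clique_edges(genes) if e != ("a", "c")])
        assert network.cluster_equivalences(full) == network.cluster_equivalences(
            reduced, ClusterParams(jaccard_min=0.6)
        )

    def test_exact_recovery_of_planted_partition(self, planted_bin, planted):
        clusters = network.cluster_equivalences(planted_bin)
        got = sorted(tuple(m) for m in clusters.values())
        want = sorted(
            tuple(sorted(g for g, c in planted.truth.gene_cluster.items() if c == k))
            for k in range(3)
        )
        assert got == want


class TestLinkClusters:
    def _two_cluster_bin(self, rel_pairs):
        a = [f"a{i}" for i in range(3)]
        b = [f"b{i}" for i in range(6)]
        records = [record(x, y, Relation.EQUIVALENT) for x, y in clique_edges(a)]
        records += [record(x, y, Relation.EQUIVALENT) for x, y in clique_edges(b)]
        for (x, y), rel in rel_pairs.items():
            records.append(record(x, y, rel))
        return BIN.from_records(records), {"CA": a, "CB": b}

    def test_unanimous_type_yields_edge(self):
        rels = {("a0", f"b{i}"): Relation.HIGH_HIGH for i in range(6)}
        bin_, clusters = self._two_cluster_bin(rels)
        cbin = network.link_clusters(clusters, bin_)
        found = [e for e in cbin.edges if (e.cluster_a, e.cluster_b) == ("CA", "CB")]
        assert len(found) == 1 and found[0].relation is Relation.HIGH_HIGH
        assert found[0].support == found[0].n_sampled == 6

    def test_below_majority_yields_no_edge(self):
        rels = {("a0", f"b{i}"): Relation.HIGH_HIGH for i in range(3)}
        bin_, clusters = self._two_cluster_bin(rels)
        cbin = network.link_clusters(clusters, bin_)
        assert not any(
            (e.cluster_a, e.cluster_b) == ("CA", "CB") for e in cbin.edges
        )

    def test_representative_has_max_internal_degree(self):
        # b gains an extra external partner; internal degrees still tie -> lexicographic
        b = equivalence_bin(clique_edges(["m", "n", "p"]))
        clusters = network.cluster_equivalences(b)
        cbin = network.link_clusters(clusters, b)
        assert list(cbin.representatives.values()) == ["m"]

    def test_same_seed_is_bit_identical(self, planted_bin):
        params = ClusterParams(rng_seed=7)
        clusters = network.cluster_equivalences(planted_bin, params)
        one = network.link_clusters(clusters, planted_bin, params)
        two = network.link_clusters(clusters, planted_bin, params)
        assert one == two

    def test_planted_chain_recovered(self, planted_bin, planted):
        clusters = network.cluster_equivalences(planted_bin)
        cbin = network.link_clusters(clusters, planted_bin)
        gc = planted.truth.gene_cluster
        got = {
            (gc[cbin.members(e.cluster_a)[0]], gc[cbin.members(e.cluster_b)[0]]):
            e.relation
            for e in cbin.edges
        }
        assert got[(0, 1)] is Relation.HIGH_HIGH
        assert got[(1, 2)] is Relation.HIGH_LOW
        # converse directions and nothing else
        assert got[(1, 0)] is Relation.LOW_LOW
        assert got[(2, 1)] is Relation.HIGH_LOW
        assert set(got) == {(0, 1), (1, 0), (1, 2), (2, 1)}


def make_cbin(edges, clusters=None):
    ids = sorted({c for e in edges for c in e[:2]})
    clusters = clusters or {c: [f"{c.lower()}_g"] for c in ids}
    reps = {c: members[0] for c, members in clusters.items()}
    return network.CBIN(
        clusters=clusters,
        representatives=reps,
        edges=tuple(network.ClusterEdge(a, b, rel, 6, 6) for a, b, rel in edges),
    )


class TestChartPaths:
    def test_single_edge(self):
        cbin = make_cbin([("A", "B", Relation.HIGH_HIGH)])
        paths = network.chart_paths(cbin, "A")
        assert [p.clusters for p in paths] == [("A", "B")]
        assert paths[0].edge_types == (Relation.HIGH_HIGH,)
        assert paths[0].weights == (1, 1)

    def test_linear_chain_prefixes(self):
        cbin = make_cbin(
            [("A", "B", Relation.HIGH_HIGH), ("B", "C", Relation.HIGH_LOW)]
        )
        paths = network.chart_paths(cbin, "A", max_len=2)
        assert [p.clusters for p in paths] == [("A", "B"), ("A", "B", "C")]

    def test_symmetric_edges_not_traversed(self):
        cbin = make_cbin([("A", "B", Relation.EQUIVALENT)])
        assert network.chart_paths(cbin, "A") == []

    def test_two_seed_mode_filters_endpoint(self):
        cbin = make_cbin(
            [("A", "B", Relation.HIGH_HIGH), ("B", "C", Relation.HIGH_HIGH),
             ("A", "D", Relation.LOW_LOW)]
        )
        paths = network.chart_paths(cbin, "A", end_cluster="C", max_len=3)
        assert [p.clusters for p in paths] == [("A", "B", "C")]

    def test_matches_exhaustive_dfs_oracle(self):
        edges = [
            ("A", "B", Relation.HIGH_HIGH), ("A", "C", Relation.LOW_LOW),
            ("B", "C", Relation.HIGH_LOW), ("C", "D", Relation.HIGH_HIGH),
            ("B", "E", Relation.LOW_HIGH), ("D", "E", Relation.HIGH_HIGH),
        ]
        cbin = make_cbin(edges)
        max_len = 4
        adj = {}
        for a, b, _ in edges:
            adj.setdefault(a, []).append(b)
        expected = []
        def dfs(seq):
            if len(seq) > 1:
                expected.append(tuple(seq))
            if len(seq) - 1 == max_len:
                return
            for nxt in adj.get(seq[-1], []):
                if nxt not in seq:
                    dfs(seq + [nxt])
        dfs(["A"])
        got = [p.clusters for p in network.chart_paths(cbin, "A", max_len=max_len)]
        assert got == sorted(expected)

    def test_unknown_cluster_rejected(self):
        cbin = make_cbin([("A", "B", Relation.HIGH_HIGH)])
        with pytest.raises(LookupError):
            network.chart_paths(cbin, "Z")
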