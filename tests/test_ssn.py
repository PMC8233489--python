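import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from serpintools.core_io import SequenceRecord
from serpintools.powerlaw_fit import (
    bootstrap_pvalue,
    fit_discrete_powerlaw,
    sample_discrete_powerlaw,
)
from serpintools.ssn import (
    ClusterSet,
    NetworkNode,
    SimilarityNetwork,
    annotation_coverage,
    build_network,
    collapse_redundancy,
    mcl_cluster,
    pairwise_identity,
    refine_large_clusters,
)

from oracles import identity_oracle

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_seq(rng, lo=5, hi=40):
    return "".join(rng.choice(AA, size=rng.integers(lo, hi + 1)))


class TestPairwiseIdentity:
    def test_self_identity_is_100(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = random_seq(rng), random_seq(rng)
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a), abs=1e-9)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")

    def test_matches_full_matrix_dp_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b = random_seq(rng), random_seq(rng)
            assert pairwise_identity(a, b) == pytest.approx(
                identity_oracle(a, b), abs=1e-9), (a, b)


class TestCollapseRedundancy:
    def test_identical_sequences_one_node(self):
        records = [SequenceRecord("a", "ACDEFGHIKL"),
                   SequenceRecord("b", "ACDEFGHIKL")]
        nodes = collapse_redundancy(records)
        assert len(nodes) == 1 and sorted(nodes[0].member_ids) == ["a", "b"]

    def test_unrelated_sequences_stay_apart(self):
        records = [SequenceRecord("a", "AAAAAAAAAA"),
                   SequenceRecord("b", "WWWWWWWWWW")]
        nodes = collapse_redundancy(records)
        assert len(nodes) == 2
        assert all(n.size == 1 for n in nodes)

    def test_planted_families_recovered(self, planted_3x5):
        nodes = collapse_redundancy(planted_3x5.records)
        # members of one node must come from one family
        for node in nodes:
            fams = {planted_3x5.family_labels[m] for m in node.member_ids}
            assert len(fams) == 1
        # union of members covers the input exactly
        members = sorted(m for n in nodes for m in n.member_ids)
        assert members == sorted(r.id for r in planted_3x5.records)

    def test_representative_bound_holds(self, planted_3x5):
        seqs = {r.id: r.sequence for r in planted_3x5.records}
        for node in collapse_redundancy(planted_3x5.records):
            for m in node.member_ids:
                assert pairwise_identity(
                    seqs[node.representative_id], seqs[m]) >= 75.0

    def test_duplicate_ids_rejected(self):
        records = [SequenceRecord("a", "ACDE"), SequenceRecord("a", "ACDF")]
        with pytest.raises(ValueError):
            collapse_redundancy(records)


class TestBuildNetwork:
    def test_triangle_at_full_identity(self):
        records = [SequenceRecord(i, "ACDEFGHIKL") for i in "abc"]
        nodes = [NetworkNode(i, [i]) for i in "abc"]
        net = build_network(nodes, records)
        assert len(net.edges) == 3

    def test_exact_threshold_excluded(self):
        # gapless optimal alignment with 2/5 identities: exactly 40.0%
        a, b = "ACWYD", "ACHKM"
        assert pairwise_identity(a, b) == 40.0
        net = build_network(
            [NetworkNode("a", ["a"]), NetworkNode("b", ["b"])],
            {"a": a, "b": b})
        assert net.edges == []

    def test_perturbing_boundary_pair_creates_one_edge(self):
        # raise one aligned mismatch to a match: 40% -> 60%, edge appears
        net = build_network(
            [NetworkNode("a", ["a"]), NetworkNode("b", ["b"])],
            {"a": "ACWYD", "b": "ACWKM"})
        assert len(net.edges) == 1

    def test_missing_sequence_errors(self):
        with pytest.raises(ValueError, match="a"):
            build_network([NetworkNode("a", ["a"])], {})


class TestMcl:
    @staticmethod
    def _net_from_graph(g, weight=100.0):
        nodes = [NetworkNode(str(i), [str(i)]) for i in sorted(g.nodes())]
        index = {str(i): k for k, i in enumerate(sorted(g.nodes()))}
        edges = []
        for u, v in g.edges():
            i, j = sorted((index[str(u)], index[str(v)]))
            edges.append((i, j, weight))
        return SimilarityNetwork(nodes, sorted(edges), identity_threshold=40.0)

    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        clusters = mcl_cluster(self._net_from_graph(g))
        got = sorted(sorted(c) for c in clusters.clusters)
        assert got == [["0", "1", "2"], ["3", "4", "5"]]

    def test_isolated_node_is_singleton(self):
        net = SimilarityNetwork([NetworkNode("x", ["x"])], [])
        clusters = mcl_cluster(net)
        assert clusters.clusters == [["x"]]

    def test_planted_partition_2x10_ari_one(self):
        g = nx.stochastic_block_model(
            [10, 10], [[0.9, 0.05], [0.05, 0.9]], seed=4)
        clusters = mcl_cluster(self._net_from_graph(g), inflation=2.0)
        label = {}
        for k, cl in enumerate(clusters.clusters):
            for n in cl:
                label[int(n)] = k
        pred = [label[i] for i in range(20)]
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_partition_property(self, planted_3x5):
        nodes = collapse_redundancy(planted_3x5.records)
        net = build_network(nodes, planted_3x5.records)
        clusters = mcl_cluster(net)
        flat = sorted(n for c in clusters.clusters for n in c)
        assert flat == sorted(net.node_ids)

    def test_relabeling_equivariance(self):
        g = nx.stochastic_block_model(
            [6, 6], [[0.95, 0.05], [0.05, 0.95]], seed=9)
        net = self._net_from_graph(g)
        base = sorted(sorted(c) for c in mcl_cluster(net).clusters)
        # relabel nodes by reversal
        n = len(net.nodes)
        perm = {i: n - 1 - i for i in range(n)}
        pnodes = [NetworkNode(str(perm[i]), [str(perm[i])])
                  for i in range(n)]
        pedges = sorted(
            (min(perm[i], perm[j]), max(perm[i], perm[j]), w)
            for i, j, w in net.edges)
        pnet = SimilarityNetwork(pnodes, pedges, net.identity_threshold)
        permuted = sorted(
            sorted(str(n - 1 - int(x)) for x in c)
            for c in mcl_cluster(pnet).clusters)
        assert base == permuted

    def test_inflation_monotonicity_smoke(self):
        rng = np.random.default_rng(23)
        for trial in range(20):
            g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            net = self._net_from_graph(g)
            low = len(mcl_cluster(net, inflation=1.5).clusters)
            high = len(mcl_cluster(net, inflation=6.0).clusters)
            assert high >= low

    def test_clusters_never_span_components(self):
        g = nx.Graph([(0, 1), (1, 2), (3, 4)])
        g.add_node(5)
        clusters = mcl_cluster(self._net_from_graph(g))
        comp = {str(n): k for k, cc in
                enumerate(nx.connected_components(g)) for n in cc}
        for cl in clusters.clusters:
            assert len({comp[n] for n in cl}) == 1


class TestRefineLargeClusters:
    def test_small_clusters_untouched(self, planted_3x5):
        nodes = collapse_redundancy(planted_3x5.records)
        net = build_network(nodes, planted_3x5.records)
        clusters = mcl_cluster(net)
        refined = refine_large_clusters(
            clusters, nodes, planted_3x5.records, size_bound=100)
        assert refined.clusters == clusters.clusters


class TestAnnotationCoverage:
    @staticmethod
    def _setup(n_clusters, annotated_flags, size=4):
        nodes, records, clusters = [], [], []
        for k in range(n_clusters):
            ids = [f"c{k}m{i}" for i in range(size)]
            for i, rid in enumerate(ids):
                ann = frozenset({"characterized"}) \
                    if (i == 0 and annotated_flags[k]) else frozenset()
                records.append(SequenceRecord(rid, "ACDEFGHIKL",
                                              annotations=ann))
            nodes.append(NetworkNode(ids[0], ids))
            clusters.append([ids[0]])
        return ClusterSet(clusters=clusters), nodes, records

    def test_coverage_fraction(self):
        cs, nodes, records = self._setup(10, [True] * 3 + [False] * 7)
        table, summary = annotation_coverage(cs, nodes, records)
        assert len(table) == 10
        assert summary["overall"] == pytest.approx(0.3)

    def test_all_below_min_size_gives_nan(self):
        cs, nodes, records = self._setup(3, [True] * 3, size=2)
        table, summary = annotation_coverage(cs, nodes, records, min_size=4)
        assert table.empty
        assert np.isnan(summary["overall"])

    def test_annotated_representative_counts(self):
        cs, nodes, records = self._setup(1, [True])
        table, _ = annotation_coverage(cs, nodes, records)
        assert bool(table["has_annotation"].iloc[0]) is True


class TestPowerlaw:
    def test_alpha_recovery(self):
        rng = np.random.default_rng(42)
        x = sample_discrete_powerlaw(2.5, 1, 5000, rng)
        fit = fit_discrete_powerlaw(x)
        assert abs(fit.alpha - 2.5) <= 0.15

    def test_sampler_matches_theoretical_mass(self):
        from scipy.special import zeta

        rng = np.random.default_rng(8)
        x = sample_discrete_powerlaw(2.5, 1, 20000, rng)
        p1 = 1 - zeta(2.5, 2) / zeta(2.5, 1)
        assert abs((x == 1).mean() - p1) < 0.01

    def test_erdos_renyi_implausible(self):
        deg = np.array([d for _, d in
                        nx.gnp_random_graph(2000, 0.01, seed=7).degree()])
        fit = fit_discrete_powerlaw(deg)
        fit.p_value = bootstrap_pvalue(deg, fit, n_bootstrap=100, seed=2)
        assert fit.goodness == "implausible"

    def test_preferential_attachment_plausible(self):
        deg = np.array([d for _, d in
                        nx.barabasi_albert_graph(2000, 2, seed=9).degree()])
        fit = fit_discrete_powerlaw(deg)
        fit.p_value = bootstrap_pvalue(deg, fit, n_bootstrap=100, seed=3)
        assert fit.goodness == "plausible"

    def test_too_few_nodes_rejected(self):
        net = SimilarityNetwork([NetworkNode("a", ["a"])], [])
        from serpintools.ssn import degree_distribution_fit

        with pytest.raises(ValueError, match="50"):
            degree_distribution_fit(net)


class TestNetworkInvariants:
    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            SimilarityNetwork([NetworkNode("a", ["a"])], [(0, 0, 50.0)])

    def test_edges_below_threshold_rejected(self):
        nodes = [NetworkNode("a", ["a"]), NetworkNode("b", ["b"])]
        with pytest.raises(ValueError):
            SimilarityNetwork(nodes, [(0, 1, 40.0)], identity_threshold=40.0)

    def test_edge_ordering_enforced(self):
        nodes = [NetworkNode("a", ["a"]), NetworkNode("b", ["b"])]
        with pytest.raises(ValueError):
            SimilarityNetwork(nodes, [(1, 0, 50.0)])
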