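"""Fst, PCA, kinship, neighbor joining and median-joining networks."""

import itertools

import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix

from drygene.structure import (
    bootstrap_nj,
    collapse_haplotypes,
    hudson_fst,
    ibs_kinship,
    mj_network,
    network_tables,
    nj_tree,
    p_distance_matrix,
    pairwise_fst,
    pca_genotypes,
)
from drygene.variants import Alignment, GenotypeMatrix


def _gm(data, taxa=None, ids=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return GenotypeMatrix(
        gene="g",
        ids=ids or [f"i{k}" for k in range(n)],
        taxa=taxa or [""] * n,
        positions=list(range(1, data.shape[1] + 1)),
        data=data,
    )


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        assert hudson_fst(0.0, 10, 1.0, 10) == pytest.approx(1.0)

    def test_direct_formula(self):
        p1, p2, n = 0.2, 0.8, 10
        hw = 0.5 * (n / (n - 1) * 2 * p1 * (1 - p1) + n / (n - 1) * 2 * p2 * (1 - p2))
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        assert hudson_fst(p1, n, p2, n) == pytest.approx(1 - hw / hb)

    def test_symmetric_in_population_order(self, rng):
        for _ in range(10):
            p1, p2 = rng.uniform(0.05, 0.95, 2)
            assert hudson_fst(p1, 8, p2, 12) == pytest.approx(hudson_fst(p2, 12, p1, 8))

    def test_identical_frequencies_floor_to_zero(self):
        # the raw sample-size-corrected estimate is slightly negative for
        # equal sample frequencies; the reported (floored) value is 0
        raw = hudson_fst(0.5, 10, 0.5, 10)
        assert raw <= 0.0
        assert max(0.0, raw) == 0.0

    def test_monomorphic_pair_is_nan(self):
        assert np.isnan(hudson_fst(0.0, 10, 0.0, 10))


class TestPairwiseFst:
    def test_per_snp_values(self):
        data = np.array([[0, 0], [0, 0], [1, 0], [1, 0]], dtype=float)
        gm = _gm(data, taxa=["a", "a", "b", "b"])
        out = pairwise_fst(gm, ("a", "b"))
        # SNP 1: fixed difference; SNP 2 monomorphic -> skipped
        assert out["position"].tolist() == [1]
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_skips_underpowered_taxa(self):
        data = np.array([[0], [1], [np.nan], [1]], dtype=float)
        gm = _gm(data, taxa=["a", "a", "b", "b"])
        assert pairwise_fst(gm, ("a", "b")).empty


class TestPca:
    def test_two_clusters_pc1_separates(self):
        data = np.vstack([np.zeros((4, 6)), np.ones((4, 6))])
        gm = _gm(data)
        scores, explained = pca_genotypes(gm)
        pc1 = scores["PC1"].to_numpy()
        assert explained[0] == pytest.approx(1.0)
        assert np.all(np.sign(pc1[:4]) != np.sign(pc1[4:]))

    def test_variance_fractions_sorted_and_bounded(self, rng):
        gm = _gm(rng.integers(0, 2, size=(12, 20)))
        _, explained = pca_genotypes(gm, n_components=5)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-12

    def test_duplicate_individuals_identical_scores(self):
        data = np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1]], dtype=float)
        scores, _ = pca_genotypes(_gm(data))
        assert np.allclose(scores.iloc[0, 1:].astype(float), scores.iloc[1, 1:].astype(float))

    def test_order_invariant_up_to_sign(self, rng):
        data = rng.integers(0, 2, size=(10, 15)).astype(float)
        scores, _ = pca_genotypes(_gm(data))
        perm = rng.permutation(10)
        scores2, _ = pca_genotypes(_gm(data[perm]))
        a = scores["PC1"].to_numpy()
        b = scores2["PC1"].to_numpy()
        # match up rows, allow a global sign flip
        assert np.allclose(a[perm], b) or np.allclose(a[perm], -b)


class TestKinship:
    def test_identical_rows(self):
        k = ibs_kinship(_gm([[0, 1, 0], [0, 1, 0]]))
        assert k.iloc[0, 1] == 1.0

    def test_complementary_rows(self):
        k = ibs_kinship(_gm([[0, 1, 0], [1, 0, 1]]))
        assert k.iloc[0, 1] == 0.0

    def test_half_matching(self):
        k = ibs_kinship(_gm([[0, 0, 1, 1], [0, 1, 1, 0]]))
        assert k.iloc[0, 1] == 0.5

    def test_snp_order_invariant(self, rng):
        data = rng.integers(0, 2, size=(6, 12)).astype(float)
        k1 = ibs_kinship(_gm(data)).to_numpy()
        k2 = ibs_kinship(_gm(data[:, rng.permutation(12)])).to_numpy()
        assert np.allclose(k1, k2)

    def test_no_shared_snps_is_error(self):
        data = np.array([[0.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            ibs_kinship(_gm(data))


class TestNeighborJoining:
    def test_three_leaves_three_point_solution(self):
        # d(AB)=3, d(AC)=5, d(BC)=6 -> a=1, b=2, c=4
        dm = DistanceMatrix(
            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float), ["A", "B", "C"]
        )
        tree = nj_tree(dm)
        tt = tree.tip_tip_distances()
        assert tt["A", "B"] == pytest.approx(3.0)
        assert tt["A", "C"] == pytest.approx(5.0)
        assert tt["B", "C"] == pytest.approx(6.0)

    def test_additive_four_leaf_recovery(self):
        # tree: A-x (1), B-x (2), x-y (2), C-y (3), D-y (4)
        d = {
            ("A", "B"): 3,
            ("A", "C"): 6,
            ("A", "D"): 7,
            ("B", "C"): 7,
            ("B", "D"): 8,
            ("C", "D"): 7,
        }
        ids = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (a, b), v in d.items():
            i, j = ids.index(a), ids.index(b)
            mat[i, j] = mat[j, i] = v
        tree = nj_tree(DistanceMatrix(mat, ids))
        tt = tree.tip_tip_distances()
        for (a, b), v in d.items():
            assert tt[a, b] == pytest.approx(v, abs=1e-9)

    def test_negative_branches_floored(self):
        # non-additive matrix that induces a negative NJ branch
        mat = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]], dtype=float
        )
        mat[0, 2] = mat[2, 0] = 2.0
        tree = nj_tree(DistanceMatrix(mat, ["A", "B", "C", "D"]))
        assert all(n.length >= 0 for n in tree.traverse() if n.length is not None)

    def test_requires_three_leaves(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.array([[0, 1], [1, 0]], dtype=float), ["A", "B"]))


class TestBootstrap:
    def test_two_clades_full_support(self):
        seq_a = "A" * 20 + "C" * 20
        seq_b = "A" * 20 + "T" * 20
        aln = Alignment(
            "g",
            [f"s{i}" for i in range(6)],
            [seq_a] * 3 + [seq_b] * 3,
            ["x"] * 6,
        )
        tree, support = bootstrap_nj(aln, replicates=50, seed=1)
        assert support  # the separating edge exists
        assert max(support.values()) == pytest.approx(100.0)

    def test_deterministic_given_seed(self):
        seqs = ["ACGTACGTAA", "ACGTACGTAT", "ACCTACGAAT", "TCCTACGAAT", "TCCAACGAAT"]
        aln = Alignment("g", [f"s{i}" for i in range(5)], seqs)
        _, s1 = bootstrap_nj(aln, replicates=30, seed=7)
        _, s2 = bootstrap_nj(aln, replicates=30, seed=7)
        assert s1 == s2


class TestCollapseHaplotypes:
    def test_all_identical(self):
        aln = Alignment("g", list("abc"), ["ACGT"] * 3, ["cult"] * 3)
        hs = collapse_haplotypes(aln)
        assert len(hs.haplotypes) == 1
        assert hs.freq == [3]
        assert hs.composition[0] == {"cult": 3}

    def test_all_distinct(self):
        aln = Alignment("g", list("abc"), ["AAAA", "TAAA", "TTAA"])
        hs = collapse_haplotypes(aln)
        assert len(hs.haplotypes) == 3
        assert hs.freq == [1, 1, 1]

    def test_missing_columns_dropped(self):
        aln = Alignment("g", list("abc"), ["ACGT", "ACG-", "ACGT"])
        hs = collapse_haplotypes(aln)
        assert hs.columns == [1, 2, 3]

    def test_diffs_symmetric_zero_diagonal(self):
        aln = Alignment("g", list("abc"), ["AAAA", "TAAA", "TTAA"])
        d = collapse_haplotypes(aln).diffs
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d[0, 2] == 2


def _steiner_min_weight(observed, max_extra=2):
    """Brute-force minimum spanning length allowing added median nodes
    drawn from the per-site product of observed states."""
    sites = list(zip(*observed))
    candidates = {"".join(c) for c in itertools.product(*[set(s) for s in sites])}
    candidates -= set(observed)

    def mst_weight(nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in itertools.combinations(nodes, 2):
            g.add_edge(a, b, weight=sum(x != y for x, y in zip(a, b)))
        return sum(d["weight"] for *_, d in nx.minimum_spanning_edges(g, data=True))

    best = mst_weight(observed)
    for r in range(1, max_extra + 1):
        for extra in itertools.combinations(sorted(candidates), r):
            best = min(best, mst_weight(list(observed) + list(extra)))
    return best


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        aln = Alignment("g", ["a", "b"], ["AAAA", "TTAA"])
        net = mj_network(collapse_haplotypes(aln))
        assert net.number_of_edges() == 1
        (_, _, w), = net.edges(data="weight")
        assert w == 2

    def test_star_resolves_with_one_median(self):
        # three haplotypes at mutual distance 2; the majority-consensus
        # median joins them with three single-step edges
        seqs = ["TAA", "ATA", "AAT"]
        aln = Alignment("g", list("abc"), seqs)
        net = mj_network(collapse_haplotypes(aln))
        inferred = [v for v, d in net.nodes(data=True) if not d["observed"]]
        assert inferred == ["AAA"]
        assert net.number_of_edges() == 3
        assert all(w == 1 for *_, w in net.edges(data="weight"))
        total = sum(w for *_, w in net.edges(data="weight"))
        assert total == _steiner_min_weight(seqs)

    def test_path_stays_a_path(self):
        seqs = ["AAA", "AAT", "ATT"]
        aln = Alignment("g", list("abc"), seqs)
        net = mj_network(collapse_haplotypes(aln))
        assert net.number_of_nodes() == 3
        assert {frozenset(e) for e in net.edges()} == {
            frozenset(("AAA", "AAT")),
            frozenset(("AAT", "ATT")),
        }
        total = sum(w for *_, w in net.edges(data="weight"))
        assert total == _steiner_min_weight(seqs)

    def test_network_connected_and_contains_observed(self, rng):
        from drygene.synthdata import SimConfig, simulate_alignment

        aln = simulate_alignment(SimConfig(seed=3, taxa=(("a", 12),), length=120, theta=3.0))
        hs = collapse_haplotypes(aln)
        net = mj_network(hs)
        assert nx.is_connected(net)
        for h in hs.haplotypes:
            assert h in net
        assert all(w >= 1 for *_, w in net.edges(data="weight"))

    def test_node_attributes_roundtrip(self):
        aln = Alignment(
            "g", list("abcd"), ["AAA", "AAA", "TAA", "TTA"], ["cult", "cult", "wild", "wild"]
        )
        net = mj_network(collapse_haplotypes(aln))
        edges, nodes = network_tables(net)
        assert set(edges.columns) == {"node1", "node2", "weight"}
        counts = dict(zip(nodes["haplotype"], nodes["count"]))
        assert counts["AAA"] == 2

    def test_shared_cultivated_haplotype_pattern(self):
        # all cultivated accessions share one haplotype; wilds are spread
        aln = Alignment(
            "g",
            [f"s{i}" for i in range(8)],
            ["AAAA"] * 4 + ["TAAA", "TTAA", "TAAT", "AAAT"],
            ["cult"] * 4 + ["wild"] * 4,
        )
        hs = collapse_haplotypes(aln)
        cult_nodes = [i for i, c in enumerate(hs.composition) if c.get("cult")]
        assert len(cult_nodes) == 1
        assert hs.freq[cult_nodes[0]] == 4
        assert hs.composition[cult_nodes[0]] == {"cult": 4}


def test_p_distance_pairwise_deletion():
    aln = Alignment("g", list("abc"), ["ACGT", "ACGA", "AC-A"])
    dm = p_distance_matrix(aln)
    assert dm["a", "b"] == pytest.approx(0.25)
    assert dm["a", "c"] == pytest.approx(1 / 3)
    assert dm["b", "c"] == pytest.approx(0.0)
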