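"""Similarity graph construction, Louvain clustering, per-cluster matrices."""

import itertools

import numpy as np
import pytest

from repeatfp.cluster import (
    ClusterPartition,
    SimilarityGraph,
    build_graph,
    cluster_matrices,
    expected_counts,
    louvain,
    modularity,
)
from repeatfp.species import ReadSet, SpeciesProfile, decode_seq

PROFILES = [
    SpeciesProfile("a", "AAAA", 1.0),
    SpeciesProfile("b", "BBBB", 1.0),
    SpeciesProfile("c", "CCCC", 1.0),
]


def _readset(seqs_by_species):
    ids, rows, spidx = [], [], []
    for i, (prof, seqs) in enumerate(zip(PROFILES, seqs_by_species)):
        for k, s in enumerate(seqs):
            ids.append(f"{prof.prefix}r{k}")
            rows.append(s)
            spidx.append(i)
    from repeatfp.species import encode_seq

    return ReadSet(ids, np.vstack([encode_seq(s) for s in rows]), spidx,
                   PROFILES[: len(seqs_by_species)])


def _random_read(rng, n=100):
    return "".join(rng.choice(list("ACGT"), n))


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def brute_force_edges(reads: ReadSet, min_identity=0.90, min_overlap_frac=0.55):
    """Independent oracle: score every pair at every offset on both strands."""
    L = reads.read_length
    min_ov = int(np.ceil(min_overlap_frac * L))
    seqs = [decode_seq(r) for r in reads.matrix]
    edges = {}
    for i, j in itertools.combinations(range(len(seqs)), 2):
        best = 0
        for b in (seqs[j], _revcomp(seqs[j])):
            a = seqs[i]
            for o in range(-(L - min_ov), L - min_ov + 1):
                if o >= 0:
                    x, y = a[o:], b[: L - o]
                else:
                    x, y = a[: L + o], b[-o:]
                m = sum(1 for p, q in zip(x, y) if p == q and p != "N")
                ov = L - abs(o)
                if m >= min_identity * ov - 1e-9:
                    best = max(best, m)
        if best:
            edges[(i, j)] = best
    return edges


class TestBuildGraph:
    def test_identical_reads_edge_weight_is_full_length(self):
        rng = np.random.default_rng(0)
        s = _random_read(rng)
        g = build_graph(_readset([[s], [s]]))
        assert g.n_edges == 1
        assert g.edge_weight[0] == 100.0

    def test_edge_at_minimum_overlap(self):
        # reads share exactly a 55-nt block at offset 45; the rest is random
        rng = np.random.default_rng(1)
        a = _random_read(rng)
        b = a[45:] + _random_read(rng, 45)
        g = build_graph(_readset([[a], [b]]))
        assert g.n_edges == 1
        assert g.edge_weight[0] >= 55

    def test_random_reads_share_no_edge(self):
        rng = np.random.default_rng(2)
        g = build_graph(_readset([[_random_read(rng)], [_random_read(rng)]]))
        assert g.n_edges == 0

    def test_reverse_complement_match(self):
        rng = np.random.default_rng(3)
        s = _random_read(rng)
        g = build_graph(_readset([[s], [_revcomp(s)]]))
        assert g.n_edges == 1
        assert g.edge_weight[0] == 100.0

    def test_matches_brute_force_oracle(self):
        # k=5 seeds make candidate generation essentially complete, so the
        # seeded scorer must agree exactly with all-offsets brute force
        rng = np.random.default_rng(4)
        base1, base2 = _random_read(rng), _random_read(rng)

        def mutate(s, n):
            s = list(s)
            for p in rng.choice(100, n, replace=False):
                s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
            return "".join(s)

        seqs = (
            [mutate(base1, k) for k in (0, 3, 6, 12, 25)]
            + [mutate(base2, k) for k in (0, 4, 9, 30)]
            + [_random_read(rng) for _ in range(5)]
            + [_revcomp(mutate(base1, 5))]
        )
        reads = _readset([seqs[:5], seqs[5:10], seqs[10:]])
        g = build_graph(reads, kmer_seed_length=5)
        got = {
            (int(i), int(j)): w
            for i, j, w in zip(g.edge_i, g.edge_j, g.edge_weight)
        }
        assert got == brute_force_edges(reads)

    def test_unequal_lengths_rejected(self):
        from repeatfp.species import encode_seq

        with pytest.raises(ValueError):
            ReadSet(
                ["AAAAx", "AAAAy"],
                [encode_seq("ACGT" * 25), encode_seq("ACGT" * 20)],
                [0, 0],
                PROFILES[:1],
            )


def _clique_graph(cliques, bridges=()):
    edges = []
    for nodes in cliques:
        edges += list(itertools.combinations(nodes, 2))
    edges += list(bridges)
    n = max(max(e) for e in edges) + 1
    ei = np.array([a for a, b in edges])
    ej = np.array([b for a, b in edges])
    ids = [f"AAAAn{i}" for i in range(n)]
    return SimilarityGraph(ids, np.zeros(n, dtype=int), ["a"], ei, ej,
                           np.ones(len(edges)), 100)


class TestLouvain:
    def test_disjoint_cliques(self):
        g = _clique_graph([range(4), range(4, 8)])
        part = louvain(g, seed=0)
        assert part.n_clusters == 2
        assert sorted(map(len, part.clusters)) == [4, 4]

    def test_bridged_cliques_modularity(self):
        # hand value: Q = 2 * (6/13 - (13/26)^2) for the two-clique partition
        g = _clique_graph([range(4), range(4, 8)], bridges=[(0, 4)])
        part = louvain(g, seed=0)
        assert part.n_clusters == 2
        assert modularity(g, part) == pytest.approx(2 * (6 / 13 - 0.25), abs=1e-12)

    def test_beats_singleton_partition(self):
        rng = np.random.default_rng(0)
        ei, ej = [], []
        for _ in range(60):
            i, j = rng.choice(30, 2, replace=False)
            ei.append(min(i, j)), ej.append(max(i, j))
        key = sorted(set(zip(ei, ej)))
        g = SimilarityGraph([f"AAAAn{i}" for i in range(30)],
                            np.zeros(30, dtype=int), ["a"],
                            np.array([a for a, _ in key]),
                            np.array([b for _, b in key]),
                            np.ones(len(key)), 100)
        part = louvain(g, seed=1)
        singletons = ClusterPartition.from_membership(np.arange(30))
        assert modularity(g, part) >= modularity(g, singletons)

    def test_modularity_matches_networkx(self):
        import networkx as nx

        g = _clique_graph([range(5), range(5, 9)], bridges=[(1, 6), (2, 7)])
        part = louvain(g, seed=3)
        G = nx.Graph()
        G.add_nodes_from(range(g.n_nodes))
        for i, j, w in zip(g.edge_i, g.edge_j, g.edge_weight):
            G.add_edge(int(i), int(j), weight=float(w))
        communities = [set(c.tolist()) for c in part.clusters]
        q_nx = nx.community.modularity(G, communities, weight="weight")
        assert modularity(g, part) == pytest.approx(q_nx, abs=1e-12)

    def test_seeded_determinism(self):
        g = _clique_graph([range(6), range(6, 12)], bridges=[(0, 6), (1, 7)])
        m1 = louvain(g, seed=5).membership
        m2 = louvain(g, seed=5).membership
        assert np.array_equal(m1, m2)


def _two_species_graph(edges, n_a, n_b):
    """edges given as (i, j) over nodes 0..n_a-1 (species a), rest species b."""
    n = n_a + n_b
    ids = [f"AAAAr{i}" for i in range(n_a)] + [f"BBBBr{i}" for i in range(n_b)]
    sp = np.array([0] * n_a + [1] * n_b)
    ei = np.array([a for a, b in edges])
    ej = np.array([b for a, b in edges])
    return SimilarityGraph(ids, sp, ["a", "b"], ei, ej, np.ones(len(edges)), 100)


class TestClusterMatrices:
    def test_worked_example(self):
        # m_AA=2, m_AB=2, m_BB=2 -> E=6, exp={1.5, 3, 1.5}, ratios {4/3, 2/3}
        edges = [(0, 1), (0, 2), (0, 3), (1, 4), (3, 4), (3, 5)]
        g = _two_species_graph(edges, 3, 3)
        part = ClusterPartition.from_membership(np.zeros(6, dtype=int))
        m, obs = cluster_matrices(g, part, 1)
        assert m.data.loc["a", "a"] == 2
        assert m.data.loc["a", "b"] == 2
        assert m.data.loc["b", "b"] == 2
        exp = expected_counts(m.to_numpy())
        assert exp == pytest.approx(np.array([[1.5, 3.0], [3.0, 1.5]]))
        assert obs.data.loc["a", "a"] == pytest.approx(4 / 3)
        assert obs.data.loc["a", "b"] == pytest.approx(2 / 3)
        assert np.triu(exp).sum() == pytest.approx(6.0)

    def test_single_species_cluster_has_no_between_matrix(self):
        g = _two_species_graph([(0, 1), (0, 2)], 3, 1)
        part = ClusterPartition.from_membership(np.array([0, 0, 0, 1]))
        m, obs = cluster_matrices(g, part, 1)
        assert m.data.loc["a", "a"] == 2
        # downstream treats one-species clusters as species-specific; the
        # zero-edge singleton cluster yields no ratio matrix at all
        m2, obs2 = cluster_matrices(g, part, 2)
        assert obs2 is None
        assert m2.to_numpy().sum() == 0

    def test_zero_edges_between_pair_is_zero_not_na(self):
        # both species have edges, but none to each other
        edges = [(0, 1), (2, 3)]
        g = _two_species_graph(edges, 2, 2)
        part = ClusterPartition.from_membership(np.zeros(4, dtype=int))
        _, obs = cluster_matrices(g, part, 1)
        assert obs.data.loc["a", "b"] == 0.0
        assert not np.isnan(obs.data.loc["a", "b"])

    def test_absent_species_yields_na(self):
        ids = [f"AAAAr{i}" for i in range(3)] + ["BBBBr0"]
        sp = np.array([0, 0, 0, 1])
        g = SimilarityGraph(ids, sp, ["a", "b", "c"],
                            np.array([0, 0, 3]), np.array([1, 2, 0]),
                            np.ones(3), 100)
        part = ClusterPartition.from_membership(np.zeros(4, dtype=int))
        _, obs = cluster_matrices(g, part, 1)
        assert np.isnan(obs.data.loc["c", "a"])
        assert obs.has_na

    @pytest.mark.parametrize("seed", range(5))
    def test_expected_counts_conserve_cluster_total(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.integers(2, 7)
        m = np.triu(rng.integers(0, 40, size=(S, S)).astype(float))
        m = m + np.triu(m, 1).T
        E = np.triu(m).sum()
        exp = expected_counts(m)
        assert abs(np.triu(exp).sum() - E) <= 1e-9 * max(E, 1.0)

    def test_edge_conservation_across_partition(self):
        rng = np.random.default_rng(1)
        edges = set()
        for base in (0, 10, 20):
            for _ in range(20):
                i, j = sorted(rng.choice(10, 2, replace=False) + base)
                edges.add((int(i), int(j)))
        edges = sorted(edges)
        n = 30
        g = SimilarityGraph(
            [f"AAAAr{i}" for i in range(n)], np.zeros(n, dtype=int), ["a"],
            np.array([a for a, _ in edges]), np.array([b for _, b in edges]),
            np.ones(len(edges)), 100,
        )
        part = louvain(g, seed=0)
        total_in_clusters = 0.0
        for cid in range(1, part.n_clusters + 1):
            m, _ = cluster_matrices(g, part, cid)
            total_in_clusters += np.triu(m.to_numpy()).sum()
        mem = part.membership
        inter = int((mem[g.edge_i] != mem[g.edge_j]).sum())
        assert total_in_clusters + inter == g.n_edges
        # on this component-separated graph Louvain cuts nothing
        assert inter == 0
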