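"""PCoA, neighbor joining, bootstrap, NeighborNet."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import random_unrooted_tree, tree_distances, tree_split_weights
from repeatfp.matrices import PairMatrix
from repeatfp.multivariate import (
    bipartitions,
    bootstrap_support,
    neighbornet,
    nj_tree,
    pcoa,
    rf_distance,
)


class TestPcoa:
    def test_collinear_points_recover_line(self):
        # points at 0, 1, 3 on a line
        D = pd.DataFrame(
            [[0, 1, 3], [1, 0, 2], [3, 2, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        res = pcoa(D)
        assert res.n_axes == 1
        x = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.abs(np.diff(np.sort(x)))
        assert gaps == pytest.approx([1.0, 2.0], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_euclidean_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        D = squareform(pdist(X))
        res = pcoa(pd.DataFrame(D))
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rebuilt - D).max() <= 1e-9

    def test_zero_matrix(self):
        res = pcoa(pd.DataFrame(np.zeros((4, 4))))
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.n_axes == 0

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(pd.DataFrame(D))

    def test_explained_fractions_properties(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 4))
        res = pcoa(pd.DataFrame(squareform(pdist(X))))
        f = res.explained_fraction
        assert np.all((0 <= f) & (f <= 1))
        assert np.all(np.diff(f) <= 1e-12)
        assert f.sum() == pytest.approx(1.0)

    def test_matches_skbio_up_to_sign(self):
        import skbio.stats.ordination as sko
        from skbio import DistanceMatrix

        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        D = squareform(pdist(X))
        mine = pcoa(pd.DataFrame(D)).coordinates.to_numpy()
        ref = sko.pcoa(DistanceMatrix(D), method="eigh").samples.to_numpy()
        for k in range(mine.shape[1]):
            col, refcol = mine[:, k], ref[:, k]
            assert min(np.abs(col - refcol).max(),
                       np.abs(col + refcol).max()) < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        D = pd.DataFrame(squareform(pdist(X)))
        a = pcoa(D).coordinates.to_numpy()
        b = pcoa(D).coordinates.to_numpy()
        assert np.array_equal(a, b)
        for k in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, k])), k] > 0


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", range(8))
    def test_additive_distances_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        true = random_unrooted_tree(8, rng)
        D = tree_distances(true)
        result = nj_tree(D)
        assert rf_distance(result.tree, true) == 0
        rebuilt = tree_distances(result.tree).loc[D.index, D.columns]
        assert np.abs(rebuilt.to_numpy() - D.to_numpy()).max() <= 1e-9
        assert result.negative_length_deficit == 0.0

    def test_four_point_quartet(self):
        # D satisfying the four-point condition with split {A,B}|{C,D};
        # oracle: least-squares fit of all three quartet topologies
        labels = list("ABCD")
        D = pd.DataFrame(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            index=labels, columns=labels, dtype=float,
        )

        def quartet_rss(split):
            # edge design matrix: 4 pendant lengths + 1 internal
            pairs = list(itertools.combinations(range(4), 2))
            A = np.zeros((6, 5))
            for r, (i, j) in enumerate(pairs):
                A[r, i] = A[r, j] = 1
                same = ({i, j} <= set(split[0])) or ({i, j} <= set(split[1]))
                if not same:
                    A[r, 4] = 1
            y = np.array([D.iloc[i, j] for i, j in pairs])
            x, *_ = np.linalg.lstsq(A, y, rcond=None)
            return ((A @ x - y) ** 2).sum()

        splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        best = min(splits, key=quartet_rss)
        assert best == ((0, 1), (2, 3))
        tree = nj_tree(D).tree
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_star_distances_zero_internal_edges(self):
        labels = list("abcde")
        D = pd.DataFrame(2.0 * (1 - np.eye(5)), index=labels, columns=labels)
        tree = nj_tree(D).tree
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(9)
        true = random_unrooted_tree(7, rng)
        D = tree_distances(true)
        perm = rng.permutation(len(D))
        D2 = D.iloc[perm, perm]
        assert bipartitions(nj_tree(D).tree) == bipartitions(nj_tree(D2).tree)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(10)
        X = rng.normal(size=(7, 4))
        D = squareform(pdist(X))
        labels = [f"t{i}" for i in range(7)]
        mine = nj_tree(pd.DataFrame(D, index=labels, columns=labels))
        ref = skbio_nj(DistanceMatrix(D, ids=labels))
        assert bipartitions(mine.tree) == bipartitions(ref)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(pd.DataFrame(np.zeros((2, 2)), index=list("ab"), columns=list("ab")))

    def test_negative_estimates_clamped_with_deficit(self):
        labels = list("abcd")
        D = pd.DataFrame(
            [[0, 2, 2, 2], [2, 0, 2, 9], [2, 2, 0, 2], [2, 9, 2, 0]],
            index=labels, columns=labels, dtype=float,
        )
        result = nj_tree(D)
        assert result.negative_length_deficit > 0
        for node in result.tree.postorder(include_self=False):
            assert node.length >= 0


def _dissim(values, species=("a", "b", "c", "d")):
    arr = np.asarray(values, dtype=float)
    return PairMatrix(arr, "obs_exp", species=list(species))


class TestBootstrap:
    def _clusters(self, seed, n=12):
        rng = np.random.default_rng(seed)
        true = random_unrooted_tree(6, rng)
        D = tree_distances(true)
        labels = list(D.index)
        out = []
        for _ in range(n):
            noise = rng.normal(0, 0.01, size=D.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            out.append(PairMatrix(np.abs(D.to_numpy() + noise), "obs_exp",
                                  species=labels))
        return out, true

    def test_identical_clusters_full_support(self):
        clusters, _ = self._clusters(0, n=1)
        clusters = clusters * 5
        result = bootstrap_support(clusters, replicates=50, seed=1)
        assert result.supports
        assert all(v == 100.0 for v in result.supports.values())

    def test_zero_replicates_returns_point_tree(self):
        clusters, _ = self._clusters(1)
        result = bootstrap_support(clusters, replicates=0, seed=0)
        assert result.supports is None

    def test_cluster_order_invariance(self):
        clusters, _ = self._clusters(2)
        a = bootstrap_support(clusters, replicates=100, seed=7)
        b = bootstrap_support(clusters[::-1], replicates=100, seed=7)
        assert a.supports == b.supports

    def test_supports_bounded_and_newick_annotated(self):
        clusters, _ = self._clusters(3)
        result = bootstrap_support(clusters, replicates=100, seed=3)
        assert all(0.0 <= v <= 100.0 for v in result.supports.values())
        assert result.to_newick().count("(") >= 3

    def test_single_cluster_rejected(self):
        clusters, _ = self._clusters(4, n=1)
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_support(clusters, replicates=10, seed=0)

    def test_support_for_true_splits_grows_with_cluster_count(self):
        # clusters from a strongly tree-like generator: more replication
        # units -> higher majority support for the true splits
        rng = np.random.default_rng(5)
        true = random_unrooted_tree(6, rng)
        D = tree_distances(true)
        labels = list(D.index)
        true_splits = bipartitions(true)

        def mean_true_support(n_clusters, seed):
            rng2 = np.random.default_rng(seed)
            mats = []
            for _ in range(n_clusters):
                noise = rng2.normal(0, 0.35, size=D.shape)
                noise = (noise + noise.T) / 2
                np.fill_diagonal(noise, 0.0)
                mats.append(PairMatrix(np.abs(D.to_numpy() + noise), "obs_exp",
                                       species=labels))
            res = bootstrap_support(mats, replicates=100, seed=seed)
            vals = [res.supports.get(s, 0.0) for s in true_splits]
            return np.mean(vals)

        supports = [mean_true_support(n, seed=11) for n in (4, 16, 64)]
        assert supports[0] <= supports[1] <= supports[2]
        assert supports[2] > 80.0


class TestNeighborNet:
    @pytest.mark.parametrize("seed", range(5))
    def test_tree_distances_give_tree_splits(self, seed):
        rng = np.random.default_rng(seed)
        true = random_unrooted_tree(8, rng)
        D = tree_distances(true)
        nn = neighbornet(D)
        expected = tree_split_weights(true)
        labels = set(D.index)
        ref = min(labels)
        got = {}
        for side, w in nn.splits:
            side = frozenset(labels - side) if ref in side else side
            got[side] = w
        assert set(got) == set(expected)
        for split, w in expected.items():
            assert got[split] == pytest.approx(w, abs=1e-6)

    def test_circular_metric_ordering_recovered(self):
        n = 5
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D[i, j] = min(abs(i - j), n - abs(i - j))
        labels = list("abcde")
        nn = neighbornet(pd.DataFrame(D, index=labels, columns=labels))
        pos = {t: k for k, t in enumerate(nn.ordering)}
        # adjacent letters in the generating circle must be adjacent in the
        # recovered cyclic ordering (up to rotation/reflection)
        for a, b in zip(labels, labels[1:] + labels[:1]):
            assert (pos[a] - pos[b]) % n in (1, n - 1)
        # and the split weights reproduce the metric
        resid = np.abs(nn.distance().loc[labels, labels].to_numpy() - D).max()
        assert resid <= 1e-8

    def test_zero_distances_empty_splits(self):
        D = pd.DataFrame(np.zeros((5, 5)), index=list("abcde"), columns=list("abcde"))
        assert neighbornet(D).splits == []

    def test_too_few_taxa(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="at least 4"):
            neighbornet(D)

    def test_splits_are_intervals_of_the_ordering(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(7, 3))
        D = squareform(pdist(X))
        labels = [f"t{i}" for i in range(7)]
        nn = neighbornet(pd.DataFrame(D, index=labels, columns=labels))
        pos = {t: k for k, t in enumerate(nn.ordering)}
        for side, w in nn.splits:
            assert w >= 0
            ks = sorted(pos[t] for t in side)
            assert ks == list(range(ks[0], ks[-1] + 1))  # contiguous block
            assert 0 not in ks  # stored side excludes the ordering's first taxon

    def test_nexus_output(self, tmp_path):
        rng = np.random.default_rng(8)
        true = random_unrooted_tree(5, rng)
        nn = neighbornet(tree_distances(true))
        out = tmp_path / "splits.nex"
        nn.to_nexus(out)
        text = out.read_text()
        assert text.startswith("#nexus")
        assert "BEGIN Splits;" in text
        assert f"nsplits={len(nn.splits)}" in text
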