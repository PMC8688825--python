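"""Desk-scale comparative read clustering.

Emulates the graph stage of RepeatExplorer-style comparative clustering:

1. all-vs-all read similarity under the classic acceptance rule — at least
   90% identity over at least 55% of the read length — implemented as an
   ungapped offset alignment with shared-k-mer candidate seeding over both
   strands followed by exhaustive offset scoring of every candidate pair;
2. Louvain community detection on the weighted similarity graph;
3. per-cluster species-pair matrices: observed edge counts m_ab and
   observed/expected ratios, where the expectation distributes the cluster's
   edge total E over species pairs by the product of edge-endpoint
   proportions q_a, exp_ab = 2*E*q_a*q_b (a != b) and E*q_a^2 (a == b), which
   conserves E exactly.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph
import numpy as np
from scipy import sparse

from .matrices import PairMatrix
from .species import ReadSet

__all__ = [
    "SimilarityGraph",
    "ClusterPartition",
    "build_graph",
    "louvain",
    "modularity",
    "cluster_matrices",
    "matrices_from_counts",
    "expected_counts",
    "edge_count_array",
]


@dataclass
class SimilarityGraph:
    """Weighted undirected read-similarity graph.

    Nodes are read indices into ``read_ids`` (the species of each node is
    known through its prefix); an edge's weight is overlap x identity — i.e.
    the number of matching positions — of the best qualifying ungapped offset
    alignment between the two reads, on either strand.
    """

    read_ids: list[str]
    species_idx: np.ndarray
    species_labels: list[str]
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_weight: np.ndarray
    read_length: int

    @property
    def n_nodes(self) -> int:
        return len(self.read_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes)
        np.add.at(deg, self.edge_i, self.edge_weight)
        np.add.at(deg, self.edge_j, self.edge_weight)
        return deg

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(
            n=self.n_nodes,
            edges=list(zip(self.edge_i.tolist(), self.edge_j.tolist())),
        )
        g.es["weight"] = self.edge_weight.tolist()
        return g

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_a\tread_b\tweight\n")
            for i, j, w in zip(self.edge_i, self.edge_j, self.edge_weight):
                fh.write(f"{self.read_ids[i]}\t{self.read_ids[j]}\t{w:g}\n")


@dataclass
class ClusterPartition:
    """Partition of graph nodes into clusters, ordered by decreasing size.

    Cluster ids are 1-based (cluster 1 = largest); ties in size are broken by
    the smallest contained node index.  Singleton components are retained as
    (species-specific) clusters of size one.
    """

    membership: np.ndarray  # node -> cluster id (1-based)
    clusters: list[np.ndarray]  # cluster id - 1 -> sorted node indices

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters])

    @classmethod
    def from_membership(cls, raw: np.ndarray) -> "ClusterPartition":
        raw = np.asarray(raw)
        groups: dict[int, list[int]] = {}
        for node, com in enumerate(raw):
            groups.setdefault(int(com), []).append(node)
        ordered = sorted(groups.values(), key=lambda nodes: (-len(nodes), nodes[0]))
        membership = np.zeros(len(raw), dtype=np.int64)
        clusters = []
        for cid, nodes in enumerate(ordered, start=1):
            arr = np.array(nodes, dtype=np.int64)
            membership[arr] = cid
            clusters.append(arr)
        return cls(membership, clusters)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def _kmer_occurrence_matrix(M: np.ndarray, k: int) -> sparse.csr_matrix:
    """Binary sparse matrix: reads x k-mer keys (windows containing N skipped)."""
    n, L = M.shape
    if k > L:
        raise ValueError(f"k-mer length {k} exceeds read length {L}")
    nw = L - k + 1
    km = np.zeros((n, nw), dtype=np.int64)
    bad = np.zeros((n, nw), dtype=bool)
    for j in range(k):
        col = M[:, j : j + nw]
        km = km * 4 + np.minimum(col, 3).astype(np.int64)
        bad |= col > 3
    rows = np.repeat(np.arange(n, dtype=np.int64), nw)
    keep = ~bad.ravel()
    rows, vals = rows[keep], km.ravel()[keep]
    # deduplicate (read, kmer) pairs so the candidate product counts pairs once
    packed = np.unique(rows * (4**k) + vals)
    rows, vals = packed // (4**k), packed % (4**k)
    return sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, vals)),
        shape=(n, 4**k),
    )


def _candidate_pairs(mat_a: sparse.csr_matrix, mat_b: sparse.csr_matrix):
    """Read pairs (i < j) sharing at least one k-mer between the two matrices."""
    prod = (mat_a @ mat_b.T).tocoo()
    i, j = prod.row, prod.col
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    keep = lo < hi
    packed = np.unique(lo[keep].astype(np.int64) * mat_a.shape[0] + hi[keep])
    return packed // mat_a.shape[0], packed % mat_a.shape[0]


def _best_offset_scores(
    A: np.ndarray,
    B: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    min_overlap: int,
    min_identity: float,
    chunk: int = 200_000,
) -> np.ndarray:
    """Best qualifying match count per pair over all ungapped offsets.

    Scores A[ii[p]] against B[jj[p]]; an offset qualifies when its overlap is
    at least ``min_overlap`` and matches/overlap >= ``min_identity``.  N bases
    never match.  Returns 0 for pairs with no qualifying offset.
    """
    L = A.shape[1]
    best = np.zeros(len(ii), dtype=np.int64)
    for s in range(0, len(ii), chunk):
        a = A[ii[s : s + chunk]]
        b = B[jj[s : s + chunk]]
        blk = np.zeros(a.shape[0], dtype=np.int64)
        for o in range(-(L - min_overlap), L - min_overlap + 1):
            if o >= 0:
                x, y = a[:, o:], b[:, : L - o]
            else:
                x, y = a[:, : L + o], b[:, -o:]
            m = ((x == y) & (x < 4)).sum(axis=1)
            ov = L - abs(o)
            qual = m >= min_identity * ov - 1e-9
            np.maximum(blk, np.where(qual, m, 0), out=blk)
        best[s : s + chunk] = blk
    return best


def build_graph(
    reads: ReadSet,
    min_identity: float = 0.90,
    min_overlap_frac: float = 0.55,
    kmer_seed_length: int = 13,
) -> SimilarityGraph:
    """Build the read-similarity graph under the identity/overlap rule.

    An edge joins two reads iff some ungapped offset alignment — on either
    strand — covers at least ceil(min_overlap_frac * L) positions with
    identity >= min_identity; its weight is overlap x identity (the match
    count) of the best such offset.  Candidates are seeded by shared k-mers,
    then every candidate pair is scored exhaustively over all offsets, so the
    only pairs a true BLAST would add are those whose qualifying alignment
    contains no exact k-mer of the seed length.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    M = reads.matrix
    L = reads.read_length
    # guard the ceiling against float artifacts (0.55*100 -> 55.000000000000007)
    min_overlap = int(np.ceil(min_overlap_frac * L - 1e-9))

    R = np.where(M < 4, 3 - M, 4)[:, ::-1].astype(np.uint8)  # reverse complements
    mf = _kmer_occurrence_matrix(M, kmer_seed_length)
    mr = _kmer_occurrence_matrix(R, kmer_seed_length)

    ii_f, jj_f = _candidate_pairs(mf, mf)
    w_f = _best_offset_scores(M, M, ii_f, jj_f, min_overlap, min_identity)

    prod = (mf @ mr.T).tocoo()  # i forward vs j reverse-complement
    lo, hi = np.minimum(prod.row, prod.col), np.maximum(prod.row, prod.col)
    keep = lo < hi
    packed = np.unique(lo[keep].astype(np.int64) * mf.shape[0] + hi[keep])
    ii_r, jj_r = packed // mf.shape[0], packed % mf.shape[0]
    w_r = _best_offset_scores(M, R, ii_r, jj_r, min_overlap, min_identity)

    # merge strands: one undirected edge per read pair, best weight wins
    key = np.concatenate([ii_f * len(reads) + jj_f, ii_r * len(reads) + jj_r])
    wts = np.concatenate([w_f, w_r]).astype(float)
    ukey, inv = np.unique(key, return_inverse=True)
    best = np.zeros(len(ukey))
    np.maximum.at(best, inv, wts)
    hit = best > 0
    ukey, best = ukey[hit], best[hit]
    return SimilarityGraph(
        read_ids=reads.ids,
        species_idx=reads.species_idx.copy(),
        species_labels=reads.species_labels,
        edge_i=(ukey // len(reads)).astype(np.int64),
        edge_j=(ukey % len(reads)).astype(np.int64),
        edge_weight=best,
        read_length=L,
    )


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

def louvain(
    graph: SimilarityGraph, seed: int = 0, resolution: float = 1.0
) -> ClusterPartition:
    """Louvain modularity optimization on edge weights (seeded, size-ordered).

    Runs igraph's multi-level Louvain; igraph draws its randomness from
    Python's ``random`` module, whose state is seeded here and restored
    afterwards, so results are reproducible for a given seed.  Isolated nodes
    come back as singleton clusters.
    """
    if graph.n_nodes == 0:
        return ClusterPartition(np.zeros(0, dtype=np.int64), [])
    g = graph.to_igraph()
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        communities = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    return ClusterPartition.from_membership(np.asarray(communities.membership))


def modularity(graph: SimilarityGraph, partition: ClusterPartition) -> float:
    """Newman weighted modularity Q of a partition, recomputed independently.

    Q = sum_c [ w_in_c / W - (deg_c / 2W)^2 ] with W the total edge weight.
    """
    W = graph.edge_weight.sum()
    if W == 0:
        return 0.0
    mem = partition.membership
    deg = graph.degrees()
    q = 0.0
    intra = np.zeros(partition.n_clusters + 1)
    same = mem[graph.edge_i] == mem[graph.edge_j]
    np.add.at(intra, mem[graph.edge_i[same]], graph.edge_weight[same])
    for cid, nodes in enumerate(partition.clusters, start=1):
        q += intra[cid] / W - (deg[nodes].sum() / (2.0 * W)) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# per-cluster species-pair matrices
# ---------------------------------------------------------------------------

def expected_counts(m: np.ndarray) -> np.ndarray:
    """Expected species-pair edge counts under proportional mixing.

    With E the cluster's edge total and q_a the proportion of edge endpoints
    belonging to species a, exp_ab = 2*E*q_a*q_b off the diagonal and
    E*q_a^2 on it; since sum(q) = 1, the expectations sum back to E exactly.
    """
    m = np.asarray(m, dtype=float)
    E = np.triu(m).sum()
    if E == 0:
        return np.zeros_like(m)
    rowsum = m.sum(axis=1)  # = m_aa + sum_{b!=a} m_ab
    q = (rowsum + np.diag(m)) / (2.0 * E)
    exp = 2.0 * E * np.outer(q, q)
    np.fill_diagonal(exp, E * q**2)
    return exp


def matrices_from_counts(
    m: np.ndarray, labels: list[str]
) -> tuple[PairMatrix, PairMatrix | None]:
    """Edges and obs/exp matrices from a symmetric edge-count array."""
    edges = PairMatrix(m, "edges", species=labels)
    E = np.triu(np.asarray(m, dtype=float)).sum()
    if E == 0:
        return edges, None
    exp = expected_counts(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp > 0, m / np.where(exp > 0, exp, 1.0), np.nan)
    obs_exp = PairMatrix(ratio, "obs_exp", species=labels)
    return edges, obs_exp


def edge_count_array(
    graph: SimilarityGraph, partition: ClusterPartition
) -> np.ndarray:
    """Per-cluster species-pair edge counts for every cluster at once.

    Returns an (n_clusters + 1, S, S) array of symmetric counts indexed by
    1-based cluster id; edges whose endpoints fall in different clusters are
    cut by the partition and belong to no cluster.
    """
    S = len(graph.species_labels)
    M = np.zeros((partition.n_clusters + 1, S, S))
    mem = partition.membership
    same = mem[graph.edge_i] == mem[graph.edge_j]
    cids = mem[graph.edge_i[same]]
    sa = graph.species_idx[graph.edge_i[same]]
    sb = graph.species_idx[graph.edge_j[same]]
    np.add.at(M, (cids, np.minimum(sa, sb), np.maximum(sa, sb)), 1.0)
    upper = np.triu(np.ones((S, S)), 1).astype(bool)
    M += np.where(upper, M, 0.0).transpose(0, 2, 1)
    return M


def cluster_matrices(
    graph: SimilarityGraph,
    partition: ClusterPartition,
    cluster_id: int,
) -> tuple[PairMatrix, PairMatrix | None]:
    """Observed-edges and observed/expected matrices for one cluster.

    m_ab counts the cluster's intra-cluster edges by species pair (the
    diagonal holds intra-species edges).  With E = sum_{a<=b} m_ab and
    endpoint proportions q_a = (2 m_aa + sum_{b!=a} m_ab) / (2E), the
    expectation is exp_ab = 2*E*q_a*q_b off-diagonal and E*q_a^2 on it, which
    sums back to E exactly.  Cells with zero expectation (species without
    reads in the cluster — or, degenerately, without any incident edge) are
    NA.  For clusters with no edges at all no matrices can be formed and
    ``(None, None)`` would be meaningless, so a zero edges matrix with
    ``obs_exp=None`` is returned; such clusters are species-specific by
    construction.
    """
    if not 1 <= cluster_id <= partition.n_clusters:
        raise KeyError(f"cluster {cluster_id} not in partition")
    labels = graph.species_labels
    S = len(labels)
    nodes = partition.clusters[cluster_id - 1]
    in_cluster = np.zeros(graph.n_nodes, dtype=bool)
    in_cluster[nodes] = True

    emask = in_cluster[graph.edge_i] & in_cluster[graph.edge_j]
    sa = graph.species_idx[graph.edge_i[emask]]
    sb = graph.species_idx[graph.edge_j[emask]]
    m = np.zeros((S, S))
    np.add.at(m, (np.minimum(sa, sb), np.maximum(sa, sb)), 1.0)
    m = m + np.triu(m, 1).T  # symmetrize off-diagonal counts
    return matrices_from_counts(m, labels)


def cluster_read_counts(
    graph: SimilarityGraph, partition: ClusterPartition, cluster_id: int
) -> dict[str, int]:
    """Reads per species inside one cluster."""
    nodes = partition.clusters[cluster_id - 1]
    counts = np.bincount(graph.species_idx[nodes], minlength=len(graph.species_labels))
    return {lab: int(c) for lab, c in zip(graph.species_labels, counts)}
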