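"""Neighbor-joining trees with cluster-resampling bootstrap support.

Canonical Saitou–Nei agglomeration with the Studier–Keppler Q criterion:
Q(i, j) = (n - 2) d(i, j) - r_i - r_j, ties broken by the lexicographically
smallest pair of subtree labels (the smallest leaf name below each node), so
output is invariant to taxon input order.  Negative branch-length estimates
are clamped to zero with the clamped amount reported.

Bootstrap support resamples whole clusters with replacement — the cluster is
the independent replication unit of the fingerprint method — re-sums the
master matrix, recomputes the Gower distance and re-runs NJ; support of an
internal edge is the percentage of replicates containing its bipartition.
Column resampling of the master variable table is available as an
alternative unit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from ..fingerprint import gower_distance, sum_master
from ..matrices import PairMatrix

__all__ = ["PhyloTree", "nj_tree", "bootstrap_support", "bipartitions", "rf_distance"]


@dataclass
class PhyloTree:
    """An unrooted leaf-labeled tree (stored with a trifurcating root).

    ``supports`` maps internal bipartitions (canonical frozenset of leaf
    labels) to bootstrap percentages in [0, 100]; ``None`` when no bootstrap
    was run.  ``negative_length_deficit`` is the total branch length clamped
    away from negative NJ estimates.
    """

    tree: skbio.TreeNode
    supports: dict[frozenset, float] | None = None
    negative_length_deficit: float = 0.0

    @property
    def taxa(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def to_newick(self) -> str:
        tree = self.tree.copy()
        if self.supports is not None:
            ref_labels = set(self.taxa)
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                key = _canonical(side, ref_labels)
                if key in self.supports:
                    node.name = f"{self.supports[key]:g}"
        buf = io.StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue()


def _canonical(side: frozenset, all_labels: set) -> frozenset:
    """Canonical representation of an unrooted bipartition: the half that
    does not contain the alphabetically first taxon."""
    ref = min(all_labels)
    return frozenset(all_labels - side) if ref in side else frozenset(side)


def bipartitions(tree: skbio.TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree."""
    labels = {t.name for t in tree.tips()}
    n = len(labels)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            splits.add(_canonical(side, labels))
    return splits


def rf_distance(t1, t2) -> int:
    """Robinson–Foulds distance (symmetric bipartition difference count)."""
    a = bipartitions(t1.tree if isinstance(t1, PhyloTree) else t1)
    b = bipartitions(t2.tree if isinstance(t2, PhyloTree) else t2)
    return len(a ^ b)


def nj_tree(distance, clamp_negative: bool = True) -> PhyloTree:
    """Neighbor joining on a species x species distance table."""
    df = pd.DataFrame(distance)
    labels = [str(x) for x in df.index]
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = df.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    nodes = [skbio.TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # smallest leaf label below each active node
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if clamp_negative and x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        pairs = sorted(
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = pairs[0]

        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        parent = skbio.TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])

        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    root = skbio.TreeNode()
    (a, b, c) = (0, 1, 2)
    nodes[a].length = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    nodes[b].length = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    nodes[c].length = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root.extend(nodes)
    return PhyloTree(root, None, deficit)


def bootstrap_support(
    clusters: list[PairMatrix],
    replicates: int = 1000,
    seed: int = 0,
    unit: str = "cluster",
) -> PhyloTree:
    """NJ tree with bootstrap percentages from cluster resampling.

    The point-estimate tree is NJ on the Gower distance of the summed master
    matrix; each replicate resamples the per-cluster dissimilarity matrices
    (``unit="cluster"``) or the master table's columns (``unit="column"``)
    with replacement and recomputes the whole chain.  ``replicates=0``
    returns the point tree without support values.
    """
    if len(clusters) < 2:
        raise ValueError("bootstrap needs at least 2 clusters to resample")
    if unit not in ("cluster", "column"):
        raise ValueError("unit must be 'cluster' or 'column'")
    master_kind = "obs" if clusters[0].kind == "obs_exp" else "edges"
    master = sum_master(clusters, master_kind)
    point = nj_tree(gower_distance(master))
    if replicates == 0:
        return point

    labels = set(master.species)
    target = bipartitions(point.tree)
    hits = {split: 0 for split in target}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # resampling indices are drawn against a canonical cluster order so the
    # supports do not depend on how the cluster list happened to be sorted
    canonical = sorted(clusters, key=lambda m: m.to_numpy().tobytes())
    for _ in range(replicates):
        if unit == "cluster":
            take = rng.integers(0, len(canonical), size=len(canonical))
            rep_master = sum_master([canonical[k] for k in take], master_kind)
            rep_table = rep_master.data
        else:
            cols = rng.integers(0, len(master.species), size=len(master.species))
            rep_table = master.data.iloc[:, cols]
        rep = nj_tree(gower_distance(rep_table))
        for split in bipartitions(rep.tree) & target:
            hits[split] += 1
    supports = {s: 100.0 * h / replicates for s, h in hits.items()}
    return PhyloTree(point.tree, supports, point.negative_length_deficit)
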