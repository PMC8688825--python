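"""Shared fixtures and oracle helpers for the repeatfp test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import skbio

from repeatfp.archive import ClusterRecord
from repeatfp.matrices import PairMatrix
from repeatfp.species import SpeciesProfile


@pytest.fixture
def two_species():
    return [
        SpeciesProfile("speciesA", "AAAA", 1.0),
        SpeciesProfile("speciesB", "BBBB", 1.0),
    ]


def random_unrooted_tree(n_leaves: int, rng: np.random.Generator) -> skbio.TreeNode:
    """Random binary unrooted tree with positive branch lengths."""
    nodes = [
        skbio.TreeNode(name=f"t{i}", length=round(float(rng.uniform(0.1, 1.0)), 6))
        for i in range(n_leaves)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        parent = skbio.TreeNode(length=round(float(rng.uniform(0.1, 1.0)), 6))
        parent.extend([a, b])
        nodes.append(parent)
    root = skbio.TreeNode()
    root.extend(nodes)
    return root


def tree_distances(tree: skbio.TreeNode) -> pd.DataFrame:
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)


def tree_split_weights(tree: skbio.TreeNode) -> dict[frozenset, float]:
    """All splits of an unrooted tree (trivial ones included), canonicalized
    to the side not containing the alphabetically first taxon, with their
    branch lengths (parallel edges summed)."""
    labels = {t.name for t in tree.tips()}
    ref = min(labels)
    out: dict[frozenset, float] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            side = frozenset({node.name})
        else:
            side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(labels - side)
        if side:
            out[side] = out.get(side, 0.0) + (node.length or 0.0)
    return out


def brute_force_gower(X: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit range-normalized Manhattan loop."""
    n, p = X.shape
    rng_ = X.max(axis=0) - X.min(axis=0)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc, used = 0.0, 0
            for k in range(p):
                if rng_[k] > 0:
                    acc += abs(X[i, k] - X[j, k]) / rng_[k]
                    used += 1
            D[i, j] = acc / used if used else 0.0
    return D


def make_record(
    cluster_id: int,
    rng: np.random.Generator,
    species=("AAAA", "BBBB", "CCCC"),
    species_specific: bool = False,
    contamination: bool = False,
    with_na: bool = False,
) -> ClusterRecord:
    """Random cluster record with the requested flag combination."""
    S = len(species)
    m = np.triu(rng.integers(1, 50, size=(S, S)).astype(float))
    m = m + np.triu(m, 1).T
    edges = PairMatrix(m, "edges", species=list(species))
    obs_exp = None
    if not species_specific:
        r = np.triu(rng.uniform(0.1, 3.0, size=(S, S)))
        r = r + np.triu(r, 1).T
        if with_na:
            r[0, 1] = r[1, 0] = np.nan
        obs_exp = PairMatrix(r, "obs_exp", species=list(species))
    annotations = {}
    if contamination:
        annotations["contamination"] = float(rng.uniform(0.1, 1.0))
    if rng.random() < 0.3:
        annotations["45S_rDNA"] = float(rng.uniform(0.0, 0.2))
    counts = {sp: int(rng.integers(1, 100)) for sp in species}
    return ClusterRecord(
        cluster_id=cluster_id,
        edges=edges,
        obs_exp=obs_exp,
        read_counts=counts,
        annotations=annotations,
    )
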