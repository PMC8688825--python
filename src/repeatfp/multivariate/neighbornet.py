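"""NeighborNet: circular split systems from distance matrices.

Two stages, after Bryant & Moulton:

1. *Agglomeration.*  Taxa are gathered into clusters of at most two linked
   nodes.  Cluster pairs are selected by the neighbor-joining Q criterion on
   average cluster distances; within the selected pair, the joined nodes are
   picked by the analogous criterion over the remaining clusters plus the
   members of the two chosen clusters.  Whenever a cluster would grow to
   three consecutive nodes (p1, p2, p3), it is reduced to two fresh nodes
   u, v with

       d(u, w) = 2/3 d(p1, w) + 1/3 d(p2, w)
       d(v, w) = 1/3 d(p2, w) + 2/3 d(p3, w)
       d(u, v) = (d(p1, p2) + d(p2, p3) + d(p1, p3)) / 3,

   and the replacement is recorded.  When three clusters remain they are
   closed into a cycle (choosing the closure of least total adjacent
   distance), and the recorded reductions are expanded in reverse to yield a
   circular ordering of the original taxa.

2. *Split weights.*  Every split that is an interval of the circular
   ordering is a candidate; weights are estimated by non-negative least
   squares against the input distances, and splits below ``epsilon`` are
   dropped.  On additive (tree) distances this returns exactly the tree's
   splits with their branch lengths; on circular-decomposable distances the
   input metric is reproduced exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["SplitSystem", "neighbornet"]


@dataclass
class SplitSystem:
    """A circular taxon ordering plus weighted splits compatible with it.

    Each split is stored as (frozenset of taxa on one side, weight >= 0); the
    stored side is an interval of ``ordering`` that excludes its first taxon.
    """

    ordering: list[str]
    splits: list[tuple[frozenset, float]]

    def distance(self) -> pd.DataFrame:
        """Distances implied by the split weights (for residual checks)."""
        n = len(self.ordering)
        D = np.zeros((n, n))
        pos = {t: k for k, t in enumerate(self.ordering)}
        for side, w in self.splits:
            mask = np.zeros(n, dtype=bool)
            mask[[pos[t] for t in side]] = True
            D[np.ix_(mask, ~mask)] += w
            D[np.ix_(~mask, mask)] += w
        return pd.DataFrame(D, index=self.ordering, columns=self.ordering)

    def to_nexus(self, path) -> None:
        """Write a SplitsTree-compatible NEXUS SPLITS block."""
        n = len(self.ordering)
        idx = {t: k + 1 for k, t in enumerate(self.ordering)}
        with open(path, "w") as fh:
            fh.write("#nexus\n\nBEGIN Taxa;\n")
            fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
            for k, t in enumerate(self.ordering, 1):
                fh.write(f"[{k}] '{t}'\n")
            fh.write(";\nEND;\n\nBEGIN Splits;\n")
            fh.write(f"DIMENSIONS ntax={n} nsplits={len(self.splits)};\n")
            fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
            fh.write(
                "CYCLE " + " ".join(str(idx[t]) for t in self.ordering) + ";\n"
            )
            fh.write("MATRIX\n")
            for side, w in self.splits:
                members = " ".join(str(idx[t]) for t in sorted(side, key=idx.get))
                fh.write(f"\t{w:.10g}\t {members},\n")
            fh.write(";\nEND;\n")


def _avg(d: np.ndarray, A: list[int], B: list[int]) -> float:
    return float(np.mean([d[x, y] for x in A for y in B]))


def _select_clusters(d: np.ndarray, clusters: list[list[int]]) -> tuple[int, int]:
    m = len(clusters)
    cd = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            cd[a, b] = cd[b, a] = _avg(d, clusters[a], clusters[b])
    r = cd.sum(axis=1)
    Q = (m - 2) * cd - r[:, None] - r[None, :]
    np.fill_diagonal(Q, np.inf)
    best = np.unravel_index(np.argmin(Q), Q.shape)
    return (min(best), max(best))


def _select_nodes(
    d: np.ndarray, clusters: list[list[int]], a: int, b: int
) -> tuple[int, int]:
    """Pick the nodes of clusters a, b to join, by the NJ criterion applied to
    the other clusters (as units) plus the members of a and b (as nodes)."""
    A, B = clusters[a], clusters[b]
    if len(A) == 1 and len(B) == 1:
        return A[0], B[0]
    others = [clusters[c] for c in range(len(clusters)) if c not in (a, b)]
    units = others + [[x] for x in A + B]
    mhat = len(units)

    def rsum(x: int) -> float:
        return sum(_avg(d, [x], u) for u in units if u != [x])

    best, best_pair = np.inf, None
    for x in A:
        rx = rsum(x)
        for y in B:
            q = (mhat - 2) * d[x, y] - rx - rsum(y)
            if q < best - 1e-12 or (
                abs(q - best) <= 1e-12 and (x, y) < best_pair
            ):
                best, best_pair = q, (x, y)
    return best_pair


def _nn_ordering(D: np.ndarray) -> list[int]:
    """Circular ordering of taxa 0..n-1 by NeighborNet agglomeration."""
    n = D.shape[0]
    if n <= 3:
        return list(range(n))
    cap = 3 * n + 8
    d = np.zeros((cap, cap))
    d[:n, :n] = D
    nxt = n
    clusters: list[list[int]] = [[i] for i in range(n)]
    stack: list[tuple[int, int, int, int, int]] = []

    def reduce_path(path: list[int]) -> list[int]:
        nonlocal nxt
        while len(path) > 2:
            p1, p2, p3 = path[0], path[1], path[2]
            u, v = nxt, nxt + 1
            nxt += 2
            active = [w for cl in clusters for w in cl] + path[3:]
            for w in active:
                if w in (p1, p2, p3):
                    continue
                d[u, w] = d[w, u] = (2 * d[p1, w] + d[p2, w]) / 3.0
                d[v, w] = d[w, v] = (d[p2, w] + 2 * d[p3, w]) / 3.0
            d[u, v] = d[v, u] = (d[p1, p2] + d[p2, p3] + d[p1, p3]) / 3.0
            stack.append((u, v, p1, p2, p3))
            path = [u, v] + path[3:]
        return path

    while len(clusters) > 3:
        a, b = _select_clusters(d, clusters)
        x, y = _select_nodes(d, clusters, a, b)
        pa, pb = clusters[a], clusters[b]
        if len(pa) == 2 and pa[0] == x:
            pa = pa[::-1]  # x must sit at the junction end of A
        if len(pb) == 2 and pb[1] == y:
            pb = pb[::-1]  # y must sit at the junction start of B
        merged = pa + pb
        clusters = [clusters[c] for c in range(len(clusters)) if c not in (a, b)]
        clusters.append(reduce_path(merged))

    # close the remaining <=3 paths into the cheapest cycle
    first, rest = clusters[0], clusters[1:]
    best_cost, cycle = np.inf, None
    for perm in itertools.permutations(range(len(rest))):
        for flips in itertools.product((False, True), repeat=len(rest) + 1):
            parts = [first[::-1] if flips[0] else first]
            for k, ci in enumerate(perm):
                parts.append(rest[ci][::-1] if flips[k + 1] else rest[ci])
            cand = [w for part in parts for w in part]
            cost = sum(d[cand[k], cand[(k + 1) % len(cand)]] for k in range(len(cand)))
            if cost < best_cost - 1e-12:
                best_cost, cycle = cost, cand

    # expand the reductions in reverse to recover the original taxa
    for u, v, p1, p2, p3 in reversed(stack):
        i = cycle.index(u)
        m = len(cycle)
        if cycle[(i + 1) % m] == v:
            seg = [p1, p2, p3]
            j = i
        elif cycle[(i - 1) % m] == v:
            seg = [p3, p2, p1]
            j = (i - 1) % m
        else:  # pragma: no cover - adjacency is guaranteed by construction
            raise AssertionError("reduced nodes not adjacent in cycle")
        if j + 1 < m:
            cycle = cycle[:j] + seg + cycle[j + 2 :]
        else:  # pair wraps around the end of the list
            cycle = seg[1:] + cycle[1:j] + [seg[0]]
    assert sorted(cycle) == list(range(n))
    return cycle


def _circular_splits(n: int):
    """Interval splits of positions 1..n-1 (never containing position 0)."""
    return [(i, j) for i in range(1, n) for j in range(i, n)]


def neighbornet(distance, epsilon: float = 1e-10) -> SplitSystem:
    """Compute a NeighborNet split system from a distance matrix."""
    df = pd.DataFrame(distance)
    labels = [str(x) for x in df.index]
    n = len(labels)
    if n < 4:
        raise ValueError("NeighborNet needs at least 4 taxa")
    D = df.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    order = _nn_ordering(D)
    ordered_labels = [labels[k] for k in order]
    Dp = D[np.ix_(order, order)]

    splits = _circular_splits(n)
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    A = np.zeros((len(pairs), len(splits)))
    for s, (i, j) in enumerate(splits):
        for r, (p, q) in enumerate(pairs):
            A[r, s] = (i <= p <= j) != (i <= q <= j)
    y = np.array([Dp[p, q] for p, q in pairs])
    w, _ = nnls(A, y)

    out = []
    for s, (i, j) in enumerate(splits):
        if w[s] >= epsilon:
            out.append((frozenset(ordered_labels[i : j + 1]), float(w[s])))
    return SplitSystem(ordered_labels, out)
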