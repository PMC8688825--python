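"""The repeatomic-fingerprint transform.

Per-cluster species-pair similarity matrices (edge counts or obs/exp ratios)
are converted to dissimilarities by d = 1/(v + 1) — the +1 guards the cells
where two species share a cluster but no direct edges — and summed over all
retained clusters into a master matrix.  The master matrix is then used in
two roles: square-rooted as a distance for principal coordinate analysis, and
as a species x variables data table from which Gower distances (range
normalized Manhattan) are computed for trees and networks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .archive import ClusterRecord
from .matrices import MasterMatrix, PairMatrix

__all__ = [
    "to_dissimilarity",
    "sum_master",
    "subset_by_annotation",
    "pcoa_distance",
    "gower_distance",
]

logger = logging.getLogger(__name__)


def to_dissimilarity(matrix: PairMatrix) -> PairMatrix:
    """Invert a similarity matrix cellwise: v -> 1/(v + 1).

    Strictly decreasing in v, with range (0, 1]: zero similarity maps to
    dissimilarity 1.  NA cells must be filtered out (or imputed) first.
    """
    vals = matrix.to_numpy()
    if np.isnan(vals).any():
        raise ValueError(
            "matrix contains NA cells; filter or impute before inversion"
        )
    return PairMatrix(1.0 / (vals + 1.0), matrix.kind, species=matrix.species)


def sum_master(dissims: list[PairMatrix], kind: str) -> MasterMatrix:
    """Sum per-cluster dissimilarity matrices cellwise into a master matrix.

    Cell sums are computed over value-sorted addends, so the result is
    independent of cluster order to the last ulp.
    """
    if not dissims:
        raise ValueError("no matrices to sum")
    species = dissims[0].species
    for m in dissims[1:]:
        if m.species != species:
            raise ValueError("all matrices must share the same species set")
    stack = np.stack([m.to_numpy() for m in dissims])
    if np.isnan(stack).any():
        raise ValueError("NA cells encountered; filter or impute first")
    total = np.sum(np.sort(stack, axis=0), axis=0)
    return MasterMatrix(total, kind, n_clusters_summed=len(dissims), species=species)


def subset_by_annotation(
    records: list[ClusterRecord], label: str, min_hit: float = 0.01
) -> list[ClusterRecord]:
    """Clusters whose annotation proportion for ``label`` strictly exceeds min_hit."""
    if not any(label in r.annotations for r in records):
        logger.warning("no cluster carries annotation label %r", label)
        return []
    return [r for r in records if r.annotations.get(label, 0.0) > min_hit]


def pcoa_distance(master: MasterMatrix) -> pd.DataFrame:
    """Cast a master matrix into the distance role for PCoA.

    Off-diagonal cells are square-rooted; the diagonal is forced to zero
    (whatever intra-species signal it carried stays in the Gower role).
    """
    vals = np.sqrt(master.to_numpy())
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=master.species, columns=master.species)


def gower_distance(table) -> pd.DataFrame:
    """Gower distance over a numeric variable table (rows = species).

    d(i, j) = (1/p) * sum_k |x_ik - x_jk| / range_k over the p columns with
    positive range; zero-range columns are dropped from p.  For numeric data
    this is exactly the range-normalized Manhattan distance, with values in
    [0, 1].  A master matrix is accepted directly, its columns (including the
    diagonal cells) acting as the variables.
    """
    if isinstance(table, MasterMatrix):
        df = table.data
    else:
        df = pd.DataFrame(table)
    if df.shape[0] < 2:
        raise ValueError("need at least two species")
    X = df.to_numpy(dtype=float)
    rng = X.max(axis=0) - X.min(axis=0)
    varying = rng > 0
    if not varying.any():
        logger.warning("all columns constant; Gower distance is identically zero")
        D = np.zeros((X.shape[0], X.shape[0]))
    else:
        Xv = X[:, varying] / rng[varying]
        D = np.abs(Xv[:, None, :] - Xv[None, :, :]).sum(axis=2) / varying.sum()
    return pd.DataFrame(D, index=df.index, columns=df.index)
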