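"""Species-pair matrix containers.

Two kinds of square, symmetric, species-labeled tables flow through the
pipeline:

* per-cluster :class:`PairMatrix` objects — raw similarity-edge counts
  (``kind="edges"``) or observed/expected edge ratios (``kind="obs_exp"``,
  where cells may be NA when the expectation is zero);
* :class:`MasterMatrix` objects — the cluster-wise sums of the inverted
  per-cluster matrices, i.e. the "repeatomic fingerprint" distance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PairMatrix", "MasterMatrix"]

_PAIR_KINDS = ("edges", "obs_exp")
_MASTER_KINDS = ("obs", "edges")


def _as_square_frame(data, species) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.astype(float)
        if species is not None:
            df = df.loc[list(species), list(species)]
    else:
        arr = np.asarray(data, dtype=float)
        if species is None:
            raise ValueError("species labels required for array input")
        df = pd.DataFrame(arr, index=list(species), columns=list(species))
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError("matrix must be square with identical row/column labels")
    return df


@dataclass
class PairMatrix:
    """Symmetric species x species table for one cluster.

    ``kind="edges"`` cells are non-negative integer edge counts; NA is not
    allowed.  ``kind="obs_exp"`` cells are observed/expected edge ratios and
    may be NA (``numpy.nan``) where the expectation is zero (a species absent
    from the cluster, or — degenerately — present but with no incident
    edges).
    """

    data: pd.DataFrame
    kind: str
    species: list = field(init=False)

    def __init__(self, data, kind, species=None):
        if kind not in _PAIR_KINDS:
            raise ValueError(f"kind must be one of {_PAIR_KINDS}, got {kind!r}")
        df = _as_square_frame(data, species)
        vals = df.to_numpy()
        na = np.isnan(vals)
        if kind == "edges":
            if na.any():
                raise ValueError("edges matrices must not contain NA cells")
            if (vals < 0).any():
                raise ValueError("edge counts must be non-negative")
        ok = ~(na | na.T)
        if not np.allclose(vals[ok & ~np.eye(len(df), dtype=bool)],
                           vals.T[ok & ~np.eye(len(df), dtype=bool)],
                           equal_nan=True):
            raise ValueError("pair matrix must be symmetric")
        if not (na == na.T).all():
            raise ValueError("NA pattern must be symmetric")
        self.data = df
        self.kind = kind
        self.species = list(df.index)

    @property
    def has_na(self) -> bool:
        return bool(np.isnan(self.data.to_numpy()).any())

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, PairMatrix):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.species == other.species
            and np.array_equal(self.to_numpy(), other.to_numpy(), equal_nan=True)
        )


@dataclass
class MasterMatrix:
    """Summed per-cluster dissimilarities: the repeatomic fingerprint.

    Dense (no NA) symmetric species x species matrix.  The diagonal carries
    the summed intra-species terms and is retained as data; it is only forced
    to zero when the matrix is cast into a distance role (see
    :func:`repeatfp.fingerprint.pcoa_distance`).
    """

    data: pd.DataFrame
    kind: str
    n_clusters_summed: int
    subset_label: str | None = None

    def __init__(self, data, kind, n_clusters_summed, subset_label=None, species=None):
        if kind not in _MASTER_KINDS:
            raise ValueError(f"kind must be one of {_MASTER_KINDS}, got {kind!r}")
        if n_clusters_summed < 1:
            raise ValueError("a master matrix sums at least one cluster")
        df = _as_square_frame(data, species)
        vals = df.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("master matrices must be dense (no NA)")
        if not np.allclose(vals, vals.T):
            raise ValueError("master matrix must be symmetric")
        self.data = df
        self.kind = kind
        self.n_clusters_summed = int(n_clusters_summed)
        self.subset_label = subset_label

    @property
    def species(self) -> list:
        return list(self.data.index)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        """Write as a PHYLIP square distance matrix (labels padded to 10)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.species)}\n")
            for sp, row in self.data.iterrows():
                label = str(sp)[:10].ljust(10)
                fh.write(label + " ".join(f"{v:.10g}" for v in row) + "\n")
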