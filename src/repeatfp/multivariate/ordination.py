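"""Principal coordinate analysis (classical metric scaling)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OrdinationResult", "pcoa"]


@dataclass
class OrdinationResult:
    """PCoA output: coordinates on the positive axes, all eigenvalues.

    ``eigenvalues`` holds the full spectrum in decreasing order — negative
    eigenvalues (non-Euclidean distances) are reported, not corrected.
    ``explained_fraction[k]`` is eigenvalue_k / sum of positive eigenvalues,
    for the positive axes only; those fractions sum to 1.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(distance) -> OrdinationResult:
    """Classical scaling of a symmetric, zero-diagonal distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  Axis signs are fixed by making
    each axis's largest-magnitude loading positive, so outputs are
    reproducible across runs and BLAS builds.
    """
    df = pd.DataFrame(distance)
    D = df.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(np.abs(evals).max(), 1.0) * 1e-10 if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]

    explained = evals[pos] / evals[pos].sum() if pos.any() else np.zeros(0)
    frame = pd.DataFrame(
        coords,
        index=df.index,
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return OrdinationResult(frame, evals, explained)
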