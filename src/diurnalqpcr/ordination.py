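"""Classical (Torgerson) metric multidimensional scaling of sample profiles.

Samples are embedded from their pairwise Euclidean distances over
quantile-normalized deltaCT profiles: squared distances are double-centered
(B = -1/2 J D^2 J), the Gram matrix is eigendecomposed, and coordinates are
the leading eigenvectors scaled by the square roots of their (positive)
eigenvalues — the construction R's ``cmdscale`` implements. Eigenvector
signs are arbitrary, so each coordinate column is flipped to make its
largest-magnitude entry positive, giving platform-reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix

GENE_POLICIES = ("complete_genes", "pairwise_complete")


@dataclass
class MdsResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # full spectrum, descending
    deficient_rank: bool = False  # fewer positive eigenvalues than requested k

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"dim{i + 1}" for i in range(k)],
        )


def sample_distances(
    norm: NormalizedMatrix, gene_policy: str = "complete_genes"
) -> tuple[np.ndarray, list[str]]:
    """Euclidean sample-sample distances over deltaCT profiles.

    ``complete_genes`` drops every gene with any missing value first;
    ``pairwise_complete`` computes each pair's distance over their shared
    non-missing genes, rescaled by sqrt(G / G_shared) so distances stay
    comparable across pairs with different amounts of overlap.
    """
    if gene_policy not in GENE_POLICIES:
        raise ValueError(f"gene_policy must be one of {GENE_POLICIES}")
    X = norm.delta_ct
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for ordination")

    if gene_policy == "complete_genes":
        keep = np.isfinite(X).all(axis=1)
        if not keep.any():
            raise ValueError("complete_genes policy leaves no genes")
        Xc = X[keep]
        diff = Xc[:, :, None] - Xc[:, None, :]
        D = np.sqrt((diff**2).sum(axis=0))
    else:
        D = np.zeros((n_samples, n_samples))
        finite = np.isfinite(X)
        for i in range(n_samples):
            for j in range(i + 1, n_samples):
                shared = finite[:, i] & finite[:, j]
                g = int(shared.sum())
                if g == 0:
                    raise ValueError(
                        f"samples {norm.sample_ids[i]!r} and {norm.sample_ids[j]!r} share no genes"
                    )
                d2 = ((X[shared, i] - X[shared, j]) ** 2).sum()
                D[i, j] = D[j, i] = np.sqrt(d2 * n_genes / g)
    return D, list(norm.sample_ids)


def classical_mds(D: np.ndarray, k: int = 3, sample_ids: Sequence[str] | None = None) -> MdsResult:
    """Torgerson scaling of a symmetric zero-diagonal distance matrix.

    Negative eigenvalues (non-Euclidean distances) contribute no coordinate;
    if fewer than ``k`` eigenvalues are positive, the remaining columns are
    zero-padded and the result is flagged rank-deficient.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-10) or np.any(D < -1e-12):
        raise ValueError("distance matrix must be nonnegative with zero diagonal")
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2  # enforce symmetry against round-off
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    n_pos = int((eigvals > 1e-9 * max(abs(eigvals[0]), 1.0)).sum())
    k_eff = min(k, n_pos)
    coords = np.zeros((n, k))
    for i in range(k_eff):
        v = eigvecs[:, i] * np.sqrt(eigvals[i])
        # deterministic sign: largest-|entry| coordinate is positive
        pivot = np.argmax(np.abs(v))
        if v[pivot] < 0:
            v = -v
        coords[:, i] = v
    return MdsResult(list(sample_ids), coords, eigvals, deficient_rank=k_eff < k)
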