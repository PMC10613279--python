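"""Spectral clustering on a precomputed distance matrix.

Standard Ng-Jordan-Weiss construction: Gaussian affinity with a median
heuristic bandwidth, symmetric normalised Laplacian, row-normalised
eigenvector embedding, and a k-means completion with many restarts.  A 2-D
variant of the same embedding serves for visual inspection of separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .distance import DistanceMatrix


def affinity_from_distance(D: DistanceMatrix | np.ndarray,
                           scale_rule: str | float = "local",
                           local_kappa: int = 7) -> np.ndarray:
    """Gaussian affinity with unit diagonal.

    ``scale_rule`` selects the bandwidth:

    * ``"local"`` (default) — per-sample scales, ``A_ij = exp(-D_ij^2 /
      (sigma_i sigma_j))`` with ``sigma_i`` the distance to sample i's
      ``local_kappa``-th nearest neighbour (Zelnik-Manor/Perona).  Mixed-type
      questionnaire distances concentrate in a narrow band, and a single
      global bandwidth flattens the eigenstructure; local scales restore the
      contrast.
    * ``"median"`` — one global bandwidth, ``A_ij = exp(-D_ij^2 /
      (2 sigma^2))`` with sigma the median off-diagonal distance.
    * a positive float — fixed global bandwidth, same kernel as ``"median"``.
    """
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = Dv.shape[0]
    if isinstance(scale_rule, str) and scale_rule == "local":
        if local_kappa >= n:
            raise ValueError("local_kappa must be smaller than n")
        Dm = Dv.copy()
        np.fill_diagonal(Dm, np.inf)
        sigma_i = np.sort(Dm, axis=1)[:, local_kappa - 1]
        if (sigma_i <= 0).any():
            raise ValueError(
                "zero local scale (duplicated samples beyond local_kappa); "
                "supply a fixed bandwidth instead"
            )
        A = np.exp(-(Dv**2) / (sigma_i[:, None] * sigma_i[None, :]))
    else:
        if isinstance(scale_rule, str):
            if scale_rule != "median":
                raise ValueError(f"unknown affinity scale rule {scale_rule!r}")
            off = Dv[~np.eye(n, dtype=bool)]
            sigma = float(np.median(off)) if off.size else 0.0
            if sigma <= 0:
                raise ValueError(
                    "median off-diagonal distance is zero; degenerate input "
                    "(all samples identical) — supply a fixed bandwidth instead"
                )
        else:
            sigma = float(scale_rule)
            if sigma <= 0:
                raise ValueError("affinity bandwidth must be positive")
        A = np.exp(-(Dv**2) / (2.0 * sigma**2))
    np.fill_diagonal(A, 1.0)
    return 0.5 * (A + A.T)


def laplacian_eigs(A: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the symmetric normalised Laplacian.

    Returns the ``m + 1`` smallest eigenvalues and their eigenvectors
    (columns), i.e. the trivial eigenpair plus the m nontrivial ones, with the
    deterministic sign convention that each vector's first nonzero component
    is positive.
    """
    A = np.asarray(A, float)
    n = A.shape[0]
    deg = A.sum(axis=1)
    if (deg <= 0).any():
        bad = int(np.argmax(deg <= 0))
        raise ValueError(f"isolated vertex (zero degree) at sample index {bad}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    L = 0.5 * (L + L.T)
    m = min(m, n - 1)
    vals, vecs = eigh(L, subset_by_index=[0, m])
    for c in range(vecs.shape[1]):
        nz = np.flatnonzero(np.abs(vecs[:, c]) > 1e-12)
        if nz.size and vecs[nz[0], c] < 0:
            vecs[:, c] = -vecs[:, c]
    return vals, vecs


def spectral_embed(A: np.ndarray, m: int,
                   eigs: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """n x m embedding from the m smallest *nontrivial* Laplacian eigenvectors,
    rows normalised to unit length (zero rows left as zero)."""
    if eigs is None:
        vals, vecs = laplacian_eigs(A, m)
    else:
        vals, vecs = eigs
        if vecs.shape[1] < m + 1:
            raise ValueError("cached eigendecomposition too small for requested m")
    coords = vecs[:, 1:m + 1].copy()
    norms = np.linalg.norm(coords, axis=1)
    nz = norms > 0
    coords[nz] /= norms[nz, None]
    return coords


def cluster_embedding(coords: np.ndarray, k: int, seed: int,
                      restarts: int = 50) -> np.ndarray:
    """k-means (k-means++ init, many restarts) on the spectral coordinates."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**32))
    labels = km.fit_predict(coords)
    labels = _repair_empty(coords, labels, k)
    return labels.astype(int)


def _repair_empty(coords: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Guarantee k non-empty clusters by splitting the largest if needed."""
    labels = labels.copy()
    counts = np.bincount(labels, minlength=k)
    for empty in np.flatnonzero(counts == 0):
        big = int(np.argmax(counts))
        members = np.flatnonzero(labels == big)
        centre = coords[members].mean(axis=0)
        far = members[np.argmax(np.linalg.norm(coords[members] - centre, axis=1))]
        labels[far] = empty
        counts = np.bincount(labels, minlength=k)
    return labels


@dataclass
class ClusteringResult:
    """A partition with the embedding it was computed in."""

    labels: np.ndarray
    k: int
    embedding: np.ndarray = field(repr=False)      # space used for partitioning
    embedding_2d: np.ndarray | None = field(default=None, repr=False)
    eigenvalues: np.ndarray | None = None
    seed: int | None = None
    sample_ids: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0 or (self.k and self.labels.max(initial=0) >= self.k):
            raise ValueError("labels must lie in 0..k-1")
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)
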