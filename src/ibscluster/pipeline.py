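"""The end-to-end clustering chain shared by fitting, model selection and
stability analysis: mixed-type distances -> dependency weights -> Gaussian
affinity -> spectral embedding -> k-means partition."""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .distance import (DependencyWeights, DistanceMatrix, dependency_weights,
                       fit_distributions, pairwise_distance_matrix)
from .schema import MixedDataMatrix
from .spectral import (ClusteringResult, affinity_from_distance,
                       cluster_embedding, laplacian_eigs, spectral_embed)
from .validity import ValidityCurve, cvnn_curve, sdbw_curve, sdbw_index


def compute_distance(data: MixedDataMatrix, config: PipelineConfig
                     ) -> tuple[DistanceMatrix, DependencyWeights | None]:
    weights = dependency_weights(data, bins=config.nmi_bins) \
        if config.dependency_weights else None
    D = pairwise_distance_matrix(data, weights=weights)
    return D, weights


def cluster_pipeline(data: MixedDataMatrix, k: int, config: PipelineConfig,
                     D: DistanceMatrix | None = None,
                     seed: int | None = None) -> ClusteringResult:
    """Run the full chain at a fixed k."""
    if D is None:
        D, _ = compute_distance(data, config)
    A = affinity_from_distance(D, config.affinity_scale_rule,
                               local_kappa=config.affinity_local_kappa)
    m = config.embedding_dim or k
    vals, vecs = laplacian_eigs(A, max(m, 2))
    coords = spectral_embed(A, m, eigs=(vals, vecs))
    coords2d = spectral_embed(A, 2, eigs=(vals, vecs))
    if seed is None:
        seed = config.seed_for(f"kmeans:k={k}")
    labels = cluster_embedding(coords, k, seed=seed,
                               restarts=config.kmeans_restarts)
    return ClusteringResult(labels=labels, k=k, embedding=coords,
                            embedding_2d=coords2d,
                            eigenvalues=vals[:m + 1], seed=seed,
                            sample_ids=list(data.sample_ids))


def select_k(data: MixedDataMatrix, config: PipelineConfig,
             D: DistanceMatrix | None = None
             ) -> tuple[ValidityCurve, ClusteringResult]:
    """Evaluate CVNN and S-Dbw over ``config.k_range``; the chosen k is the
    CVNN argmin (ties toward smaller k), with both argmins reported."""
    if not config.k_range:
        raise ValueError("k_range is empty")
    if D is None:
        D, _ = compute_distance(data, config)
    A = affinity_from_distance(D, config.affinity_scale_rule,
                               local_kappa=config.affinity_local_kappa)
    kmax = max(config.k_range)
    m_top = config.embedding_dim or kmax
    vals, vecs = laplacian_eigs(A, max(m_top, 2))

    labelings: dict[int, np.ndarray] = {}
    results: dict[int, ClusteringResult] = {}
    per_k_embed: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    coords2d = spectral_embed(A, 2, eigs=(vals, vecs))
    for k in sorted(config.k_range):
        m = config.embedding_dim or k
        coords = spectral_embed(A, m, eigs=(vals, vecs))
        seed = config.seed_for(f"kmeans:k={k}")
        labels = cluster_embedding(coords, k, seed=seed,
                                   restarts=config.kmeans_restarts)
        labelings[k] = labels
        per_k_embed[k] = (coords, labels)
        results[k] = ClusteringResult(labels=labels, k=k, embedding=coords,
                                      embedding_2d=coords2d,
                                      eigenvalues=vals[:m + 1], seed=seed,
                                      sample_ids=list(data.sample_ids))
    cv = cvnn_curve(D, labelings, kappa=config.knn_kappa)
    sd = sdbw_curve(per_k_embed)
    curve = ValidityCurve.from_curves(cv, sd)
    return curve, results[curve.chosen_k]
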