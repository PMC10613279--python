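"""Model/Results interface for mixed-type spectral subgroup discovery.

:class:`MixedSpectralClustering` is built from a :class:`~ibscluster.schema.
MixedDataMatrix` (or a labelled DataFrame plus schema) and a
:class:`~ibscluster.config.PipelineConfig`.  ``fit()`` runs the full chain --
mixed-type distances with dependency weighting, Gaussian affinity, spectral
embedding, k-means partition -- either at a fixed k or, when k is omitted,
with CVNN/S-Dbw model selection over the configured candidate range.  The
returned :class:`ClusteringResults` carries the partition, embedding and
validity curves, and exposes the downstream analyses: subsampling stability,
leave-one-out classification, the nonparametric profiling battery and the
z-value radar profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .distance import DependencyWeights, DistanceMatrix
from .pipeline import cluster_pipeline, compute_distance, select_k
from .profiling import (ClusterProfile, TestResults, cluster_z_profiles,
                        qualitative_labels, run_battery)
from .schema import MixedDataMatrix, VariableSchema
from .spectral import ClusteringResult
from .stability import (LOOReport, StabilityReport, loo_classification,
                        stability_analysis)
from .validity import ValidityCurve


class MixedSpectralClustering:
    """Spectral clustering model for a mixed-type questionnaire cohort.

    Parameters
    ----------
    data : MixedDataMatrix
        Validated n x p cohort.
    config : PipelineConfig, optional
        Pipeline knobs; defaults follow the study design.

    Examples
    --------
    >>> model = MixedSpectralClustering(data)
    >>> res = model.fit()            # CVNN/S-Dbw selection over k_range
    >>> res9 = model.fit(k=9)        # fixed k
    >>> print(res.summary())
    """

    def __init__(self, data: MixedDataMatrix,
                 config: PipelineConfig | None = None, **config_kwargs):
        if not isinstance(data, MixedDataMatrix):
            raise TypeError("data must be a MixedDataMatrix; see from_dataframe")
        self.data = data
        if config is None:
            config = PipelineConfig(**config_kwargs)
        elif config_kwargs:
            raise ValueError("pass either a config object or keyword overrides")
        self.config = config
        self._distance: DistanceMatrix | None = None
        self._weights: DependencyWeights | None = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       schema: Sequence[VariableSchema],
                       config: PipelineConfig | None = None,
                       on_missing: str = "error",
                       **config_kwargs) -> "MixedSpectralClustering":
        """Build from a table of raw labels/values plus a variable schema."""
        data = MixedDataMatrix.from_labeled(frame, schema, on_missing=on_missing)
        return cls(data, config=config, **config_kwargs)

    # -- lazily shared distance --------------------------------------------
    @property
    def distance(self) -> DistanceMatrix:
        if self._distance is None:
            self._distance, self._weights = compute_distance(self.data, self.config)
        return self._distance

    @property
    def dependency_weights(self) -> DependencyWeights | None:
        self.distance  # noqa: B018 - force computation
        return self._weights

    # -- fitting ------------------------------------------------------------
    def fit(self, k: int | None = None) -> "ClusteringResults":
        """Cluster at fixed ``k``, or select k by CVNN/S-Dbw when omitted."""
        if k is None:
            curve, result = select_k(self.data, self.config, D=self.distance)
        else:
            curve = None
            result = cluster_pipeline(self.data, int(k), self.config,
                                      D=self.distance)
        return ClusteringResults(model=self, clustering=result,
                                 validity=curve)


@dataclass
class ClusteringResults:
    """Fitted partition plus the analyses that characterise it."""

    model: MixedSpectralClustering
    clustering: ClusteringResult
    validity: ValidityCurve | None = None
    _profile: ClusterProfile | None = field(default=None, repr=False)
    _tests: TestResults | None = field(default=None, repr=False)

    # -- basic accessors ----------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self.clustering.labels

    @property
    def k(self) -> int:
        return self.clustering.k

    @property
    def embedding_2d(self) -> np.ndarray:
        return self.clustering.embedding_2d

    @property
    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.clustering.cluster_sizes,
                         index=pd.RangeIndex(self.k, name="cluster"), name="n")

    # -- downstream analyses ------------------------------------------------
    def stability(self, rates: Sequence[float] | None = None,
                  iterations: int | None = None) -> StabilityReport:
        """Subsampling stability (Hungarian-matched accuracy vs this fit)."""
        config = self.model.config
        if rates is not None or iterations is not None:
            d = config.to_dict()
            if rates is not None:
                d["subsample_rates"] = tuple(rates)
            if iterations is not None:
                d["subsample_iterations"] = int(iterations)
            config = PipelineConfig.from_dict(d)
        return stability_analysis(self.model.data, self.k, config,
                                  reference_labels=self.labels)

    def loo_classification(self) -> LOOReport:
        """Leave-one-out SVM prediction of the assigned cluster labels."""
        return loo_classification(self.model.data, self.labels,
                                  self.model.config)

    def tests(self) -> TestResults:
        """Kruskal-Wallis/eps2, Conover-Holm, one-vs-rest MWU/Cliff's delta."""
        if self._tests is None:
            self._tests = run_battery(self.model.data, self.labels)
        return self._tests

    def profile(self) -> ClusterProfile:
        """z-value profiles with qualitative high/moderate/low calls."""
        if self._profile is None:
            prof = cluster_z_profiles(self.model.data, self.labels)
            qualitative_labels(prof, self.tests())
            self._profile = prof
        return self._profile

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = []
        lines.append("Mixed-type spectral clustering")
        lines.append("=" * 46)
        lines.append(f"samples: {len(self.labels):>6d}   "
                     f"variables: {self.model.data.n_variables}")
        lines.append(f"clusters (k): {self.k}")
        if self.validity is not None:
            lines.append(f"selected over k = {min(self.validity.table.index)}.."
                         f"{max(self.validity.table.index)}  "
                         f"(CVNN argmin {self.validity.cvnn_argmin}, "
                         f"S-Dbw argmin {self.validity.sdbw_argmin})")
        sizes = " ".join(f"{c}:{n}" for c, n in self.cluster_sizes.items())
        lines.append(f"cluster sizes: {sizes}")
        if self._profile is not None:
            highs = (self._profile.qualitative == "high").sum(axis=1)
            lines.append("high-call variables per cluster: "
                         + " ".join(f"{c}:{n}" for c, n in highs.items()))
        return "\n".join(lines)

    def plot_embedding(self, ax=None):
        """Scatter of the 2-D spectral embedding coloured by cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        emb = self.embedding_2d
        sc = ax.scatter(emb[:, 0], emb[:, 1], c=self.labels, s=8, cmap="tab10")
        ax.set_xlabel("spectral dim 1")
        ax.set_ylabel("spectral dim 2")
        ax.figure.colorbar(sc, ax=ax, label="cluster")
        return ax

    def save(self, out_dir) -> dict:
        """Write labels, embedding, validity curve (if any) and profiles."""
        from .artifacts import save_artifacts

        items: list = [self.clustering]
        if self.validity is not None:
            items.append(self.validity)
        if self._tests is not None:
            items.append(self._tests)
        if self._profile is not None:
            items.append(self._profile)
        return save_artifacts(items, out_dir)
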