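"""Pipeline configuration and reproducible per-stage seeding.

All randomness in the package flows from a single master seed.  Each stochastic
stage (cohort generation, k-means partitioning, subsampling, ...) derives its
own seed by hashing the stage name together with the master seed, so any stage
can be re-run in isolation and still reproduce the full-pipeline behaviour.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic 31-bit seed for a named stage."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Knobs for the clustering pipeline.

    Defaults follow the study design: candidate k = 2..14, CVNN neighbour
    count kappa = 10, subsampling at 90-98% with 10 iterations per rate.
    """

    k_range: tuple[int, ...] = tuple(range(2, 15))
    knn_kappa: int = 10
    subsample_rates: tuple[float, ...] = (0.90, 0.92, 0.94, 0.96, 0.98)
    subsample_iterations: int = 10
    master_seed: int = 988
    affinity_scale_rule: str | float = "local"
    affinity_local_kappa: int = 7
    tie_break_rule: str = "smaller_k"
    dependency_weights: bool = True
    nmi_bins: int = 4
    kmeans_restarts: int = 50
    embedding_dim: int | None = None  # None -> m = k
    svm_c: float = 10.0
    svm_gamma: str | float = "scale"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        if any(k < 2 for k in self.k_range):
            raise ValueError("k_range values must be >= 2")
        if any(not (0.0 < r < 1.0) for r in self.subsample_rates):
            raise ValueError("subsample rates must lie in (0, 1)")
        if self.subsample_iterations < 1:
            raise ValueError("subsample_iterations must be >= 1")
        if self.knn_kappa < 1:
            raise ValueError("knn_kappa must be >= 1")

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("k_range", "subsample_rates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
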