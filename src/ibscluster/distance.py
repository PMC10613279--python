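"""Unified mixed-type distance with data-driven dependency weighting.

The metric follows two principles: (i) each variable's contribution is shaped
by its own empirical distribution and measurement kind, and (ii) variables
that carry redundant information (high mutual dependency with the rest of the
battery) are up-weighted so that shared symptom axes dominate the geometry.

Per-variable distances, all on [0, 1]:

* ordinal   ``d(a, b) = |F(a) - F(b)| / (F(L-1) - F(0))`` where ``F`` is the
  empirical CDF over the declared level order; the extreme *observed*
  categories are therefore at distance 1.  A constant variable has d = 0.
* nominal   simple mismatch, ``d = [a != b]``.
* continuous ``d(a, b) = |a - b| / (max - min)`` using the *schema* range, so
  distances do not drift when the data are subsampled.

Dependency weights: every variable is discretised (continuous variables into
equal-frequency bins), pairwise normalised mutual information
``NMI(j, l) = I(j; l) / sqrt(H(j) H(l))`` is computed, and variable j gets
weight ``w_j = 1 + mean_{l != j} NMI(j, l)``, rescaled to mean 1.  The sample
distance is the w-weighted mean of per-variable distances, hence again in
[0, 1] with zero diagonal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy
from sklearn.metrics import mutual_info_score

from .schema import MixedDataMatrix, SchemaError, VariableSchema


@dataclass
class VariableDistribution:
    """Empirical distribution summary of one variable."""

    code: str
    kind: str
    frequencies: np.ndarray | None = None  # ordinal/nominal, over declared levels
    cdf: np.ndarray | None = None          # ordinal only
    schema_range: tuple[float, float] | None = None
    observed_range: tuple[float, float] | None = None
    degenerate: bool = False


def fit_distributions(data: MixedDataMatrix) -> list[VariableDistribution]:
    """One :class:`VariableDistribution` per variable, in schema order."""
    if data.n_samples == 0:
        raise ValueError("cannot fit distributions on an empty matrix")
    out = []
    for v in data.schema:
        col = data.frame[v.code].to_numpy()
        if v.kind == "continuous":
            out.append(
                VariableDistribution(
                    code=v.code,
                    kind=v.kind,
                    schema_range=v.range,
                    observed_range=(float(col.min()), float(col.max())),
                    degenerate=bool(col.min() == col.max()),
                )
            )
        else:
            counts = np.bincount(col.astype(int), minlength=v.n_levels).astype(float)
            freqs = counts / counts.sum()
            dist = VariableDistribution(
                code=v.code,
                kind=v.kind,
                frequencies=freqs,
                degenerate=bool((freqs > 0).sum() <= 1),
            )
            if v.kind == "ordinal":
                dist.cdf = np.cumsum(freqs)
            out.append(dist)
    return out


def per_variable_distance(a, b, dist: VariableDistribution,
                          schema: VariableSchema | None = None) -> float:
    """Distance between two raw internal values of a single variable."""
    if dist.kind == "continuous":
        lo, hi = dist.schema_range
        return abs(float(a) - float(b)) / (hi - lo)
    if dist.kind == "nominal":
        n_levels = len(dist.frequencies)
        for x in (a, b):
            if not (0 <= int(x) < n_levels):
                raise SchemaError(f"{dist.code}: invalid level code {x}")
        return 0.0 if int(a) == int(b) else 1.0
    # ordinal
    cdf = dist.cdf
    for x in (a, b):
        if not (0 <= int(x) < len(cdf)):
            raise SchemaError(f"{dist.code}: invalid level code {x}")
    denom = cdf[-1] - cdf[0]
    if denom <= 0:
        return 0.0
    return abs(cdf[int(a)] - cdf[int(b)]) / denom


@dataclass
class DependencyWeights:
    """Per-variable weights derived from pairwise normalised MI."""

    codes: list[str]
    weights: np.ndarray
    nmi: pd.DataFrame = field(repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.codes, name="weight")


def _discretize(data: MixedDataMatrix, bins: int) -> list[np.ndarray]:
    cols = []
    for v in data.schema:
        col = data.frame[v.code].to_numpy()
        if v.kind == "continuous":
            # equal-frequency bins; duplicate edges collapse for spiky data
            edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
            cols.append(np.searchsorted(edges, col, side="right"))
        else:
            cols.append(col.astype(int))
    return cols


def dependency_weights(data: MixedDataMatrix, bins: int = 4) -> DependencyWeights:
    """NMI-based variable weights; all ones when p < 2 or data degenerate."""
    if data.n_samples < 2:
        raise ValueError("need at least two samples for dependency weights")
    p = data.n_variables
    codes = data.codes
    if p < 2:
        nmi = pd.DataFrame(np.ones((p, p)), index=codes, columns=codes)
        return DependencyWeights(codes, np.ones(p), nmi)
    disc = _discretize(data, bins)
    H = np.array([_entropy(np.bincount(c).astype(float)) for c in disc])
    nmi = np.eye(p)
    for j in range(p):
        for l in range(j + 1, p):
            if H[j] <= 0 or H[l] <= 0:
                val = 0.0
            else:
                mi = mutual_info_score(disc[j], disc[l])
                val = mi / np.sqrt(H[j] * H[l])
            nmi[j, l] = nmi[l, j] = val
    for j in range(p):
        if H[j] <= 0:
            nmi[j, j] = 0.0  # degenerate variable: no information
    mean_off = (nmi.sum(axis=1) - np.diag(nmi)) / (p - 1)
    w = 1.0 + mean_off
    w = w / w.mean()
    return DependencyWeights(codes, w, pd.DataFrame(nmi, index=codes, columns=codes))


@dataclass
class DistanceMatrix:
    """Symmetric n x n dissimilarities on [0, 1] with provenance hash."""

    values: np.ndarray = field(repr=False)
    sample_ids: list = field(default_factory=list, repr=False)
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check(self, atol: float = 1e-10) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=atol):
            raise ValueError("distance matrix diagonal not zero")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("distances outside [0, 1]")


def pairwise_distance_matrix(data: MixedDataMatrix,
                             weights: DependencyWeights | None = None,
                             distributions: list[VariableDistribution] | None = None,
                             ) -> DistanceMatrix:
    """Weighted mean of per-variable distances for every sample pair.

    Ordinal and continuous variables reduce to 1-D transforms (normalised CDF
    values resp. range-scaled values), so their pairwise contribution is an
    absolute difference; nominal variables contribute 0/1 mismatches.
    """
    n, p = data.n_samples, data.n_variables
    dists = distributions if distributions is not None else fit_distributions(data)
    w = np.ones(p) if weights is None else np.asarray(weights.weights, dtype=float)
    if w.shape != (p,):
        raise ValueError("weights length must equal number of variables")
    if not np.all(np.isfinite(w)) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be finite, nonnegative, not all zero")

    total = np.zeros((n, n))
    for j, (v, dist) in enumerate(zip(data.schema, dists)):
        col = data.frame[v.code].to_numpy()
        if v.kind == "nominal":
            contrib = (col[:, None] != col[None, :]).astype(float)
        else:
            if v.kind == "continuous":
                lo, hi = v.range
                t = (col.astype(float) - lo) / (hi - lo)
            else:
                cdf = dist.cdf
                denom = cdf[-1] - cdf[0]
                t = cdf[col.astype(int)] / denom if denom > 0 else np.zeros(n)
            contrib = np.abs(t[:, None] - t[None, :])
        total += w[j] * contrib
    D = total / w.sum()
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # enforce exact symmetry against fp noise
    digest = hashlib.sha256(np.ascontiguousarray(D).tobytes()).hexdigest()[:16]
    return DistanceMatrix(values=D, sample_ids=list(data.sample_ids),
                          provenance=digest)
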