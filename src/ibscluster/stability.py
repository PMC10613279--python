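"""Subsampling stability and leave-one-out classification of the partition.

Stability: the cohort is subsampled without replacement at several rates, the
*entire* pipeline (distances and dependency weights re-fitted on the
subsample) is re-run at the same k, and each subsample partition is compared
with the full-data reference partition, restricted to the subsample, via
Hungarian-matched clustering accuracy.

Classification: a radial-kernel support-vector machine with fixed
hyperparameters predicts the assigned cluster from the standardised features,
scored by leave-one-out accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.svm import SVC

from .config import PipelineConfig
from .pipeline import cluster_pipeline, compute_distance
from .schema import MixedDataMatrix


def hungarian_accuracy(labels_a, labels_b) -> float:
    """Fraction of samples agreeing under the optimal one-to-one matching of
    cluster ids (optimal assignment on the contingency table)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    side = max(ka, kb)  # pad to square for unequal cluster counts
    cont = np.zeros((side, side))
    np.add.at(cont, (ai, bi), 1)
    rows, cols = linear_sum_assignment(cont, maximize=True)
    return float(cont[rows, cols].sum() / a.size)


@dataclass
class StabilityReport:
    """Per-(rate, iteration) clustering accuracies and their means."""

    table: pd.DataFrame = field(repr=False)  # columns rate, iteration, ca, n_sub
    k: int = 0

    @property
    def per_rate_means(self) -> pd.Series:
        return self.table.groupby("rate")["ca"].mean()

    @property
    def mean_ca(self) -> float:
        return float(self.table["ca"].mean())


def stability_analysis(data: MixedDataMatrix, k: int, config: PipelineConfig,
                       reference_labels: np.ndarray | None = None
                       ) -> StabilityReport:
    """Reference-vs-subsample stability of the full pipeline at fixed k."""
    n = data.n_samples
    if reference_labels is None:
        reference_labels = cluster_pipeline(data, k, config).labels
    reference_labels = np.asarray(reference_labels, int)
    rows = []
    for rate in config.subsample_rates:
        if not (0.0 < rate < 1.0):
            raise ValueError(f"subsample rate {rate} outside (0, 1)")
        for it in range(config.subsample_iterations):
            rng = np.random.default_rng(
                config.seed_for(f"stability:rate={rate:.4f}:iter={it}"))
            m = int(np.ceil(rate * n))
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = data.subset(idx)
            subD, _ = compute_distance(sub, config)
            res = cluster_pipeline(
                sub, k, config, D=subD,
                seed=config.seed_for(f"stability-kmeans:rate={rate:.4f}:iter={it}"))
            ca = hungarian_accuracy(reference_labels[idx], res.labels)
            rows.append({"rate": rate, "iteration": it, "ca": ca, "n_sub": m})
    return StabilityReport(table=pd.DataFrame(rows), k=k)


@dataclass
class LOOReport:
    """Leave-one-out classification accuracy and confusion table."""

    accuracy: float
    confusion: pd.DataFrame = field(repr=False)


def _standardized_features(data: MixedDataMatrix) -> np.ndarray:
    X = data.numeric().to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def loo_classification(data: MixedDataMatrix, labels, config: PipelineConfig
                       ) -> LOOReport:
    """Leave-one-out SVM (RBF kernel, fixed C and gamma) on standardised
    ordinal ranks and continuous scores."""
    y = np.asarray(labels, int)
    n = data.n_samples
    if y.shape[0] != n:
        raise ValueError("labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than 2 members")
    X = _standardized_features(data)
    gamma = config.svm_gamma
    if gamma == "scale":
        gamma = 1.0 / (X.shape[1] * X.var())
    # precompute the kernel once; each LOO fit slices it
    sq = (X**2).sum(axis=1)
    K = np.exp(-float(gamma) * (sq[:, None] + sq[None, :] - 2 * X @ X.T))
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = SVC(kernel="precomputed", C=config.svm_c)
        clf.fit(K[np.ix_(train, train)], y[train])
        preds[i] = clf.predict(K[i, train][None, :])[0]
    acc = float((preds == y).mean())
    conf = pd.crosstab(pd.Series(y, name="true"), pd.Series(preds, name="predicted"))
    conf = conf.reindex(index=classes, columns=classes, fill_value=0)
    return LOOReport(accuracy=acc, confusion=conf)
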