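"""Internal cluster validity indices: CVNN and S-Dbw.

Both indices balance separation against compactness and are minimised at the
best candidate number of clusters.

CVNN
    Sep(k) = max over clusters of the mean, over members, of the fraction of a
    member's kappa nearest neighbours lying outside its cluster.
    Comp(k) = sum over clusters of the mean pairwise intra-cluster distance.
    Each component is normalised by its maximum over the candidate set, and
    CVNN(k) is their sum (a zero maximum contributes 0).

S-Dbw (computed in the spectral embedding space used for partitioning)
    Scatt(k) = (1/k) sum_i ||var(C_i)|| / ||var(X)||
    Dens_bw(k) = mean over cluster pairs of the point density at the pair
    midpoint divided by the larger of the densities at the two centroids,
    where density counts points within a radius equal to the mean cluster
    standard-deviation norm.  A zero denominator contributes the worst case 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)


def _knn_indices(D: np.ndarray, kappa: int) -> np.ndarray:
    n = D.shape[0]
    if kappa >= n:
        raise ValueError(f"kappa={kappa} must be smaller than n={n}")
    Dm = D.copy()
    np.fill_diagonal(Dm, np.inf)
    part = np.argpartition(Dm, kappa - 1, axis=1)[:, :kappa]
    return part


def cvnn_components(D: DistanceMatrix | np.ndarray, labels: np.ndarray,
                    kappa: int, knn: np.ndarray | None = None
                    ) -> tuple[float, float]:
    """Raw (unnormalised) Sep and Comp for one labelling."""
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    labels = np.asarray(labels, int)
    if knn is None:
        knn = _knn_indices(Dv, kappa)
    outside = (labels[knn] != labels[:, None]).mean(axis=1)
    sep = 0.0
    comp = 0.0
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        sep = max(sep, float(outside[members].mean()))
        if members.size < 2:
            logger.debug("singleton cluster %d: compactness term 0", c)
            continue
        sub = Dv[np.ix_(members, members)]
        m = members.size
        comp += float(sub.sum() / (m * (m - 1)))
    return sep, comp


def cvnn_curve(D: DistanceMatrix | np.ndarray, labelings: dict[int, np.ndarray],
               kappa: int) -> pd.DataFrame:
    """CVNN over a candidate set; normalisation is across the set itself."""
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    knn = _knn_indices(Dv, kappa)
    ks = sorted(labelings)
    seps, comps = {}, {}
    for k in ks:
        seps[k], comps[k] = cvnn_components(Dv, labelings[k], kappa, knn=knn)
    max_sep = max(seps.values())
    max_comp = max(comps.values())
    rows = []
    for k in ks:
        val = (seps[k] / max_sep if max_sep > 0 else 0.0) + \
              (comps[k] / max_comp if max_comp > 0 else 0.0)
        rows.append({"k": k, "sep": seps[k], "comp": comps[k], "cvnn": val})
    return pd.DataFrame(rows).set_index("k")


def sdbw_index(coords: np.ndarray, labels: np.ndarray) -> float:
    """S-Dbw of one labelling in its embedding space."""
    X = np.asarray(coords, float)
    labels = np.asarray(labels, int)
    clusters = np.unique(labels)
    k = clusters.size
    total_var = X.var(axis=0)
    total_norm = np.linalg.norm(total_var)
    if total_norm <= 0:
        raise ValueError("zero total variance: degenerate embedding")
    member_idx = []
    centres = []
    var_norms = []
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"empty cluster {c}")
        member_idx.append(members)
        centres.append(X[members].mean(axis=0))
        var_norms.append(np.linalg.norm(X[members].var(axis=0)))
    scatt = float(np.mean(var_norms) / total_norm)
    if k == 1:
        return scatt
    radius = float(np.mean(np.sqrt(var_norms)))

    def density(point: np.ndarray, members: np.ndarray) -> int:
        d = np.linalg.norm(X[members] - point, axis=1)
        return int((d <= radius).sum())

    terms = []
    for i in range(k):
        for j in range(i + 1, k):
            union = np.concatenate([member_idx[i], member_idx[j]])
            mid = 0.5 * (centres[i] + centres[j])
            denom = max(density(centres[i], union), density(centres[j], union))
            if denom == 0:
                logger.debug("zero centre density for pair (%d, %d): worst case 1",
                             clusters[i], clusters[j])
                terms.append(1.0)
            else:
                terms.append(density(mid, union) / denom)
    return scatt + float(np.mean(terms))


def sdbw_curve(per_k: dict[int, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    rows = [{"k": k, "sdbw": sdbw_index(coords, labels)}
            for k, (coords, labels) in sorted(per_k.items())]
    return pd.DataFrame(rows).set_index("k")


@dataclass
class ValidityCurve:
    """CVNN and S-Dbw across candidate k, with the selected k."""

    table: pd.DataFrame = field(repr=False)  # index k, columns sep, comp, cvnn, sdbw
    chosen_k: int = 0
    cvnn_argmin: int = 0
    sdbw_argmin: int = 0

    @classmethod
    def from_curves(cls, cvnn: pd.DataFrame, sdbw: pd.DataFrame) -> "ValidityCurve":
        table = cvnn.join(sdbw)
        # ties within an index break toward smaller k (index is sorted)
        cv_arg = int(table["cvnn"].idxmin())
        sd_arg = int(table["sdbw"].idxmin())
        # CVNN is primary whether the two indices agree or not
        return cls(table=table, chosen_k=cv_arg, cvnn_argmin=cv_arg,
                   sdbw_argmin=sd_arg)
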