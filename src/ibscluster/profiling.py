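"""Cluster characterisation battery.

For every variable the battery runs, across the assigned clusters:

* Kruskal-Wallis H (tie-corrected) with the epsilon-squared effect size
  ``eps2 = H / (n - 1)``;
* Conover-Iman post-hoc pairwise comparisons on the pooled ranks with Holm
  step-down correction across the cluster pairs of that variable;
* one-vs-rest Mann-Whitney U (normal approximation, tie-corrected) with
  Cliff's delta, positive when the cluster exceeds the rest;
* z-value profiles: each cluster's variable mean standardised against the
  whole-population mean and SD (ordinal items enter via their integer ranks),
  the quantity drawn on the radar plots with 0.5 sigma circles;
* the qualitative high/moderate/low call per (cluster, variable):
  high if z > 0.5 or (one-vs-rest p < 0.001 and delta > 0.3); low if z <= 0;
  moderate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import MixedDataMatrix

RADAR_CIRCLES = (0.0, 0.5, 1.0, 1.5)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def kruskal_wallis_epsilon2(values, group_labels) -> tuple[float, float, float]:
    """Tie-corrected Kruskal-Wallis H, chi-square p, and epsilon-squared."""
    x = np.asarray(values, float)
    g = np.asarray(group_labels)
    groups = np.unique(g)
    if groups.size < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    n = x.size
    ranks = stats.rankdata(x)
    ssq = 0.0
    for grp in groups:
        r = ranks[g == grp]
        if r.size == 0:
            raise ValueError(f"empty group {grp!r}")
        ssq += r.sum() ** 2 / r.size
    H = 12.0 / (n * (n + 1)) * ssq - 3 * (n + 1)
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if tie_term <= 0:  # all values identical
        H = 0.0
    else:
        H /= tie_term
    H = max(H, 0.0)
    p = float(stats.chi2.sf(H, groups.size - 1))
    eps2 = H / (n - 1) if n > 1 else 0.0
    return float(H), p, float(eps2)


def conover_posthoc_holm(values, group_labels) -> pd.DataFrame:
    """Conover-Iman pairwise t statistics on ranks with Holm-adjusted p.

    Uses the pooled tie-corrected rank variance S^2 and the
    ``(n - 1 - H) / (n - k)`` multiplier; two-sided p from Student's t with
    ``n - k`` degrees of freedom, Holm step-down across all pairs.
    """
    x = np.asarray(values, float)
    g = np.asarray(group_labels)
    groups = np.unique(g)
    k = groups.size
    n = x.size
    H, _, _ = kruskal_wallis_epsilon2(x, g)
    ranks = stats.rankdata(x)
    S2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    factor = S2 * (n - 1 - H) / (n - k)
    means = {grp: ranks[g == grp].mean() for grp in groups}
    sizes = {grp: int((g == grp).sum()) for grp in groups}
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = np.sqrt(factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
            t = (means[a] - means[b]) / se if se > 0 else 0.0
            p = 2.0 * float(stats.t.sf(abs(t), n - k)) if se > 0 else 1.0
            rows.append({"group_a": a, "group_b": b, "statistic": float(t),
                         "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment with the running-maximum convention."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def cliffs_delta(a, b) -> float:
    """Dominance effect size via rank arithmetic; positive when a exceeds b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra = ranks[:na].sum()
    # U1 = #{a>b} + 0.5 #{a=b}; delta = 2 U1/(na nb) - 1 = (#> - #<)/(na nb)
    u1 = ra - na * (na + 1) / 2.0
    return float(2.0 * u1 / (na * nb) - 1.0)


def mwu_cliffs_one_vs_rest(values, cluster_labels) -> pd.DataFrame:
    """Mann-Whitney U and Cliff's delta for each cluster against the rest."""
    x = np.asarray(values, float)
    g = np.asarray(cluster_labels)
    clusters = np.unique(g)
    if clusters.size < 2:
        raise ValueError("one-vs-rest needs at least two clusters")
    rows = []
    for c in clusters:
        mask = g == c
        a, b = x[mask], x[~mask]
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        rows.append({"cluster": c, "U": float(res.statistic),
                     "p": float(res.pvalue), "delta": cliffs_delta(a, b)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterProfile:
    """k x p z-values, qualitative calls, and the population scale used."""

    z: pd.DataFrame = field(repr=False)            # index cluster, columns codes
    qualitative: pd.DataFrame = field(repr=False)  # same shape, {high,moderate,low}
    population_mean: pd.Series = field(repr=False)
    population_sd: pd.Series = field(repr=False)
    cluster_sizes: pd.Series = field(repr=False)


@dataclass
class TestResults:
    """The full battery for one clustering."""

    __test__ = False  # not a pytest class

    kruskal: pd.DataFrame = field(repr=False)     # per variable: H, p, eps2
    conover: pd.DataFrame = field(repr=False)     # per variable x pair
    one_vs_rest: pd.DataFrame = field(repr=False)  # per variable x cluster


def cluster_z_profiles(data: MixedDataMatrix, labels) -> ClusterProfile:
    """z(c, j) = (cluster mean - population mean) / population SD.

    Qualitative calls are filled in by :func:`qualitative_labels`; here they
    start as the z-only rule (no test results yet).
    """
    y = np.asarray(labels, int)
    if y.shape[0] != data.n_samples:
        raise ValueError("labels length mismatch")
    X = data.numeric()
    clusters = np.unique(y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    rows = {}
    sizes = {}
    for c in clusters:
        members = X.iloc[y == c]
        if len(members) == 0:
            raise ValueError(f"empty cluster {c}")
        sizes[c] = len(members)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[c] = ((members.mean(axis=0) - mu) / sd).where(sd > 0, np.nan)
    z = pd.DataFrame(rows).T
    z.index.name = "cluster"
    qual = z.map(lambda v: "high" if v > 0.5 else ("low" if v <= 0 else "moderate"))
    return ClusterProfile(z=z, qualitative=qual, population_mean=mu,
                          population_sd=sd,
                          cluster_sizes=pd.Series(sizes, name="n"))


def run_battery(data: MixedDataMatrix, labels) -> TestResults:
    """Run KW + eps2, Conover-Holm, and one-vs-rest MWU + delta per variable."""
    y = np.asarray(labels, int)
    kw_rows, con_frames, ovr_frames = [], [], []
    for v in data.schema:
        x = data.frame[v.code].to_numpy(float)
        H, p, eps2 = kruskal_wallis_epsilon2(x, y)
        kw_rows.append({"code": v.code, "H": H, "p": p, "eps2": eps2})
        con = conover_posthoc_holm(x, y)
        con.insert(0, "code", v.code)
        con_frames.append(con)
        ovr = mwu_cliffs_one_vs_rest(x, y)
        ovr.insert(0, "code", v.code)
        ovr_frames.append(ovr)
    return TestResults(
        kruskal=pd.DataFrame(kw_rows),
        conover=pd.concat(con_frames, ignore_index=True),
        one_vs_rest=pd.concat(ovr_frames, ignore_index=True),
    )


def qualitative_labels(profile: ClusterProfile, tests: TestResults,
                       z_high: float = 0.5, p_high: float = 1e-3,
                       delta_high: float = 0.3) -> pd.DataFrame:
    """k x p high/moderate/low calls combining the radar rule and the tests."""
    ovr = tests.one_vs_rest.set_index(["code", "cluster"])
    out = {}
    for code in profile.z.columns:
        col = {}
        for c in profile.z.index:
            z = profile.z.loc[c, code]
            p = ovr.loc[(code, c), "p"]
            delta = ovr.loc[(code, c), "delta"]
            if (np.isfinite(z) and z > z_high) or (p < p_high and delta > delta_high):
                col[c] = "high"
            elif not np.isfinite(z) or z <= 0:
                col[c] = "low"
            else:
                col[c] = "moderate"
        out[code] = col
    qual = pd.DataFrame(out).loc[profile.z.index, profile.z.columns]
    qual.index.name = "cluster"
    profile.qualitative = qual
    return qual


# ---------------------------------------------------------------------------
# radar export
# ---------------------------------------------------------------------------

def radar_records(profile: ClusterProfile) -> pd.DataFrame:
    """Tidy records (cluster, code, z, label), one row per cluster x variable."""
    z_long = profile.z.stack().rename("z")
    q_long = profile.qualitative.stack().rename("label")
    out = pd.concat([z_long, q_long], axis=1).reset_index()
    out.columns = ["cluster", "code", "z", "label"]
    return out


def radar_export(profile: ClusterProfile, path: str | Path) -> dict[str, Path]:
    """Write radar records plus circle metadata; round-trips via
    :func:`radar_import`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = radar_records(profile)
    records.to_csv(path, index=False, float_format="%.17g")
    meta_path = path.with_suffix(".circles.csv")
    pd.DataFrame({"z": RADAR_CIRCLES}).to_csv(meta_path, index=False)
    return {"records": path, "circles": meta_path}


def radar_import(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def plot_radar(profile: ClusterProfile, cluster: int, ax=None):
    """Polar plot of one cluster's z-profile with 0.5 sigma circles.

    Purely presentational; all quantitative content lives in
    :func:`radar_records`.
    """
    import matplotlib.pyplot as plt

    codes = list(profile.z.columns)
    zvals = profile.z.loc[cluster].to_numpy(float)
    theta = np.linspace(0, 2 * np.pi, len(codes), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    closed_t = np.concatenate([theta, theta[:1]])
    closed_z = np.concatenate([zvals, zvals[:1]])
    ax.plot(closed_t, closed_z)
    ax.fill(closed_t, closed_z, alpha=0.2)
    for circle in RADAR_CIRCLES:
        ax.plot(np.linspace(0, 2 * np.pi, 200), np.full(200, circle),
                lw=0.5, color="grey")
    ax.set_xticks(theta)
    ax.set_xticklabels(codes, fontsize=6)
    ax.set_title(f"cluster {cluster}")
    return ax
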