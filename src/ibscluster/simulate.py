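"""Synthetic IBS questionnaire cohorts with planted subgroup structure.

The generator emulates the statistical shape of a population-based IBS
questionnaire study: 36 gastrointestinal symptom items on a 4-point Likert
scale (never or rarely / sometimes / often / always), nine continuous
psychometric scores (hospital anxiety and depression scales, GHQ-12,
somatization, NEO five-factor traits) with realistic means/SDs, a shared
latent "psychological burden" factor that induces the observed psychosomatic
inter-score correlation (~0.5 between somatization and depression), and K
planted subgroups whose variable-wise target z-shifts mirror the qualitative
nine-profile structure of the study population (diarrhea-, constipation-,
upper-GI-, and psychologically-dominated subgroups plus milder core groups).

Mechanism.  Each sample draws a subgroup, a factor value f, and per-variable
noise.  Every variable has a latent Gaussian whose cluster-specific mean is
*calibrated* (probit arithmetic for the thresholded ordinal items,
censored-normal arithmetic for range-clipped continuous scores) so that the
realized population z-value of cluster c on variable j matches the configured
target shift -- in units of the realized population SD, exactly the quantity
the profiling battery estimates.  Because population z-values are centred by
construction, the generator centres each profile column by the mixing
proportions before calibrating; configured columns should therefore be read
as contrasts around the population mean.

The module also implements the Rome III machinery used to characterise
samples: the IBS inclusion filter, the bowel-habit subtype rule
(IBS-C/D/M/U), and the abdominal-pain-plus-bloating severity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .schema import MixedDataMatrix, VariableSchema

LIKERT_LEVELS = ("never or rarely", "sometimes", "often", "always")

#: Table of the 36 GI symptom items (code, description).
GI_ITEMS: tuple[tuple[str, str], ...] = (
    ("AP", "Abdominal pain"),
    ("AO", "Anorectal obstruction"),
    ("B", "Bloating"),
    ("CFSAP", "Change in the frequency/form of stool during abdominal pain"),
    ("CFSEP", "Change in the frequency/form of stool during epigastric pain"),
    ("DR", "Difficulty relaxing during bowel movement"),
    ("EPB", "Epigastric pain or burning"),
    ("ES", "Early satiation"),
    ("FT", "Food sticking in the throat"),
    ("FTH", "Food sticking in the throat with heartburn"),
    ("HB", "Heartburn"),
    ("HS", "Lumpy or hard stools"),
    ("IE", "Sensation of incomplete evacuation"),
    ("LS", "Very loose or watery stool"),
    ("LT", "Sensation of a lump in the throat"),
    ("L3DW", "Less than 3 defecations in a week"),
    ("MM", "Manual maneuvers for defecation"),
    ("MS", "Mucus in stool"),
    ("M3D", "More than 3 defecations in a day"),
    ("N", "Nausea"),
    ("NCP", "Non-cardiac chest pain"),
    ("PF", "Postprandial fullness"),
    ("PS", "Pain during swallowing"),
    ("PUA", "Pain in the upper or side of the abdomen"),
    ("R", "Regurgitation"),
    ("RAPCS", "Relief of abdominal pain by change in the body situation"),
    ("RAPD", "Relief of abdominal pain by defecation"),
    ("RB", "Rectal burning"),
    ("RDAAP", "Restriction of daily activities due to the abdominal pain"),
    ("REPD", "Relief of epigastric pain/burn by defecation"),
    ("REPE", "Relief of epigastric pain/burn by eating"),
    ("RP", "Rectal pain"),
    ("SD", "Straining during defecation"),
    ("SG", "Stomach growling"),
    ("SI", "Stool incontinence"),
    ("U", "Urgency"),
)

#: Continuous psychometric scores: code, name, (min, max), population mean, SD.
CONTINUOUS_SCORES: tuple[tuple[str, str, tuple[float, float], float, float], ...] = (
    ("DEP", "Depression (HADS)", (0, 21), 7.5, 3.5),
    ("ANX", "Anxiety (HADS)", (0, 21), 5.4, 4.0),
    ("GHQ", "Psychological distress (GHQ-12)", (0, 12), 3.1, 3.1),
    ("SOM", "Somatization score", (0, 42), 11.6, 5.9),
    ("NEU", "Neuroticism (NEO-FFI)", (0, 48), 21.7, 7.4),
    ("EXT", "Extraversion (NEO-FFI)", (0, 48), 27.9, 6.4),
    ("OPE", "Openness (NEO-FFI)", (0, 48), 24.5, 4.9),
    ("AGR", "Agreeableness (NEO-FFI)", (0, 48), 30.7, 5.7),
    ("CON", "Conscientiousness (NEO-FFI)", (0, 48), 35.7, 6.5),
)

#: Default Likert level frequencies of the baseline (unshifted) cluster.
DEFAULT_LEVEL_FREQS = (0.4, 0.3, 0.2, 0.1)

#: Cluster sizes of the nine-subgroup solution, used as mixing proportions.
DEFAULT_CLUSTER_SIZES = (103, 103, 158, 104, 100, 80, 132, 74, 134)

# variable groups used to spell out the nine planted profiles
_PAIN = ("AP", "B", "CFSAP", "RAPD", "RAPCS", "RDAAP", "PUA")
_DIAR = ("LS", "M3D", "U", "SI")
_CONS = ("HS", "L3DW", "SD", "AO", "IE", "MM", "DR")
_ANOR = ("RB", "RP")
_LOWER_MISC = ("MS", "SG")
_UPPER = ("EPB", "ES", "FT", "FTH", "HB", "LT", "N", "NCP", "PF", "PS", "R",
          "REPD", "REPE", "CFSEP")
_PSY = ("DEP", "ANX", "GHQ", "SOM", "NEU")
_PERS = ("EXT", "OPE", "AGR", "CON")


def default_schema() -> list[VariableSchema]:
    """36 Likert GI items followed by 9 continuous psychometric scores."""
    out = [VariableSchema(code=c, name=n, kind="ordinal", levels=LIKERT_LEVELS)
           for c, n in GI_ITEMS]
    out += [VariableSchema(code=c, name=n, kind="continuous", range=rng)
            for c, n, rng, _, _ in CONTINUOUS_SCORES]
    return out


def _spread(codes, value) -> dict[str, float]:
    return {c: value for c in codes}


def default_profile_matrix() -> pd.DataFrame:
    """Target z-shift matrix (9 clusters x 45 variables).

    Values are target population z-shifts; each cluster's signature variables
    sit near +2 before centring (>= +1.5 after), with moderate shifts
    elsewhere reproducing the qualitative nine-profile pattern: (1) diarrhea +
    pain + upper GI + psych burden, (2) upper GI + somatization, (3) psych
    burden with moderate GI, (4) constipation + psych burden, (5) moderate
    constipation, (6) diarrhea with raised depression, (7) moderate diarrhea,
    (8) globally mild, (9) moderate lower GI.
    """
    profiles: list[dict[str, float]] = []
    # 1: high diarrhea, pain, upper GI, high psychological burden
    c = {}
    c.update(_spread(_PAIN, 2.0))
    c.update(_spread(_DIAR, 1.5))
    c.update(_spread(_ANOR, 0.7))
    c.update(_spread(_LOWER_MISC, 0.7))
    c.update(_spread(_UPPER, 0.4))
    c.update({"EPB": 1.7, "PF": 1.5, "NCP": 1.2, "N": 0.9})
    c.update(_spread(_CONS, -0.3))
    c.update({"DEP": 1.0, "ANX": 2.0, "GHQ": 0.9, "SOM": 1.0, "NEU": 1.8})
    c.update(_spread(_PERS, -0.5))
    profiles.append(c)
    # 2: high upper GI and somatization, moderate lower GI and psych
    c = {}
    c.update(_spread(_UPPER, 1.8))
    c.update({"EPB": 1.2, "N": 1.3, "PF": 1.0, "REPD": 1.0, "REPE": 1.0,
              "CFSEP": 1.2})
    c.update(_spread(_PAIN, 0.6))
    c.update(_spread(_DIAR, 0.6))
    c.update(_spread(_ANOR, 0.9))
    c.update({"HS": 0.5})
    c.update({"DEP": 0.5, "ANX": 0.5, "GHQ": 0.5, "SOM": 1.9, "NEU": 0.5})
    c.update(_spread(_PERS, -0.3))
    profiles.append(c)
    # 3: high psychological burden, moderate overall GI
    c = {}
    for grp in (_PAIN, _DIAR, _CONS, _ANOR, _LOWER_MISC, _UPPER):
        c.update(_spread(grp, 0.45))
    c.update({"DEP": 2.0, "GHQ": 2.0, "ANX": 1.1, "NEU": 1.1, "SOM": 0.6})
    c.update(_spread(_PERS, -0.7))
    profiles.append(c)
    # 4: high constipation, pain, moderate upper GI, high psychological burden
    c = {}
    c.update(_spread(_CONS, 1.8))
    c.update(_spread(_PAIN, 0.9))
    c.update(_spread(_UPPER, 0.4))
    c.update({"EPB": 0.9})
    c.update(_spread(_DIAR, -0.3))
    c.update({"DEP": 1.0, "ANX": 1.1, "GHQ": 1.0, "SOM": 1.0, "NEU": 1.0})
    c.update(_spread(_PERS, -0.5))
    profiles.append(c)
    # 5: moderate constipation, low psychological burden
    c = {}
    c.update(_spread(_CONS, 0.9))
    c.update(_spread(_PAIN, -0.3))
    c.update(_spread(_DIAR, -0.3))
    c.update(_spread(_UPPER, -0.3))
    c.update(_spread(_PSY, -0.35))
    c.update(_spread(_PERS, 0.25))
    profiles.append(c)
    # 6: high diarrhea, moderate psychological burden (raised depression)
    c = {}
    c.update(_spread(_DIAR, 2.1))
    c.update({"SI": 1.0})
    c.update(_spread(_PAIN, 0.3))
    c.update(_spread(_CONS, -0.5))
    c.update(_spread(_UPPER, -0.25))
    c.update({"DEP": 0.8, "ANX": 0.3, "GHQ": 0.3, "SOM": 0.4, "NEU": 0.3})
    c.update(_spread(_PERS, -0.2))
    profiles.append(c)
    # 7: moderate diarrhea, low psychological burden
    c = {}
    c.update(_spread(_DIAR, 0.8))
    c.update(_spread(_PAIN, -0.1))
    c.update(_spread(_CONS, -0.4))
    c.update(_spread(_UPPER, -0.25))
    c.update(_spread(_PSY, -0.45))
    c.update(_spread(_PERS, 0.3))
    profiles.append(c)
    # 8: low overall GI and psychological burden
    c = {}
    for grp in (_PAIN, _DIAR, _CONS, _ANOR, _LOWER_MISC, _UPPER):
        c.update(_spread(grp, -0.3))
    c.update(_spread(_PSY, -0.55))
    c.update(_spread(_PERS, 0.4))
    profiles.append(c)
    # 9: moderate lower GI, low psychological burden
    c = {}
    c.update(_spread(_PAIN, 0.8))
    c.update(_spread(_DIAR, 0.6))
    c.update(_spread(_CONS, 0.6))
    c.update(_spread(_ANOR, 0.6))
    c.update(_spread(_LOWER_MISC, 0.6))
    c.update(_spread(_UPPER, -0.2))
    c.update(_spread(_PSY, -0.35))
    c.update(_spread(_PERS, 0.2))
    profiles.append(c)

    codes = [c for c, _ in GI_ITEMS] + [c for c, *_ in CONTINUOUS_SCORES]
    mat = pd.DataFrame(0.0, index=range(1, 10), columns=codes)
    for i, prof in enumerate(profiles, start=1):
        for code, val in prof.items():
            mat.loc[i, code] = val
    mat.index = range(9)  # cluster ids 0..8
    return mat


def default_latent_loadings() -> pd.Series:
    """Loadings of each variable on the shared psychological-burden factor."""
    codes = [c for c, _ in GI_ITEMS] + [c for c, *_ in CONTINUOUS_SCORES]
    s = pd.Series(0.25, index=codes)
    s[list(_PSY)] = 0.35
    s[list(_PERS)] = -0.25
    return s


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``profile_matrix`` rows are clusters, columns variables, entries target
    z-shifts in units of the population SD (centred internally by the mixing
    proportions).  ``baseline_level_freqs`` gives the Likert level
    probabilities of an unshifted cluster; cutpoints are calibrated from it.
    """

    n_samples: int = 1000
    mixing_proportions: tuple[float, ...] = tuple(
        np.asarray(DEFAULT_CLUSTER_SIZES, float) / sum(DEFAULT_CLUSTER_SIZES))
    profile_matrix: pd.DataFrame = field(default_factory=default_profile_matrix)
    baseline_means: dict[str, float] = field(default_factory=lambda: {
        c: m for c, _, _, m, _ in CONTINUOUS_SCORES})
    baseline_sds: dict[str, float] = field(default_factory=lambda: {
        c: s for c, _, _, _, s in CONTINUOUS_SCORES})
    baseline_level_freqs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    latent_loadings: pd.Series = field(default_factory=default_latent_loadings)
    seed: int = 988

    def __post_init__(self) -> None:
        pi = np.asarray(self.mixing_proportions, float)
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("mixing proportions must sum to 1")
        if (pi <= 0).any():
            raise ValueError("mixing proportions must be positive")
        if not np.all(np.isfinite(self.profile_matrix.to_numpy(float))):
            raise ValueError("profile matrix must be finite")
        if len(self.mixing_proportions) != len(self.profile_matrix):
            raise ValueError("mixing proportions and profile rows disagree")

    @property
    def n_clusters(self) -> int:
        return len(self.profile_matrix)

    def level_freqs(self, code: str) -> np.ndarray:
        f = np.asarray(self.baseline_level_freqs.get(code, DEFAULT_LEVEL_FREQS),
                       float)
        return f / f.sum()


@dataclass
class CohortTruth:
    """Planted cluster assignment of a generated cohort."""

    labels: np.ndarray
    config: GeneratorConfig = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        K = self.config.n_clusters
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= K):
            raise ValueError("truth labels outside 0..K-1")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _centred_targets(config: GeneratorConfig) -> pd.DataFrame:
    pi = np.asarray(config.mixing_proportions, float)
    prof = config.profile_matrix.to_numpy(float)
    centred = prof - (pi[:, None] * prof).sum(axis=0, keepdims=True)
    between = (pi[:, None] * centred**2).sum(axis=0)
    bad = between >= 0.95
    if bad.any():
        codes = config.profile_matrix.columns[bad].tolist()
        raise ValueError(
            f"profile shifts on {codes} imply between-cluster variance >= 95% "
            "of the population variance; reduce or spread the shifts"
        )
    return pd.DataFrame(centred, index=config.profile_matrix.index,
                        columns=config.profile_matrix.columns)


def _ordinal_moments(delta: np.ndarray, cuts: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the thresholded rank for latent N(delta, 1)."""
    p_ge = norm.cdf(delta[:, None] - cuts[None, :])  # P(rank >= t), t = 1..L-1
    mean = p_ge.sum(axis=1)
    second = ((2 * np.arange(1, cuts.size + 1) - 1)[None, :] * p_ge).sum(axis=1)
    return mean, second - mean**2


def _calibrate_ordinal(s_target: np.ndarray, pi: np.ndarray, cuts: np.ndarray,
                       n_iter: int = 80) -> np.ndarray:
    """Latent cluster shifts delta_c such that realized rank z-values match
    the centred targets."""
    L1 = cuts.size
    delta = s_target.copy()
    lo_mean, hi_mean = 0.02, L1 - 0.02
    for _ in range(n_iter):
        mean, var = _ordinal_moments(delta, cuts)
        m = float(pi @ mean)
        V = float(pi @ (var + mean**2) - m**2)
        target_mean = np.clip(m + s_target * np.sqrt(max(V, 1e-12)),
                              lo_mean, hi_mean)
        # Newton on the monotone probit mean
        for _ in range(25):
            mean_c = norm.cdf(delta[:, None] - cuts[None, :]).sum(axis=1)
            grad = norm.pdf(delta[:, None] - cuts[None, :]).sum(axis=1)
            step = (target_mean - mean_c) / np.maximum(grad, 1e-6)
            delta = delta + np.clip(step, -1.0, 1.0)
            if np.max(np.abs(step)) < 1e-10:
                break
    return delta


def _censored_moments(a: np.ndarray, w: float, lo: float, hi: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of clip(N(a, w^2), lo, hi)."""
    alpha = (lo - a) / w
    beta = (hi - a) / w
    Phi_a, Phi_b = norm.cdf(alpha), norm.cdf(beta)
    phi_a, phi_b = norm.pdf(alpha), norm.pdf(beta)
    delta = Phi_b - Phi_a
    mean = lo * Phi_a + hi * (1 - Phi_b) + a * delta + w * (phi_a - phi_b)
    ex2 = (lo**2 * Phi_a + hi**2 * (1 - Phi_b) + (a**2) * delta
           + 2 * a * w * (phi_a - phi_b)
           + w**2 * (delta + alpha * phi_a - beta * phi_b))
    return mean, np.maximum(ex2 - mean**2, 1e-12)


def _calibrate_continuous(s_target: np.ndarray, pi: np.ndarray,
                          target_mean: float, target_sd: float,
                          lo: float, hi: float, n_iter: int = 120
                          ) -> tuple[np.ndarray, float]:
    """Latent cluster means a_c and shared within-cluster SD w such that the
    clipped variable matches the population mean/SD and the centred z-targets."""
    between = float(pi @ s_target**2)
    w = target_sd * np.sqrt(max(1.0 - between, 0.04))
    a = target_mean + s_target * target_sd
    for _ in range(n_iter):
        mean, var = _censored_moments(a, w, lo, hi)
        m = float(pi @ mean)
        V = float(pi @ (var + mean**2) - m**2)
        sd = np.sqrt(max(V, 1e-12))
        tgt = m + (target_mean - m) + s_target * sd  # recentre and rescale
        # Newton step on the censored mean (derivative = interior mass)
        for _ in range(15):
            mean_c, _ = _censored_moments(a, w, lo, hi)
            alpha = (lo - a) / w
            beta = (hi - a) / w
            grad = np.maximum(norm.cdf(beta) - norm.cdf(alpha), 1e-4)
            step = (tgt - mean_c) / grad
            a = a + np.clip(step, -w, w)
            if np.max(np.abs(step)) < 1e-10:
                break
        w = float(np.clip(w * (target_sd / sd) ** 0.7,
                          0.05 * target_sd, 3.0 * target_sd))
    return a, w


@dataclass
class _CalibratedVariable:
    code: str
    kind: str
    cluster_shift: np.ndarray          # latent mean per cluster
    cuts: np.ndarray | None = None     # ordinal
    within_sd: float = 1.0             # continuous latent SD
    bounds: tuple[float, float] | None = None


def calibrate_generator(config: GeneratorConfig) -> list[_CalibratedVariable]:
    """Solve, per variable, the latent parameters reproducing the targets."""
    pi = np.asarray(config.mixing_proportions, float)
    centred = _centred_targets(config)
    schema = default_schema_for(config)
    out = []
    for v in schema:
        s = centred[v.code].to_numpy(float)
        if v.kind == "ordinal":
            freqs = config.level_freqs(v.code)
            cuts = norm.ppf(np.cumsum(freqs)[:-1])
            delta = _calibrate_ordinal(s, pi, cuts)
            out.append(_CalibratedVariable(v.code, "ordinal", delta, cuts=cuts))
        else:
            lo, hi = v.range
            a, w = _calibrate_continuous(
                s, pi, config.baseline_means[v.code],
                config.baseline_sds[v.code], lo, hi)
            out.append(_CalibratedVariable(v.code, "continuous", a,
                                           within_sd=w, bounds=(lo, hi)))
    return out


def default_schema_for(config: GeneratorConfig) -> list[VariableSchema]:
    """Schema matching the profile-matrix columns (default battery)."""
    by_code = {v.code: v for v in default_schema()}
    try:
        return [by_code[c] for c in config.profile_matrix.columns]
    except KeyError as exc:  # pragma: no cover - config error path
        raise ValueError(f"unknown variable code in profile matrix: {exc}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig | None = None
                    ) -> tuple[MixedDataMatrix, CohortTruth]:
    """Draw a cohort; deterministic for a fixed config seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(int(config.seed))
    n = config.n_samples
    pi = np.asarray(config.mixing_proportions, float)
    labels = rng.choice(config.n_clusters, size=n, p=pi)
    factor = rng.standard_normal(n)
    schema = default_schema_for(config)
    calibrated = calibrate_generator(config)
    cols = {}
    for v, cal in zip(schema, calibrated):
        lam = float(config.latent_loadings.get(v.code, 0.0))
        lam = float(np.clip(lam, -0.99, 0.99))
        unit = lam * factor + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        if cal.kind == "ordinal":
            latent = cal.cluster_shift[labels] + unit
            cols[v.code] = (latent[:, None] > cal.cuts[None, :]).sum(axis=1)
        else:
            lo, hi = cal.bounds
            latent = cal.cluster_shift[labels] + cal.within_sd * unit
            cols[v.code] = np.clip(latent, lo, hi)
    frame = pd.DataFrame(cols, index=pd.RangeIndex(n, name="sample_id"))
    data = MixedDataMatrix(schema=schema, frame=frame)
    return data, CohortTruth(labels=labels, config=config)


# ---------------------------------------------------------------------------
# Rome III machinery
# ---------------------------------------------------------------------------

_SOMETIMES = 1  # Likert rank of "sometimes"
_OFTEN = 2


def rome3_ibs_filter(data: MixedDataMatrix, pain_item: str = "AP",
                     improvement_item: str = "RAPD",
                     change_item: str = "CFSAP",
                     change_counts_both: bool = False
                     ) -> tuple[np.ndarray, MixedDataMatrix]:
    """Rome III IBS inclusion: recurrent abdominal pain at least "sometimes"
    plus two or more of {improvement with defecation, pain onset with a change
    in stool frequency, pain onset with a change in stool form}.

    The questionnaire's combined frequency/form-change item satisfies at most
    one criterion by default (conservative); set ``change_counts_both=True``
    to let it satisfy both change criteria.
    """
    for item in (pain_item, improvement_item, change_item):
        if item not in data.frame.columns:
            raise ValueError(f"required Rome III item {item!r} missing from schema")
    f = data.frame
    gate = f[pain_item].to_numpy() >= _SOMETIMES
    n_criteria = (f[improvement_item].to_numpy() >= _SOMETIMES).astype(int)
    change = (f[change_item].to_numpy() >= _SOMETIMES).astype(int)
    n_criteria = n_criteria + (2 * change if change_counts_both else change)
    passed = gate & (n_criteria >= 2)
    return passed, data.subset(np.flatnonzero(passed))


SUBTYPES = ("IBS-C", "IBS-D", "IBS-M", "IBS-U")


def rome3_subtype(row: pd.Series, hard_item: str = "HS",
                  loose_item: str = "LS") -> str:
    """Bowel-habit subtype from the hard- and loose-stool items; a level of
    "often" or "always" counts as elevated."""
    hard = int(row[hard_item]) >= _OFTEN
    loose = int(row[loose_item]) >= _OFTEN
    if hard and loose:
        return "IBS-M"
    if hard:
        return "IBS-C"
    if loose:
        return "IBS-D"
    return "IBS-U"


def rome3_subtypes(data: MixedDataMatrix, **kw) -> pd.Series:
    return data.frame.apply(lambda r: rome3_subtype(r, **kw), axis=1)


SEVERITY_CATEGORIES = ("mild", "moderate", "high")


def ibs_severity(row: pd.Series, pain_item: str = "AP",
                 bloating_item: str = "B") -> tuple[int, str]:
    """Severity score = Likert rank of abdominal pain + bloating (0-6);
    category mild/moderate/high at score 0 / 1 / >= 2."""
    score = int(row[pain_item]) + int(row[bloating_item])
    return score, severity_category(score)


def severity_category(score: float) -> str:
    if score < 1:
        return "mild"
    if score < 2:
        return "moderate"
    return "high"


def cluster_severity(data: MixedDataMatrix, labels,
                     pain_item: str = "AP", bloating_item: str = "B"
                     ) -> pd.DataFrame:
    """Median severity score and category per cluster."""
    y = np.asarray(labels, int)
    score = (data.frame[pain_item] + data.frame[bloating_item]).to_numpy()
    rows = []
    for c in np.unique(y):
        med = float(np.median(score[y == c]))
        rows.append({"cluster": c, "median_score": med,
                     "category": severity_category(med)})
    return pd.DataFrame(rows).set_index("cluster")
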