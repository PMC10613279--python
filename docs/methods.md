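# Methods

`ibscluster` implements a subgroup-discovery pipeline for symptom
questionnaire cohorts in which ordinal Likert items (gastrointestinal
symptoms) and continuous psychometric scores (anxiety, depression, GHQ-12,
somatization, NEO-FFI traits) must be clustered jointly. This note records
the model, the numerical choices, and what the synthetic cohort does and does
not establish.

## The mixed-type distance

Each variable contributes a unit-interval distance shaped by its measurement
kind and empirical distribution:

- **Ordinal** items use the empirical CDF over the declared level order:
  `d(a, b) = |F(a) − F(b)| / (F(L−1) − F(0))`. Distances between adjacent
  levels therefore reflect how much probability mass separates them, and the
  extreme *observed* categories sit at distance 1. A constant item
  contributes 0 and is flagged degenerate.
- **Nominal** variables use simple mismatch (0/1).
- **Continuous** scores use `|a − b| / (max − min)` with the *schema* range
  (the instrument's range), not the observed range, so that the metric does
  not drift when the cohort is subsampled during stability analysis.

Variables are then weighted by their dependency on the rest of the battery:
all variables are discretised (continuous scores into 4 equal-frequency bins,
matching the Likert granularity), pairwise normalised mutual information
`NMI(j, l) = I(j; l)/√(H_j H_l)` is computed, and variable *j* receives
weight `w_j = 1 + mean_{l≠j} NMI(j, l)`, rescaled to mean 1. The sample
distance is the weighted mean of per-variable distances, hence symmetric,
zero-diagonal and bounded in [0, 1]. No *user*-imposed prior weights enter;
the weighting is data-driven and can be disabled
(`dependency_weights=False` / `--no-dependency-weights`) to obtain the
strictly equal-weight metric.

The triangle inequality is *not* asserted for the ordinal component (the CDF
transform is per-variable monotone, which preserves it per variable, but we
make no claim for the weighted mixture with data-dependent weights) and is
not required by any downstream step.

## Spectral clustering

The distance matrix is converted to a Gaussian affinity. The default
bandwidth rule is **local scaling** (per-sample scales, `A_ij =
exp(−D_ij²/(σ_i σ_j))` with `σ_i` the distance to the 7th nearest
neighbour). The reason is empirical and structural: mixed-type questionnaire
distances concentrate in a narrow band (on the packaged cohort, mean
within-cluster distance ≈ 0.27 vs between ≈ 0.38 with SD ≈ 0.09), and a
single global bandwidth — including the common median heuristic — produces a
nearly flat Laplacian spectrum (first nontrivial eigenvalue ≈ 0.85) from
which the planted structure is barely recoverable (Hungarian accuracy ≈ 0.68
against planted truth). Local scales restore the contrast (accuracy ≈ 0.93
on the same cohort). The global `"median"` rule and fixed bandwidths remain
available via `affinity_scale_rule`.

Partitioning follows the standard normalised-spectral recipe: symmetric
normalised Laplacian, the m smallest *nontrivial* eigenvectors (m = k by
default; m = 2 for the visualisation embedding), rows normalised to unit
length, deterministic sign convention (first nonzero component of each
eigenvector positive), and k-means with k-means++ initialisation and 50
restarts under a per-stage derived seed. A dense symmetric eigensolver is
used (cohorts of interest are n ≲ 5000). Empty k-means clusters are repaired
by splitting the largest cluster; every reported cluster is non-empty.

All randomness derives from one master seed: each stage hashes
`"{master_seed}:{stage name}"` (SHA-256, 31 bits), so any stage can be
reproduced in isolation.

## Number of clusters: CVNN and S-Dbw

`select_k` evaluates two internal validity indices over the candidate range
(default k = 2..14) and picks the CVNN argmin (ties toward smaller k), with
both argmins reported:

- **CVNN** on the mixed distance matrix: separation is the worst-cluster mean
  fraction of each member's κ = 10 nearest neighbours lying outside its
  cluster; compactness is the sum over clusters of the mean pairwise
  intra-cluster distance; each component is normalised by its maximum over
  the candidate set and the two are added.
- **S-Dbw** in the spectral embedding used for partitioning: average relative
  cluster scatter plus the mean, over cluster pairs, of the midpoint density
  relative to the denser of the two cluster centres (density = points within
  a radius equal to the mean cluster standard-deviation norm; a zero
  denominator contributes the worst case 1).

**Known limitation.** On data with a per-variable noise floor — any realistic
questionnaire cohort — the summed compactness term cannot fall below
(number of clusters) × (noise-floor distance), so it grows roughly linearly
in k and CVNN attains its minimum at the smallest candidate k regardless of
the true structure; an interior CVNN minimum requires between/within distance
ratios (≳ 3) that moderate symptom shifts cannot produce. We verified this on
the packaged cohort in every natural evaluation space (raw mixed distances,
per-k spectral embeddings, fixed embeddings of several dimensions, raw
standardised features, multiple seeds): recovery of the planted nine-group
structure peaks sharply at k = 9, yet neither index has its minimum there.
The indices are therefore reported as diagnostics, and analyses of a known
design should fix k from substantive grounds. The package keeps the
CVNN-primary selection rule because it is the declared contract, and the
validity curve output makes the behaviour inspectable.

## Stability and classification

Stability follows a reference-matching design: the full cohort is clustered
once at fixed k; then for each subsampling rate (defaults 0.90, 0.92, 0.94,
0.96, 0.98) and iteration (default 10), a subsample is drawn without
replacement, the *entire* pipeline — including distribution fitting and
dependency weights — is re-run on the subsample at the same k, and the
subsample partition is scored against the reference partition restricted to
the subsample by Hungarian-matched clustering accuracy (optimal one-to-one
cluster assignment on the contingency table, padded when cluster counts
differ). Reference matching, rather than all subsample pairs, is the direct
reading of "stability of the clustering" and is linear in the number of
experiments.

Cluster membership is also checked for predictability: ordinal ranks and
continuous scores are standardised and a support-vector machine with RBF
kernel and fixed hyperparameters (C = 10, gamma = "scale"; no tuning loop) is
scored by leave-one-out accuracy with a precomputed kernel.

## Profiling battery

Per variable, across clusters: tie-corrected Kruskal–Wallis H with
ε² = H/(n−1); Conover–Iman post-hoc pairwise t statistics on the pooled ranks
(tie-corrected pooled variance, (n−1−H)/(n−k) multiplier, t with n−k df) with
Holm step-down correction, the family being all cluster pairs within one
variable; and one-vs-rest Mann–Whitney U (asymptotic, tie-corrected) with
Cliff's delta computed by rank arithmetic, positive when the cluster exceeds
the rest.

z-profiles standardise each cluster's variable mean against the
whole-population mean and SD (ordinal items via integer ranks 0..3; sample SD
with ddof = 1). The size-weighted mean of z over clusters is identically
zero. The qualitative call per (cluster, variable) is: **high** if z > 0.5
or (one-vs-rest p < 0.001 and delta > 0.3); **low** if z ≤ 0; **moderate**
otherwise. "Low" is read as at-or-below the population mean ("inside the
central circle"); the effect size in the high rule is the one-vs-rest
Cliff's delta (the per-cluster test), not ε² (which is a single
across-cluster quantity per variable). Radar exports are tidy records
(cluster, code, z, qualitative call) plus circle metadata at z = 0, 0.5,
1.0, 1.5; images are optional and carry no additional information.

## The synthetic cohort

The generator emulates the structure such a study observes: 36 Likert GI
items (baseline level frequencies 0.40/0.30/0.20/0.10 for never-or-rarely /
sometimes / often / always), 9 continuous scores with instrument ranges and
population means/SDs (depression 7.5 ± 3.5, anxiety 5.4 ± 4.0, GHQ-12
3.1 ± 3.1, somatization 11.6 ± 5.9, NEO-FFI 21.7/27.9/24.5/30.7/35.7), nine
planted subgroups with mixing proportions matching the nine-cluster solution
sizes (103, 103, 158, 104, 100, 80, 132, 74, 134 of 988), and a shared
latent psychological-burden factor (loadings 0.35 on the five burden scores,
−0.25 on the other four personality traits, 0.25 on GI items) calibrated so
the somatization–depression Spearman correlation is ≈ 0.5.

Profile shifts are **target z-values in units of the population SD** — the
exact quantity the profiling battery estimates. Two consequences are built
in. First, since realized z-values are centred by construction, profile
columns are centred by the mixing proportions before use. Second, the
mixing-weighted variance of a centred column is the between-cluster share of
the population variance and must stay below 1; the generator rejects
configurations violating this. This is why each subgroup's signature sits at
≈ +1.5σ on its *own* variables (at most 2-3 subgroups ≥ 1.4σ on any one
variable) with moderate shifts elsewhere: a profile in which half the
subgroups are 1.5σ above the population mean on the same score is
arithmetically impossible.

Generation draws a subgroup, a factor value, and per-variable noise, and
maps a unit-variance latent Gaussian through per-variable calibrated
parameters: for ordinal items, cutpoints from the baseline level frequencies
and cluster-specific latent shifts solved (probit arithmetic plus Newton
iterations inside a fixed-point loop over the population moments) so the
realized *rank-scale* z-values equal the centred targets; for continuous
scores, censored-normal moments (clipping to the instrument range is part of
the model) with the latent offset, within-cluster SD and cluster shifts
solved to match the population mean, population SD and centred z-targets
simultaneously. Realized z-profiles match targets to within ±0.15 at
n = 5000 (typically ±0.10).

What the synthetic cohort does **not** emulate: item-level missingness,
response styles (acquiescence, extreme responding), non-Gaussian latent
shapes, demographic covariates, and any within-subject longitudinal
structure. Passing tests establish that the pipeline recovers planted
structure of realistic geometry — not that nine subgroups exist in any real
population.

## Default problem sizes

The packaged analyses use n = 1000 (cohort), 50 stability experiments
(5 rates × 10 iterations), leave-one-out over all 1000 samples, candidate
k = 2..14, and n = 5000 for generator-fidelity checks — sizes chosen so the
full battery runs on a laptop-class single core in minutes while keeping
Monte-Carlo noise well inside the asserted margins.

## Degenerate inputs and tie-breaks

Constant variables: distance 0, zero NMI, weight 1 before rescaling.
All-identical cohorts: affinity construction refuses (no meaningful scale).
Singleton clusters: compactness term 0 (logged). Zero density denominators
in S-Dbw: worst-case contribution 1 (logged). Validity ties: smaller k.
k-means: fixed restart count and derived seeds; eigenvector signs fixed by
first-nonzero-positive. Missing cells: rejected by default, listwise
deletion on request (count logged).
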