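# Methods

## The generative model

Each simulated cohort is an N × D binary disease matrix (default
N = 2,000, D = 26) with known patient clusters, built in three steps.

**Cluster membership.** Each patient belongs to exactly one of K disease
clusters. Cluster probabilities are either a single draw of K
exponential(λ) variables normalised to sum to one (default, λ = 1,
producing unbalanced clusters) or uniform 1/K. An optional
`fraction_unclustered` places patients in no cluster (label 0, diseases
from noise only); it defaults to 0.

**Disease allocation.** Cluster k receives `max(Poisson(mean), min)`
diseases (defaults mean = 5, min = 2, reflecting a clinically expected
2–10 conditions per cluster). With overlap (the default for the parameter
sweeps), clusters draw their disease sets independently, so one disease
can drive several clusters; without overlap, sets are drawn sequentially
without replacement. When the disjoint pool runs short the affected
cluster is truncated to the remaining diseases, and the configuration is
rejected if fewer than `min` remain — the sequential description leaves
exhaustion behaviour open, and truncate-then-reject is the least
surprising total rule.

**Multivariate probit observation.** For a patient in cluster k, a latent
D-vector z ~ N(0, Σₖ) is thresholded: disease d is present iff
z_d > Φ⁻¹(1 − p_d), where p_d equals `within_prevalence` for d in the
cluster's disease set and 0 (threshold +∞) otherwise. Σₖ is the identity
with an equicorrelated block of value ρ over the cluster's diseases;
for ρ ∈ [0, 1) the block latent vector is sampled exactly via the
one-factor decomposition √ρ·z₀ + √(1−ρ)·z_d. The stated within-cluster
prevalence is therefore the *pre-noise* marginal P(disease | member) —
the simplest reading of a threshold model. Finally every cell is OR-ed
with an independent Bernoulli(q) background draw (`noise_prob`): noise
adds spurious presences but never removes a disease, matching the notion
of observing a disease in a patient outside its cluster. Hence the
observed in-cluster marginal is p + q − pq, and same-cluster pairwise
co-occurrence follows the bivariate-normal orthant probability at latent
correlation ρ — both are verified against closed forms in the test suite
at N = 10⁵ with 3σ Monte-Carlo bands.

The cohort size N per simulated dataset is a package default (2,000),
chosen so cluster sizes stay well above K after the multimorbidity filter
while replicate sweeps remain cheap; it is configurable everywhere.

**Multimorbidity filter.** Downstream analyses concern patients with two
or more conditions; `filter_multimorbid` drops rows with fewer than two
presences (preserving order and subsetting the true labels). At the
default p = 0.15 with ~5 diseases per cluster only roughly a fifth of
patients pass the filter — cluster recovery is then evaluated on exactly
the population to which it would be applied.

## Clustering algorithms

All four assign every patient to exactly one cluster and are
deterministic given their `random_state`.

* **Latent class analysis** — a K-component mixture of conditionally
  independent Bernoulli variables fitted by EM. Defaults: 10 random
  restarts (keeping the best log-likelihood), convergence at relative
  log-likelihood change below 1e−6, at most 500 iterations
  (non-convergence is a warning, not an error), item probabilities floored
  to [1e−6, 1−1e−6] and class weights floored at 1e−6 against degenerate
  classes. Patients take the class with the highest posterior probability.
  Model selection tabulates BIC = −2ℓ + m·log N, sample-size-adjusted
  BIC = −2ℓ + m·log((N+2)/24) with m = (K−1) + K·D, and the relative
  entropy diagnostic E = 1 − [−Σᵢₖ p_ik log p_ik]/(N log K), scaled so 1
  means perfectly certain assignment (defined as 1 at K = 1).
* **Binary k-means** — Lloyd iterations on the raw 0/1 matrix (via
  scikit-learn), initial centroids drawn as k observations without
  replacement, 10 restarts, best inertia kept; empty clusters are
  re-seeded from the points contributing most inertia (scikit-learn's
  relocation rule).
* **MCA + k-means** — correspondence-analysis SVD of the complete
  disjunctive table (each condition expanded to a present/absent pair;
  constant columns carry no chi-square inertia and are dropped with a
  warning), then k-means on the row principal coordinates. By default
  K − 1 components are retained — the subspace sufficient to separate K
  centroids; `n_components="inertia"` instead keeps the dimensions
  covering ≥ 80% of Benzécri-corrected inertia. The CA identity (total
  non-trivial inertia = (J − Q)/Q) is asserted in tests.
* **k-means → Ward hybrid** — hierarchical clustering of every patient is
  quadratic in N, so k-means first reduces the cohort to 50 centroids,
  Ward agglomeration (squared-update "Ward.D2"-style recurrence, via
  scipy) merges the centroids, the dendrogram is cut at K, and each
  patient inherits its centroid's cluster. Centroid distances are
  Euclidean by default: the asymmetric binary (Jaccard) distance is
  defined on binary profiles, and binarising fractional centroids
  discards information; `centroid_metric="asymmetric_binary"` (threshold
  0.5) is available for sensitivity analysis.

The asymmetric binary distance 1 − |A∩B|/|A∪B| ignores joint absences;
for two all-zero profiles the ratio is undefined and the distance is
defined as 0 with a warning (the supports are identical), keeping the
function total on unfiltered data.

Ties anywhere (equal restart likelihoods, equal greedy correlations) are
broken by lowest index so repeated runs are identical.

## Evaluation

* **Adjusted Rand Index** (Hubert–Arabie, contingency-table form),
  reported unclamped: chance-level agreement can be slightly negative
  even though the nominal range is described as 0–1. Equivalence with the
  exhaustive pair-counting definition is asserted over all partitions of
  up to 8 items into ≤ 3 blocks, and against scikit-learn independently.
* **Greedy profile matching**: all Pearson correlations between the two
  partitions' within-cluster prevalence profiles; the globally best pair
  is matched and removed, repeatedly, stopping at the threshold (default
  0.5). Zero-variance profile rows have undefined correlation and are
  reported unmatched rather than assigned 0.
* **Bootstrap stability** (default 400 resamples): rows resampled with
  replacement, the clusterer refitted (fresh derived seed per resample),
  the bootstrap profile matched back to the original partition (original
  clusters as the reference, at the original K); per original cluster the
  mean/SD of matched correlations and the count of matched samples are
  reported. Un-clusterable resamples are skipped and counted.
* **Exclusivity** (share of a disease's carriers in each cluster; columns
  sum to 1) and **O/E ratio** (within-cluster over overall prevalence;
  size-weighted cluster average 1) satisfy their partition identities
  exactly and flag zero-carrier diseases as missing. Clusters are named
  by the top-3 conditions with the greatest within-cluster excess
  prevalence, ties alphabetical.

## Scenario runner

Sweeps one of ρ, noise, within-cluster prevalence, or the requested K
(generator fixed at 4 true clusters for the K sweep, and requested K
equal to the true K for the generator sweeps). Default grids:
ρ ∈ {0.3, 0.5, 0.7, 0.9}, noise ∈ {0.005, 0.02, 0.04, 0.08, 0.15},
p ∈ {0.015, 0.05, 0.15, 0.30, 0.50, 0.75, 0.90}, K ∈ {2..6}. Each sweep
cell runs `n_replicates` independent replicates (package default 100 for
desk-scale runs; 1,000 is the full protocol) with individually recorded
child seeds, so any replicate is re-runnable in isolation and results are
independent of execution order. Summaries are median and quartiles of the
aRI per algorithm; cells with more than 10% failed replicates are flagged
unreliable.

The test suite runs the sweeps at 100 replicates of N = 2,000; these
problem sizes are the package's reduced-scale defaults, and the observed
behaviours (aRI rising with ρ and prevalence, collapsing when noise
reaches the within-cluster prevalence, peaking at the true K, and
degrading sharply when non-multimorbid patients are included) are stable
at this scale.

## Synthetic EHR cohort

`generate_ehr` emulates a primary-care multimorbidity snapshot: 49
conditions with fixed marginal prevalences (hypertension 56.7% down to
hyperthyroidism 1.1%) for a default 23,251 patients, sampled through a
Gaussian copula whose latent correlation is the identity plus planted
blocks — a diabetes/erectile-dysfunction/hypertension group and a
heart-disease group at latent 0.4, and two strong pairs, aneurysm–PVD at
0.95 and diabetes–ED at 0.8. The pair values are chosen from the
bivariate-orthant relation so the *observed* phi correlations exceed 0.5
at those marginals (phi crosses 0.5 at latent ≈ 0.745 for the
diabetes–ED marginals; for the rare aneurysm–PVD pair the attainable phi
is capped near 0.55, hence the high latent value). Overlapping blocks
take the pairwise maximum; a non-positive-definite assembly is repaired
by eigenvalue clipping with a warning (or rejected in strict mode).

This generator is synthetic scaffolding: marginals and the planted blocks
are calibrated, but real records carry ascertainment bias, coding
artefacts and a full dependence structure that it does not model. The
prevalence targets describe an already-filtered multimorbid cohort, while
the copula applies them pre-filter, so post-filter marginals drift
upward; calibration tests therefore run pre-filter. Passing tests show
the pipeline's mechanics and calibration, not fidelity to any real
population.

## Known limitations

* The simulator draws one shared correlation ρ for all clusters and a
  single within-cluster prevalence; real disease clusters are
  heterogeneous in both.
* aRI medians for k-means at low ρ sit on a bimodal replicate
  distribution (the algorithm either finds or merges the planted
  clusters), so median differences carry a few hundredths of
  seed-to-seed variation at 100 replicates.
* Hard modal assignment discards the LCA posterior's uncertainty;
  entropy is reported so users can judge how much is lost.
* Cross-sectional binary snapshots only: no onset times, covariates or
  longitudinal structure.
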