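"""Generative simulator of correlated binary disease cohorts with known clusters.

The generator produces an ``N x D`` binary disease matrix in three steps:

1. each patient is assigned to one of ``K`` disease clusters, with cluster
   probabilities either drawn once as normalised exponential(lambda) weights
   or uniform (balanced);
2. each cluster receives a set of diseases of size ``max(Poisson(mean), min)``,
   drawn with or without overlap between clusters;
3. each patient's binary disease vector is generated from a multivariate
   probit model: a zero-mean latent Gaussian vector with an equicorrelated
   block (correlation ``rho``) over the patient's cluster diseases,
   thresholded so that each in-cluster disease has marginal probability
   ``within_prevalence``; diseases outside the cluster are absent before
   noise.  Finally each cell is independently OR-ed with a
   Bernoulli(``noise_prob``) background observation.

Because downstream analyses concern multimorbidity, a filter retaining only
patients with two or more conditions is provided and applied by the
experiment runners before clustering.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .cohort import BinaryCohort
from .exceptions import EmptyCohortError, InvalidConfigError

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "assign_patients_to_clusters",
    "assign_diseases_to_clusters",
    "build_correlation_matrix",
    "sample_disease_matrix",
    "add_noise",
    "filter_multimorbid",
    "generate",
]


def _default_condition_names(n: int) -> list[str]:
    """Diseases are labelled A..Z for up to 26 columns, D1..Dn beyond."""
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [f"D{i + 1}" for i in range(n)]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort.

    Attributes
    ----------
    n_patients : int
        Cohort size N before any multimorbidity filtering (default 2,000).
    n_clusters : int
        Number of true disease clusters K.
    n_diseases : int
        Number of disease columns D (default 26).
    weight_mode : {"exponential", "uniform"}
        Cluster membership probabilities: normalised exponential(lambda)
        draws, or balanced 1/K.
    weight_lambda : float
        Rate of the exponential weight draws (default 1).
    diseases_per_cluster_mean : float
        Poisson mean for the per-cluster disease count (default 5).
    diseases_per_cluster_min : int
        Lower bound on the per-cluster disease count (default 2).
    allow_overlap : bool
        Whether a disease may belong to several clusters.
    rho : float
        Latent equicorrelation among a cluster's diseases, in [0, 1).
    within_prevalence : float
        Marginal probability of each in-cluster disease for cluster
        members, before noise.
    noise_prob : float
        Background probability of a spurious disease observation, OR-ed
        into every cell.
    fraction_unclustered : float
        Fraction of patients belonging to no cluster (all their diseases
        arise from noise); label 0.  Default 0.
    seed : int
        Root seed; the whole generation is reproducible from it.
    """

    n_patients: int = 2000
    n_clusters: int = 3
    n_diseases: int = 26
    weight_mode: str = "exponential"
    weight_lambda: float = 1.0
    diseases_per_cluster_mean: float = 5.0
    diseases_per_cluster_min: int = 2
    allow_overlap: bool = True
    rho: float = 0.5
    within_prevalence: float = 0.15
    noise_prob: float = 0.005
    fraction_unclustered: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_clusters < 1 or self.n_diseases < 1:
            raise InvalidConfigError("n_patients, n_clusters, n_diseases must be >= 1")
        if self.weight_mode not in ("exponential", "uniform"):
            raise InvalidConfigError(f"unknown weight_mode {self.weight_mode!r}")
        if self.weight_lambda <= 0:
            raise InvalidConfigError("weight_lambda must be positive")
        if self.diseases_per_cluster_min < 1:
            raise InvalidConfigError("diseases_per_cluster_min must be >= 1")
        if not 0 <= self.rho < 1:
            raise InvalidConfigError("rho must lie in [0, 1)")
        if not 0 < self.within_prevalence < 1:
            raise InvalidConfigError("within_prevalence must lie in (0, 1)")
        if not 0 <= self.noise_prob < 1:
            raise InvalidConfigError("noise_prob must lie in [0, 1)")
        if not 0 <= self.fraction_unclustered < 1:
            raise InvalidConfigError("fraction_unclustered must lie in [0, 1)")
        if (not self.allow_overlap
                and self.n_diseases < self.n_clusters * self.diseases_per_cluster_min):
            raise InvalidConfigError(
                "disjoint assignment infeasible: "
                f"{self.n_diseases} diseases < {self.n_clusters} clusters x "
                f"min {self.diseases_per_cluster_min}"
            )

    # flat key: value round-trip, e.g. for scenario configuration files
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def replace(self, **changes) -> "SimConfig":
        return replace(self, **changes)


@dataclass
class SimulatedCohort:
    """A generated cohort together with its ground truth.

    ``true_labels`` holds the per-patient cluster index in 1..K (0 for
    unclustered patients when ``fraction_unclustered > 0``);
    ``disease_map`` maps each cluster index to the disease columns planted
    in it.
    """

    cohort: BinaryCohort
    true_labels: np.ndarray
    disease_map: Dict[int, np.ndarray]
    config: SimConfig

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels)
        if len(self.true_labels) != self.cohort.n_patients:
            raise ValueError("label vector length must equal the number of rows")

    def save(self, directory: str | Path, stem: str = "cohort") -> None:
        """Write the matrix as CSV plus a structured-text sidecar with the
        true labels, disease map and generating configuration."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(directory / f"{stem}.csv")
        sidecar = {
            "true_labels": self.true_labels.tolist(),
            "disease_map": {int(k): np.asarray(v).tolist()
                            for k, v in self.disease_map.items()},
            "config": asdict(self.config),
        }
        (directory / f"{stem}.truth.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path, stem: str = "cohort") -> "SimulatedCohort":
        directory = Path(directory)
        cohort = BinaryCohort.from_csv(directory / f"{stem}.csv")
        sidecar = json.loads((directory / f"{stem}.truth.json").read_text())
        return cls(
            cohort=cohort,
            true_labels=np.asarray(sidecar["true_labels"]),
            disease_map={int(k): np.asarray(v)
                         for k, v in sidecar["disease_map"].items()},
            config=SimConfig(**sidecar["config"]),
        )


# ---------------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------------

def assign_patients_to_clusters(
    n_patients: int,
    n_clusters: int,
    weight_mode: str = "exponential",
    weight_lambda: float = 1.0,
    rng: np.random.Generator | None = None,
    return_weights: bool = False,
):
    """Assign each patient to one of ``n_clusters`` clusters.

    Under ``exponential`` mode one exponential(lambda) draw per cluster is
    normalised into a probability vector; under ``uniform`` mode every
    cluster has probability 1/K.  Returns labels in 1..K (and the weight
    vector when ``return_weights`` is set).
    """
    if n_patients < 1 or n_clusters < 1:
        raise InvalidConfigError("need at least one patient and one cluster")
    rng = np.random.default_rng(rng)
    if weight_mode == "exponential":
        weights = rng.exponential(scale=1.0 / weight_lambda, size=n_clusters)
        weights = weights / weights.sum()
    elif weight_mode == "uniform":
        weights = np.full(n_clusters, 1.0 / n_clusters)
    else:
        raise InvalidConfigError(f"unknown weight_mode {weight_mode!r}")
    labels = rng.choice(n_clusters, size=n_patients, p=weights) + 1
    if return_weights:
        return labels, weights
    return labels


def assign_diseases_to_clusters(
    n_diseases: int,
    n_clusters: int,
    mean: float = 5.0,
    minimum: int = 2,
    allow_overlap: bool = True,
    rng: np.random.Generator | None = None,
) -> Dict[int, np.ndarray]:
    """Draw each cluster's disease set, of size ``max(Poisson(mean), minimum)``.

    Without overlap, clusters draw disjoint sets sequentially without
    replacement; a cluster hitting an exhausted pool is truncated to the
    remaining diseases, and the configuration is rejected if fewer than
    ``minimum`` remain.  With overlap, sets are drawn independently.
    """
    rng = np.random.default_rng(rng)
    if not allow_overlap and n_diseases < n_clusters * minimum:
        raise InvalidConfigError("disjoint disease assignment infeasible")
    counts = np.maximum(rng.poisson(mean, size=n_clusters), minimum)
    counts = np.minimum(counts, n_diseases)
    disease_map: Dict[int, np.ndarray] = {}
    if allow_overlap:
        for k in range(n_clusters):
            disease_map[k + 1] = np.sort(
                rng.choice(n_diseases, size=counts[k], replace=False))
    else:
        pool = np.arange(n_diseases)
        for k in range(n_clusters):
            take = min(counts[k], len(pool))
            if take < minimum:
                raise InvalidConfigError(
                    f"disease pool exhausted at cluster {k + 1}: "
                    f"{len(pool)} left, minimum {minimum}")
            chosen = rng.choice(len(pool), size=take, replace=False)
            disease_map[k + 1] = np.sort(pool[chosen])
            pool = np.delete(pool, chosen)
    return disease_map


def build_correlation_matrix(
    disease_set: Sequence[int], rho: float, n_diseases: int
) -> np.ndarray:
    """A D x D identity with an equicorrelated block of value ``rho`` over
    ``disease_set``.  Rejects values outside the positive-definite range
    (-1/(m-1), 1) for a block of size m."""
    disease_set = np.asarray(disease_set)
    m = len(disease_set)
    if m > 1 and not (-1.0 / (m - 1) < rho < 1.0):
        raise InvalidConfigError(
            f"rho={rho} gives a non-positive-definite {m}x{m} block")
    corr = np.eye(n_diseases)
    ix = np.ix_(disease_set, disease_set)
    block = np.full((m, m), rho)
    np.fill_diagonal(block, 1.0)
    corr[ix] = block
    return corr


def sample_disease_matrix(
    labels: np.ndarray,
    disease_map: Mapping[int, np.ndarray],
    within_prevalence: float,
    rho: float,
    n_diseases: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multivariate-probit sampling of the pre-noise disease matrix.

    For a patient in cluster k, a latent Gaussian vector with the cluster's
    equicorrelated block is thresholded at ``Phi^-1(1 - p)`` over the
    cluster's diseases (p = ``within_prevalence``); all other diseases have
    threshold +inf, i.e. are absent before noise.  Unclustered patients
    (label 0) get an all-zero row.

    For rho >= 0 the equicorrelated latent vector is sampled exactly via
    the one-factor decomposition sqrt(rho)*Z0 + sqrt(1-rho)*Z_d.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    if not 0 <= rho < 1:
        raise InvalidConfigError("rho must lie in [0, 1) for probit sampling")
    threshold = norm.ppf(1.0 - within_prevalence)
    X = np.zeros((len(labels), n_diseases), dtype=np.int8)
    for k, diseases in disease_map.items():
        members = np.flatnonzero(labels == k)
        if len(members) == 0:
            continue
        m = len(diseases)
        shared = rng.standard_normal(size=(len(members), 1))
        own = rng.standard_normal(size=(len(members), m))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        X[np.ix_(members, diseases)] = (latent > threshold).astype(np.int8)
    return X


def add_noise(
    matrix: np.ndarray, noise_prob: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """OR each cell with an independent Bernoulli(``noise_prob``) draw.

    Noise only ever adds spurious disease observations; a present disease
    is never removed.
    """
    if not 0 <= noise_prob < 1:
        raise InvalidConfigError("noise_prob must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    if noise_prob == 0:
        return matrix.copy()
    noise = rng.random(matrix.shape) < noise_prob
    return (matrix.astype(bool) | noise).astype(np.int8)


def filter_multimorbid(cohort):
    """Retain only patients with two or more conditions, preserving row order.

    Accepts a :class:`~morbiclust.cohort.BinaryCohort` or a
    :class:`SimulatedCohort` (whose true labels are subset consistently)
    and returns the same type.  Raises :class:`EmptyCohortError` when no
    patient remains.
    """
    if isinstance(cohort, SimulatedCohort):
        keep = cohort.cohort.condition_counts() >= 2
        if not keep.any():
            raise EmptyCohortError("no multimorbid patient remains after filtering")
        return SimulatedCohort(
            cohort=cohort.cohort.subset(keep),
            true_labels=cohort.true_labels[keep],
            disease_map=cohort.disease_map,
            config=cohort.config,
        )
    keep = cohort.condition_counts() >= 2
    if not keep.any():
        raise EmptyCohortError("no multimorbid patient remains after filtering")
    return cohort.subset(keep)


def generate(config: SimConfig) -> SimulatedCohort:
    """Run the full three-step generator for one configuration.

    Deterministic given ``config.seed``; the returned object records the
    true labels and the disease->cluster map for downstream evaluation.
    The multimorbidity filter is *not* applied here.
    """
    rng = np.random.default_rng(config.seed)
    labels = assign_patients_to_clusters(
        config.n_patients, config.n_clusters, config.weight_mode,
        config.weight_lambda, rng)
    if config.fraction_unclustered > 0:
        unclustered = rng.random(config.n_patients) < config.fraction_unclustered
        labels = np.where(unclustered, 0, labels)
    disease_map = assign_diseases_to_clusters(
        config.n_diseases, config.n_clusters, config.diseases_per_cluster_mean,
        config.diseases_per_cluster_min, config.allow_overlap, rng)
    X = sample_disease_matrix(
        labels, disease_map, config.within_prevalence, config.rho,
        config.n_diseases, rng)
    X = add_noise(X, config.noise_prob, rng)
    cohort = BinaryCohort(X, _default_condition_names(config.n_diseases))
    return SimulatedCohort(cohort=cohort, true_labels=labels,
                           disease_map=disease_map, config=config)
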