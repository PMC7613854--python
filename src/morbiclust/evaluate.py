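"""Partition comparison and cluster-stability machinery.

Covers the adjusted Rand Index, within-cluster morbidity profiles, greedy
one-to-one profile matching by Pearson correlation, bootstrap stability,
exclusivity and observed/expected prevalence ratios, and prevalence-based
cluster naming.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone

from .cohort import BinaryCohort, validate_binary_matrix

__all__ = [
    "adjusted_rand_index", "morbidity_profile", "greedy_match", "MatchTable",
    "bootstrap_stability", "StabilityReport", "exclusivity", "oe_ratio",
    "name_clusters",
]

logger = logging.getLogger(__name__)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand Index between two partitions.

    Chance-corrected pair-counting agreement: 1 for identical partitions
    (up to relabelling), expectation 0 under independent random labelling.
    Values are reported unclamped, so worse-than-chance agreement can be
    slightly negative.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 observations")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n_a, n_b = ai.max() + 1, bi.max() + 1
    contingency = np.bincount(ai * n_b + bi, minlength=n_a * n_b).reshape(n_a, n_b)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial and in agreement
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _as_matrix(cohort) -> Tuple[np.ndarray, list]:
    if isinstance(cohort, BinaryCohort):
        return cohort.matrix.astype(float), list(cohort.condition_names)
    X = validate_binary_matrix(cohort)
    return X, list(range(X.shape[1]))


def morbidity_profile(cohort, labels) -> pd.DataFrame:
    """Within-cluster morbidity profile: proportion of patients with each
    condition in each cluster (clusters x conditions)."""
    X, names = _as_matrix(cohort)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match the number of patients")
    clusters = np.unique(labels)
    rows = []
    for k in clusters:
        members = labels == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        rows.append(X[members].mean(axis=0))
    return pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"),
                        columns=names)


@dataclass
class MatchTable:
    """Greedy one-to-one pairing of clusters across two partitions.

    ``pairs`` lists (cluster in A, cluster in B, Pearson r) in greedy
    selection order, hence with non-increasing correlation; clusters whose
    best remaining correlation fell at or below ``threshold`` are
    unmatched.
    """

    pairs: List[Tuple[object, object, float]]
    unmatched_a: List[object] = field(default_factory=list)
    unmatched_b: List[object] = field(default_factory=list)
    threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["cluster_a", "cluster_b", "pcc"])

    def pcc_for_b(self) -> Dict[object, float]:
        """Map each matched cluster of profile B to its correlation."""
        return {b: pcc for _, b, pcc in self.pairs}


def greedy_match(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                 threshold: float = 0.5) -> MatchTable:
    """Match clusters across two morbidity profiles greedily by Pearson r.

    All pairwise correlations between profile rows are computed; the
    globally best pair is selected and both clusters removed, repeatedly,
    stopping when the best remaining correlation is <= ``threshold``.
    Equal correlations are broken by lowest (row, column) index pair.
    Zero-variance profile rows have undefined correlation and are reported
    unmatched with a warning.
    """
    if list(profile_a.columns) != list(profile_b.columns):
        raise ValueError("profiles must be over the same condition set")
    A = profile_a.to_numpy(dtype=float)
    B = profile_b.to_numpy(dtype=float)
    a_idx = list(profile_a.index)
    b_idx = list(profile_b.index)
    degen_a = [i for i in range(len(a_idx)) if A[i].std() == 0]
    degen_b = [j for j in range(len(b_idx)) if B[j].std() == 0]
    if degen_a or degen_b:
        warnings.warn("zero-variance profile row(s); treated as unmatched",
                      UserWarning)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(A, B)[: len(a_idx), len(a_idx):]
    corr[degen_a, :] = -np.inf
    corr[:, degen_b] = -np.inf
    corr = np.nan_to_num(corr, nan=-np.inf)

    pairs: List[Tuple[object, object, float]] = []
    free_a = set(range(len(a_idx)))
    free_b = set(range(len(b_idx)))
    while free_a and free_b:
        best = None
        for i in sorted(free_a):
            for j in sorted(free_b):
                if best is None or corr[i, j] > best[2]:
                    best = (i, j, corr[i, j])
        if best is None or best[2] <= threshold:
            break
        pairs.append((a_idx[best[0]], b_idx[best[1]], float(best[2])))
        free_a.discard(best[0])
        free_b.discard(best[1])
    return MatchTable(
        pairs=pairs,
        unmatched_a=[a_idx[i] for i in sorted(free_a)],
        unmatched_b=[b_idx[j] for j in sorted(free_b)],
        threshold=threshold,
    )


@dataclass
class StabilityReport:
    """Bootstrap stability of one partition.

    ``table`` has one row per original cluster with the mean and SD of the
    matched Pearson correlation over bootstrap samples where that cluster
    had a similar counterpart (correlation above threshold), and the count
    of such samples.
    """

    table: pd.DataFrame
    n_boot: int
    n_failed: int = 0
    threshold: float = 0.5


def bootstrap_stability(cohort, clusterer, n_boot: int = 400,
                        threshold: float = 0.5, random_state: int | None = None,
                        labels=None, resample: bool = True) -> StabilityReport:
    """Assess cluster stability over bootstrap resamples of the cohort.

    The clusterer is fitted to the original cohort (unless reference
    ``labels`` are given) and then refitted to ``n_boot`` resamples of the
    rows drawn with replacement; each bootstrap partition's morbidity
    profile is greedily matched to the original profile (original clusters
    as the reference).  Resamples the clusterer fails on are skipped and
    counted in ``n_failed``.

    ``resample=False`` is a pipeline diagnostic: every "resample" is the
    unmodified cohort, so a deterministic clusterer must yield mean
    correlation 1 and SD 0 for every cluster.
    """
    X, names = _as_matrix(cohort)
    ss = np.random.SeedSequence(random_state)
    rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = ss.generate_state(n_boot + 1) & 0x7FFFFFFF
    if labels is None:
        ref = clone(clusterer)
        if "random_state" in ref.get_params():
            ref.set_params(random_state=int(fit_seeds[0]))
        labels = ref.fit(X).labels_
    labels = np.asarray(labels)
    orig_profile = morbidity_profile(cohort, labels)
    clusters = list(orig_profile.index)
    matched: Dict[object, List[float]] = {k: [] for k in clusters}
    n_failed = 0
    n = X.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        est = clone(clusterer)
        if "random_state" in est.get_params():
            seed = fit_seeds[b + 1] if resample else fit_seeds[0]
            est.set_params(random_state=int(seed))
        try:
            boot_labels = est.fit(X[idx]).labels_
            boot_profile = morbidity_profile(X[idx], boot_labels)
            boot_profile.columns = orig_profile.columns
            table = greedy_match(boot_profile, orig_profile, threshold)
        except Exception as err:  # un-clusterable resample
            n_failed += 1
            logger.warning("bootstrap sample %d skipped: %s", b, err)
            continue
        for k, pcc in table.pcc_for_b().items():
            matched[k].append(pcc)
    rows = []
    for k in clusters:
        pccs = np.asarray(matched[k])
        rows.append({
            "cluster": k,
            "mean_pcc": pccs.mean() if len(pccs) else np.nan,
            "sd_pcc": pccs.std(ddof=1) if len(pccs) > 1 else
                      (0.0 if len(pccs) == 1 else np.nan),
            "n_matched": len(pccs),
            "n_boot": n_boot,
        })
    return StabilityReport(table=pd.DataFrame(rows).set_index("cluster"),
                           n_boot=n_boot, n_failed=n_failed, threshold=threshold)


def exclusivity(cohort, labels) -> pd.DataFrame:
    """Share of each condition's carriers falling in each cluster.

    Entry (k, d) = count(condition d present AND cluster k) / count(d
    present).  Columns sum to 1 over clusters for every condition with at
    least one carrier; conditions nobody has are NaN.
    """
    X, names = _as_matrix(cohort)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    carriers = X.sum(axis=0)
    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in clusters:
            rows.append(X[labels == k].sum(axis=0) / carriers)
    out = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"),
                       columns=names)
    return out.where(np.isfinite(out))


def oe_ratio(cohort, labels) -> pd.DataFrame:
    """Observed/expected ratio: within-cluster prevalence of each
    condition divided by its overall prevalence (NaN for conditions nobody
    has).  The cluster-size-weighted average over clusters is 1 for every
    condition."""
    X, names = _as_matrix(cohort)
    overall = X.mean(axis=0)
    profile = morbidity_profile(cohort, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = profile / overall
    return out.where(np.isfinite(out))


def name_clusters(profile: pd.DataFrame, overall_prevalence, top: int = 3
                  ) -> Dict[object, List[str]]:
    """Name clusters by their ``top`` conditions with the greatest excess
    of within-cluster prevalence over overall prevalence (ties broken
    alphabetically)."""
    overall = np.asarray(overall_prevalence, dtype=float)
    if len(overall) != profile.shape[1]:
        raise ValueError("overall prevalence length must match profile columns")
    names = {}
    cols = [str(c) for c in profile.columns]
    for k in profile.index:
        diff = profile.loc[k].to_numpy() - overall
        order = sorted(range(len(cols)), key=lambda i: (-diff[i], cols[i]))
        names[k] = [cols[i] for i in order[:top]]
    return names
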