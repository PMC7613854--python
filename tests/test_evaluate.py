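"""Evaluation machinery: aRI, profiles, greedy matching, bootstrap
stability, exclusivity / O-E identities and cluster naming."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score

from morbiclust import (BinaryCohort, BinaryKMeans, MatchTable,
                        adjusted_rand_index, bootstrap_stability, exclusivity,
                        greedy_match, morbidity_profile, name_clusters,
                        oe_ratio)


def pair_counting_ari(a, b):
    """Independent oracle: aRI from exhaustive pair agreement counts."""
    a, b = np.asarray(a), np.asarray(b)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa and not sb:
            n10 += 1
        elif sb and not sa:
            n01 += 1
        else:
            n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


class TestAdjustedRandIndex:
    def test_identical_partitions_give_one(self, rng):
        labels = rng.integers(0, 3, size=30)
        assert adjusted_rand_index(labels, labels) == 1.0

    def test_relabeling_invariance(self, rng):
        labels = rng.integers(0, 4, size=40)
        renamed = np.array([{0: 7, 1: 2, 2: 9, 3: 0}[x] for x in labels])
        assert adjusted_rand_index(labels, renamed) == 1.0

    def test_hand_example_matches_pair_counting(self):
        a, b = (1, 1, 2, 2), (1, 2, 1, 2)
        assert np.isclose(adjusted_rand_index(a, b), pair_counting_ari(a, b))

    def test_matches_oracle_on_random_partitions(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            assert np.isclose(adjusted_rand_index(a, b),
                              pair_counting_ari(a, b), atol=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(50):
            a = rng.integers(0, 5, size=100)
            b = rng.integers(0, 4, size=100)
            assert np.isclose(adjusted_rand_index(a, b),
                              adjusted_rand_score(a, b), atol=1e-12)

    def test_random_labeling_mean_near_zero(self, rng):
        fixed = rng.integers(0, 3, size=60)
        aris = [adjusted_rand_index(fixed, rng.integers(0, 3, size=60))
                for _ in range(1000)]
        assert abs(np.mean(aris)) < 0.02

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestMorbidityProfile:
    def test_single_cluster_equals_overall_prevalence(self, planted_two_block):
        cohort, _ = planted_two_block
        profile = morbidity_profile(cohort, np.zeros(cohort.n_patients))
        np.testing.assert_allclose(profile.iloc[0].to_numpy(),
                                   cohort.prevalence.to_numpy())

    def test_size_weighted_rows_give_overall(self, planted_two_block):
        cohort, truth = planted_two_block
        profile = morbidity_profile(cohort, truth)
        sizes = np.bincount(truth) / len(truth)
        weighted = sizes @ profile.to_numpy()
        np.testing.assert_allclose(weighted, cohort.prevalence.to_numpy())

    def test_planted_prevalences_recovered(self, planted_two_block):
        cohort, truth = planted_two_block
        profile = morbidity_profile(cohort, truth).to_numpy()
        planted = np.array([[0.9] * 5 + [0.1] * 5, [0.1] * 5 + [0.9] * 5])
        se = np.sqrt(planted * (1 - planted) / 200)
        assert np.all(np.abs(profile - planted) < 4 * se)


class TestGreedyMatch:
    def test_identity_matches_everything_at_one(self):
        profile = pd.DataFrame(np.random.default_rng(1).random((3, 8)))
        table = greedy_match(profile, profile.copy())
        assert all(a == b for a, b, _ in table.pairs)
        assert all(np.isclose(p, 1.0) for *_, p in table.pairs)
        assert not table.unmatched_a and not table.unmatched_b

    def test_greedy_exclusion_hand_example(self, monkeypatch):
        """pcc matrix [[0.9, 0.2], [0.8, 0.7]]: after (A1,B1) is taken,
        (A2,B1)=0.8 is blocked, so (A2,B2)=0.7 is selected."""
        import morbiclust.evaluate as ev
        rng = np.random.default_rng(4)
        profile = pd.DataFrame(rng.random((2, 4)), index=["A1", "A2"])
        other = pd.DataFrame(rng.random((2, 4)), index=["B1", "B2"])
        target = np.array([[0.9, 0.2], [0.8, 0.7]])
        monkeypatch.setattr(
            ev.np, "corrcoef",
            lambda A, B: np.block([[np.eye(2), target],
                                   [target.T, np.eye(2)]]))
        table = ev.greedy_match(profile, other)
        assert [(a, b, round(p, 2)) for a, b, p in table.pairs] == \
               [("A1", "B1", 0.9), ("A2", "B2", 0.7)]

    def test_all_below_threshold_unmatched(self):
        a = pd.DataFrame([[1.0, 0.0, 0.5, 0.2]], index=["A1"])
        b = pd.DataFrame([[0.0, 1.0, 0.2, 0.5]], index=["B1"])
        table = greedy_match(a, b, threshold=0.5)
        assert table.pairs == []
        assert table.unmatched_a == ["A1"] and table.unmatched_b == ["B1"]

    def test_pcc_sequence_non_increasing_and_injective(self, rng):
        a = pd.DataFrame(rng.random((4, 20)))
        b = pd.DataFrame(rng.random((5, 20)))
        table = greedy_match(a, b, threshold=-1.1)
        pccs = [p for *_, p in table.pairs]
        assert all(x >= y for x, y in zip(pccs, pccs[1:]))
        assert len({p[0] for p in table.pairs}) == len(table.pairs)
        assert len({p[1] for p in table.pairs}) == len(table.pairs)

    def test_zero_variance_row_unmatched_with_warning(self):
        a = pd.DataFrame([[0.3, 0.3, 0.3], [0.9, 0.1, 0.5]], index=["A1", "A2"])
        b = pd.DataFrame([[0.9, 0.1, 0.5], [0.8, 0.2, 0.4]], index=["B1", "B2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            table = greedy_match(a, b)
        assert "A1" in table.unmatched_a


class _FixedLabels(ClusterMixin, BaseEstimator):
    """Degenerate clusterer returning a fixed alternating partition."""

    def __init__(self, k: int = 2, random_state=None):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        self.labels_ = np.arange(len(X)) % self.k
        return self


class TestBootstrapStability:
    def test_degenerate_clusterer_always_matches(self, rng):
        # heterogeneous prevalences, so every subset's profile mirrors them
        probs = np.linspace(0.05, 0.9, 12)
        cohort = BinaryCohort((rng.random((400, 12)) < probs).astype(int),
                              [f"c{i}" for i in range(12)])
        report = bootstrap_stability(cohort, _FixedLabels(k=2), n_boot=20,
                                     random_state=0)
        assert (report.table["n_matched"] == 20).all()
        assert (report.table["mean_pcc"] > 0.95).all()

    def test_zero_boot_empty_report(self, planted_two_block):
        cohort, _ = planted_two_block
        report = bootstrap_stability(cohort, _FixedLabels(k=2), n_boot=0,
                                     random_state=0)
        assert (report.table["n_matched"] == 0).all()
        assert report.table["mean_pcc"].isna().all()

    def test_identity_resamples_give_perfect_stability(self, planted_two_block):
        """With the unmodified cohort substituted for every resample, a
        deterministic clusterer yields mean pcc 1 and SD 0."""
        cohort, _ = planted_two_block
        est = BinaryKMeans(n_clusters=2, random_state=0)
        report = bootstrap_stability(cohort, est, n_boot=8, random_state=0,
                                     resample=False)
        np.testing.assert_allclose(report.table["mean_pcc"], 1.0, atol=1e-12)
        np.testing.assert_allclose(report.table["sd_pcc"], 0.0, atol=1e-12)
        assert (report.table["n_matched"] == 8).all()

    def test_stable_simulation_all_matched(self, small_sim):
        """Strongly separated clusters are recovered in every bootstrap
        sample with near-perfect profile correlation."""
        from morbiclust import LatentClassAnalysis
        est = LatentClassAnalysis(n_classes=3, n_restarts=3, random_state=0)
        report = bootstrap_stability(small_sim.cohort, est, n_boot=25,
                                     random_state=1)
        assert (report.table["n_matched"] == 25).all()
        assert (report.table["mean_pcc"] > 0.99).all()


class TestExclusivityAndOE:
    def test_single_cluster_all_ones(self, planted_two_block):
        cohort, _ = planted_two_block
        excl = exclusivity(cohort, np.zeros(cohort.n_patients))
        assert np.allclose(excl.dropna(axis=1).to_numpy(), 1.0)
        oe = oe_ratio(cohort, np.zeros(cohort.n_patients))
        assert np.allclose(oe.dropna(axis=1).to_numpy(), 1.0)

    def test_exclusivity_columns_sum_to_one(self, planted_two_block):
        cohort, truth = planted_two_block
        excl = exclusivity(cohort, truth)
        sums = excl.sum(axis=0, skipna=False).dropna()
        np.testing.assert_allclose(sums, 1.0)

    def test_exclusive_disease_fully_in_its_cluster(self):
        X = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]])
        labels = np.array([1, 1, 2, 2])
        excl = exclusivity(BinaryCohort(X, ["a", "b", "x"]), labels)
        assert excl.loc[2, "x"] == 1.0 and excl.loc[1, "x"] == 0.0

    def test_oe_size_weighted_average_is_one(self, planted_two_block):
        cohort, truth = planted_two_block
        oe = oe_ratio(cohort, truth)
        weights = np.bincount(truth) / len(truth)
        np.testing.assert_allclose(weights @ oe.to_numpy(), 1.0)

    def test_oe_direct_arithmetic(self):
        # disease at 10% overall and 30% in the first cluster: O/E = 3
        X = np.zeros((100, 2), dtype=int)
        X[:, 1] = 1  # keep no zero-carrier columns in play
        X[:9, 0] = 1
        X[90, 0] = 1
        labels = np.array([1] * 30 + [2] * 70)
        oe = oe_ratio(BinaryCohort(X, ["d", "pad"]), labels)
        assert np.isclose(oe.loc[1, "d"], 3.0)

    def test_zero_carrier_condition_is_nan(self):
        X = np.array([[1, 0], [1, 0], [1, 0]])
        excl = exclusivity(BinaryCohort(X, ["a", "none"]), [1, 1, 2])
        assert excl["none"].isna().all()


class TestNameClusters:
    def test_hand_sorted_differences(self):
        profile = pd.DataFrame(
            [[0.5, 0.4, 0.2, 0.0]], index=[1],
            columns=["diabetes", "ed", "hyp", "other"])
        overall = [0.1, 0.1, 0.1, 0.2]
        names = name_clusters(profile, overall, top=3)
        assert names[1] == ["diabetes", "ed", "hyp"]

    def test_ties_broken_alphabetically(self):
        profile = pd.DataFrame([[0.3, 0.3, 0.3]], index=[0],
                               columns=["c", "a", "b"])
        names = name_clusters(profile, [0.1, 0.1, 0.1], top=2)
        assert names[0] == ["a", "b"]

    def test_invariant_to_column_order(self, planted_two_block):
        cohort, truth = planted_two_block
        profile = morbidity_profile(cohort, truth)
        overall = cohort.prevalence.to_numpy()
        names = name_clusters(profile, overall)
        perm = np.random.default_rng(2).permutation(profile.shape[1])
        names_perm = name_clusters(profile.iloc[:, perm], overall[perm])
        assert names == names_perm
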