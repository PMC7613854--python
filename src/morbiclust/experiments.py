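"""Scenario runner: parameter sweeps over simulated cohorts and the
end-to-end real-cohort analysis pipeline.

A :class:`Scenario` sweeps one generator parameter (``rho``,
``noise_prob``, ``within_prevalence``) or the number of clusters the
algorithms are asked to find (``requested_k``), running many independent
replicate simulations per sweep value and summarising the adjusted Rand
Index against the known labels as median and quartiles per algorithm.

Replicates are seeded individually from the scenario seed, so any single
replicate can be re-run in isolation to the identical result, and results
do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cluster import ALGORITHMS, make_clusterer
from .cohort import BinaryCohort
from .evaluate import (StabilityReport, adjusted_rand_index, bootstrap_stability,
                       exclusivity, greedy_match, morbidity_profile,
                       name_clusters, oe_ratio)
from .lca import lca_selection
from .simulate import SimConfig, filter_multimorbid, generate

__all__ = ["Scenario", "ScenarioResult", "run_replicate", "run_scenario",
           "run_ehr_pipeline", "EHRReport", "plot_scenario"]

_SWEEPABLE = ("rho", "noise_prob", "within_prevalence", "requested_k")

# grids covering the studied ranges: correlation 0.3-0.9, noise up to the
# within-cluster prevalence, prevalence 1.5%-90%, requested K around truth
DEFAULT_GRIDS = {
    "rho": [0.3, 0.5, 0.7, 0.9],
    "noise_prob": [0.005, 0.02, 0.04, 0.08, 0.15],
    "within_prevalence": [0.015, 0.05, 0.15, 0.30, 0.50, 0.75, 0.90],
    "requested_k": [2, 3, 4, 5, 6],
}


@dataclass
class Scenario:
    """One parameter sweep over replicate simulated cohorts."""

    base: SimConfig = field(default_factory=SimConfig)
    sweep_parameter: str = "rho"
    sweep_values: Sequence = None  # type: ignore[assignment]
    algorithms: Sequence[str] = ALGORITHMS
    n_replicates: int = 100
    include_non_multimorbid: bool = False
    requested_k: Optional[int] = None  # None -> the generator's true K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_parameter not in _SWEEPABLE:
            raise ValueError(f"sweep_parameter must be one of {_SWEEPABLE}")
        if self.sweep_values is None:
            self.sweep_values = DEFAULT_GRIDS[self.sweep_parameter]
        self.sweep_values = list(self.sweep_values)
        if not self.sweep_values:
            raise ValueError("sweep_values must be non-empty")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        self.algorithms = list(self.algorithms)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["base"] = asdict(self.base)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        doc = yaml.safe_load(Path(path).read_text())
        doc["base"] = SimConfig(**doc.get("base", {}))
        return cls(**doc)


@dataclass
class ScenarioResult:
    """Aggregated sweep output plus the per-replicate seed ledger."""

    table: pd.DataFrame           # sweep_value x algorithm medians/quartiles
    replicates: pd.DataFrame      # tidy per-replicate aRI values with seeds
    scenario: Scenario


def run_replicate(config: SimConfig, algorithms: Sequence[str] = ALGORITHMS,
                  requested_k: Optional[int] = None,
                  multimorbid_only: bool = True,
                  seed: Optional[int] = None) -> Dict[str, float]:
    """Generate one cohort, cluster it with each algorithm, and score each
    partition against the true labels with the adjusted Rand Index.

    The aRI is computed on the retained rows (after the multimorbidity
    filter when ``multimorbid_only``).  An algorithm failing on this
    replicate yields NaN rather than aborting the sweep.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(1 + len(algorithms)) & 0x7FFFFFFF
    sim = generate(config.replace(seed=int(child[0])))
    if multimorbid_only:
        sim = filter_multimorbid(sim)
    k = requested_k if requested_k is not None else config.n_clusters
    out: Dict[str, float] = {}
    for i, name in enumerate(algorithms):
        try:
            est = make_clusterer(name, k, random_state=int(child[i + 1]))
            labels = est.fit(sim.cohort).labels_
            out[name] = adjusted_rand_index(labels, sim.true_labels)
        except Exception:
            out[name] = np.nan
    return out


def run_scenario(scenario: Scenario) -> ScenarioResult:
    """Run all sweep values x replicates and aggregate median/quartile aRI.

    Cells where more than 10% of replicates failed are flagged
    ``unreliable`` in the summary table.
    """
    seeds = (np.random.SeedSequence(scenario.seed)
             .generate_state(len(scenario.sweep_values) * scenario.n_replicates)
             & 0x7FFFFFFF)
    seeds = seeds.reshape(len(scenario.sweep_values), scenario.n_replicates)
    records = []
    for vi, value in enumerate(scenario.sweep_values):
        if scenario.sweep_parameter == "requested_k":
            config = scenario.base
            requested_k = int(value)
        else:
            config = scenario.base.replace(**{scenario.sweep_parameter: value})
            requested_k = scenario.requested_k
        for r in range(scenario.n_replicates):
            aris = run_replicate(
                config, scenario.algorithms, requested_k=requested_k,
                multimorbid_only=not scenario.include_non_multimorbid,
                seed=int(seeds[vi, r]))
            for name, ari in aris.items():
                records.append({
                    "sweep_value": value, "replicate": r,
                    "seed": int(seeds[vi, r]), "algorithm": name, "ari": ari,
                })
    replicates = pd.DataFrame.from_records(records)
    rows = []
    for (value, name), grp in replicates.groupby(["sweep_value", "algorithm"],
                                                 sort=False):
        ari = grp["ari"]
        n_failed = int(ari.isna().sum())
        rows.append({
            "sweep_value": value, "algorithm": name,
            "median_ari": ari.median(), "q1_ari": ari.quantile(0.25),
            "q3_ari": ari.quantile(0.75),
            "n_replicates": len(grp), "n_failed": n_failed,
            "unreliable": n_failed > 0.1 * len(grp),
        })
    return ScenarioResult(table=pd.DataFrame(rows), replicates=replicates,
                          scenario=scenario)


def plot_scenario(result: ScenarioResult, ax=None):
    """Median aRI with interquartile error bars per algorithm across the
    sweep (optional convenience; returns the matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, grp in result.table.groupby("algorithm", sort=False):
        x = np.asarray(grp["sweep_value"], dtype=float)
        med = grp["median_ari"].to_numpy()
        err = np.vstack([med - grp["q1_ari"], grp["q3_ari"] - med])
        ax.errorbar(x, med, yerr=np.clip(err, 0, None), marker="o",
                    capsize=3, label=name)
    ax.set_xlabel(result.scenario.sweep_parameter)
    ax.set_ylabel("adjusted Rand Index")
    ax.legend()
    return ax


@dataclass
class EHRReport:
    """Full multi-algorithm analysis of one (real or synthetic) cohort."""

    selection: pd.DataFrame                      # LCA diagnostics per K
    labels: Dict[str, np.ndarray]                # per-algorithm partitions
    cross_ari: pd.DataFrame                      # algorithm x algorithm aRI
    profiles: Dict[str, pd.DataFrame]
    cross_match: Dict[tuple, "object"]           # (alg_a, alg_b) -> MatchTable
    shared_members: pd.DataFrame                 # matched-pair membership overlap
    stability: Dict[str, StabilityReport]
    cluster_names: Dict[str, Dict]
    exclusivity: Dict[str, pd.DataFrame]
    oe: Dict[str, pd.DataFrame]
    chosen_k: int


def run_ehr_pipeline(cohort: BinaryCohort, k_range=range(2, 9), chosen_k: int = 4,
                     seed: int = 0, n_boot: int = 400,
                     algorithms: Sequence[str] = ALGORITHMS,
                     lca_n_restarts: int = 10) -> EHRReport:
    """Apply the whole analysis battery to one binary cohort.

    The multimorbidity filter is applied first; then LCA model selection
    over ``k_range``; all requested algorithms at ``chosen_k``; the
    cross-algorithm aRI matrix; greedy morbidity-profile matching and
    shared-membership counts for every algorithm pair; per-algorithm
    bootstrap stability; and cluster naming, exclusivity and O/E exports.
    """
    cohort = filter_multimorbid(cohort)
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 + 2 * len(algorithms)) & 0x7FFFFFFF
    selection, _ = lca_selection(cohort, k_range, n_restarts=lca_n_restarts,
                                 random_state=int(child[0]))

    labels: Dict[str, np.ndarray] = {}
    estimators = {}
    for i, name in enumerate(algorithms):
        est = make_clusterer(name, chosen_k, random_state=int(child[2 + i]))
        labels[name] = est.fit(cohort).labels_
        estimators[name] = est

    algs = list(algorithms)
    cross = pd.DataFrame(np.eye(len(algs)), index=algs, columns=algs)
    for i, a in enumerate(algs):
        for j, b in enumerate(algs):
            if j > i:
                cross.iloc[i, j] = cross.iloc[j, i] = adjusted_rand_index(
                    labels[a], labels[b])

    profiles = {name: morbidity_profile(cohort, lab)
                for name, lab in labels.items()}
    overall = cohort.prevalence.to_numpy()
    cross_match = {}
    shared_rows = []
    for i, a in enumerate(algs):
        for b in algs[i + 1:]:
            table = greedy_match(profiles[a], profiles[b])
            cross_match[(a, b)] = table
            for ka, kb, pcc in table.pairs:
                in_a = labels[a] == ka
                in_b = labels[b] == kb
                shared_rows.append({
                    "algorithm_a": a, "cluster_a": ka,
                    "algorithm_b": b, "cluster_b": kb, "pcc": pcc,
                    "n_a": int(in_a.sum()), "n_b": int(in_b.sum()),
                    "n_shared": int((in_a & in_b).sum()),
                })
    shared = pd.DataFrame(shared_rows)

    stability = {}
    for i, name in enumerate(algs):
        est = make_clusterer(name, chosen_k,
                             random_state=int(child[2 + len(algs) + i]))
        stability[name] = bootstrap_stability(
            cohort, est, n_boot=n_boot, labels=labels[name],
            random_state=int(child[1]))

    cluster_names = {name: name_clusters(profiles[name], overall)
                     for name in algs}
    excl = {name: exclusivity(cohort, lab) for name, lab in labels.items()}
    oe = {name: oe_ratio(cohort, lab) for name, lab in labels.items()}
    return EHRReport(selection=selection, labels=labels, cross_ari=cross,
                     profiles=profiles, cross_match=cross_match,
                     shared_members=shared, stability=stability,
                     cluster_names=cluster_names, exclusivity=excl, oe=oe,
                     chosen_k=chosen_k)
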