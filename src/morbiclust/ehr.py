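"""Synthetic EHR-like cohort generator.

Produces a binary cohort of 49 long-term health conditions whose marginal
prevalences default to those observed in UK primary care records of men
aged 65--84 with multimorbidity, with a small number of planted correlated
condition blocks (a cardiometabolic diabetes/erectile-dysfunction/
hypertension group, a heart-disease group, and two strongly correlated
pairs: aortic aneurysm with peripheral vascular disease, and diabetes with
erectile dysfunction).

Sampling uses a Gaussian copula: a latent multivariate normal vector with
a block-structured correlation matrix is thresholded per condition at
``Phi^-1(1 - prevalence)``, so marginals match the prevalence table
exactly in expectation while planted pairs carry the configured latent
correlation.  This is synthetic scaffolding for exercising the analysis
pipeline end to end; beyond the marginals and the planted blocks it makes
no claim of distributional fidelity to any real cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import BinaryCohort
from .exceptions import InvalidConfigError
from .simulate import filter_multimorbid

__all__ = ["CONDITION_PREVALENCE", "DEFAULT_BLOCKS", "EHRSynthConfig",
           "generate_ehr", "summarize_cohort"]

# Default marginal prevalences (fractions) for the 49 conditions, as
# observed in multimorbid men aged 65-84 in UK primary care.
CONDITION_PREVALENCE: Dict[str, float] = {
    "Hyp": 0.567, "ED": 0.360, "OA": 0.278, "Diab": 0.246, "IHD": 0.245,
    "Deaf": 0.222, "Can": 0.217, "BPH": 0.194, "Ecz": 0.184, "CKD": 0.154,
    "Dep": 0.148, "Asth": 0.144, "Gout": 0.143, "AF": 0.134, "Cat": 0.127,
    "Stroke": 0.116, "COPD": 0.110, "Div": 0.106, "Rhin": 0.101,
    "Anx": 0.097, "PVD": 0.081, "Pep": 0.071, "HF": 0.069, "Psor": 0.065,
    "Sinus": 0.056, "Hypothy": 0.055, "Glau": 0.047, "IBS": 0.047,
    "Valve": 0.043, "Mig": 0.042, "Addict": 0.040, "Tissue": 0.040,
    "VTE": 0.034, "OSA": 0.030, "Osteo": 0.027, "Aneu": 0.026,
    "Bowel": 0.026, "Dem": 0.025, "Auto.oth": 0.024, "Epi": 0.022,
    "PE": 0.021, "AMD": 0.018, "Blind": 0.018, "Liver": 0.016,
    "SMI": 0.013, "Bronc": 0.013, "Park": 0.012, "Oth.heart": 0.012,
    "Hyperthy": 0.011,
}

# planted latent-correlation blocks: two clinically coherent groups at a
# moderate correlation, plus the two pairs whose observed (phi)
# correlation should exceed 0.5; latent values chosen from the bivariate
# orthant relation at the respective marginals
DEFAULT_BLOCKS: List[Tuple[Tuple[str, ...], float]] = [
    (("Diab", "ED", "Hyp"), 0.40),
    (("HF", "IHD", "AF", "Oth.heart", "Valve"), 0.40),
    (("Aneu", "PVD"), 0.95),
    (("Diab", "ED"), 0.80),
]


@dataclass
class EHRSynthConfig:
    """Configuration of the synthetic EHR cohort.

    ``blocks`` entries are (condition names, latent correlation); a pair
    appearing in several blocks takes the largest configured value.  With
    ``strict=True`` a non-positive-definite assembled correlation matrix
    is an error instead of being repaired.
    """

    n_patients: int = 23251
    prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(CONDITION_PREVALENCE))
    blocks: Sequence[Tuple[Tuple[str, ...], float]] = field(
        default_factory=lambda: list(DEFAULT_BLOCKS))
    multimorbid_only: bool = True
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        for name, p in self.prevalence.items():
            if not 0 < p < 1:
                raise InvalidConfigError(f"prevalence of {name} must be in (0, 1)")
        known = set(self.prevalence)
        for conditions, rho in self.blocks:
            unknown = set(conditions) - known
            if unknown:
                raise InvalidConfigError(f"block references unknown conditions "
                                         f"{sorted(unknown)}")
            m = len(conditions)
            if m > 1 and not (-1.0 / (m - 1) < rho < 1.0):
                raise InvalidConfigError(
                    f"block correlation {rho} infeasible for size {m}")


def _assemble_correlation(config: EHRSynthConfig) -> np.ndarray:
    names = list(config.prevalence)
    index = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for conditions, rho in config.blocks:
        ix = [index[c] for c in conditions]
        for a in ix:
            for b in ix:
                if a != b:
                    corr[a, b] = max(corr[a, b], rho)
    eigval = np.linalg.eigvalsh(corr)
    if eigval.min() <= 1e-10:
        if config.strict:
            raise InvalidConfigError(
                "assembled correlation matrix is not positive-definite")
        warnings.warn("assembled correlation matrix repaired to nearest "
                      "positive-definite", UserWarning)
        w, v = np.linalg.eigh(corr)
        corr = (v * np.clip(w, 1e-8, None)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def generate_ehr(config: EHRSynthConfig | None = None) -> BinaryCohort:
    """Sample the synthetic cohort (Gaussian copula, then by default the
    multimorbidity filter).  Deterministic given ``config.seed``."""
    config = config or EHRSynthConfig()
    names = list(config.prevalence)
    p = np.array([config.prevalence[n] for n in names])
    corr = _assemble_correlation(config)
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((config.n_patients, len(names))) @ chol.T
    X = (latent > norm.ppf(1.0 - p)).astype(np.int8)
    cohort = BinaryCohort(X, names)
    if config.multimorbid_only:
        cohort = filter_multimorbid(cohort)
    return cohort


def summarize_cohort(cohort: BinaryCohort) -> dict:
    """Calibration summary: per-condition prevalence and the distribution
    of per-patient condition counts."""
    counts = pd.Series(cohort.condition_counts())
    return {
        "prevalence": cohort.prevalence,
        "condition_count_median": float(counts.median()),
        "condition_count_q1": float(counts.quantile(0.25)),
        "condition_count_q3": float(counts.quantile(0.75)),
        "condition_counts": counts.value_counts().sort_index(),
    }
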