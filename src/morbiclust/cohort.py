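"""Binary patient x condition cohorts.

The universal input of every clusterer and evaluation metric in this
package is a cross-sectional snapshot of long-term health conditions: a
0/1 matrix with one row per patient and one column per condition, plus
ordered condition names and patient identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class BinaryCohort:
    """A patients x conditions presence/absence matrix.

    Parameters
    ----------
    matrix : ndarray of shape (n_patients, n_conditions)
        Entries must be exactly 0 or 1.
    condition_names : sequence of str
        Ordered column labels.
    patient_ids : sequence of str
        Ordered row identifiers; generated as ``P000001`` ... when omitted.
    """

    matrix: np.ndarray
    condition_names: Sequence[str]
    patient_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("cohort matrix must be 2-dimensional")
        values = np.unique(self.matrix)
        if not np.isin(values, [0, 1]).all():
            raise ValueError("cohort matrix entries must be exactly 0 or 1")
        self.matrix = self.matrix.astype(np.int8, copy=False)
        self.condition_names = list(self.condition_names)
        if len(self.condition_names) != self.matrix.shape[1]:
            raise ValueError(
                f"{len(self.condition_names)} condition names for "
                f"{self.matrix.shape[1]} columns"
            )
        if self.patient_ids is None:
            self.patient_ids = [f"P{i + 1:06d}" for i in range(self.matrix.shape[0])]
        else:
            self.patient_ids = list(self.patient_ids)
        if len(self.patient_ids) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.patient_ids)} patient ids for "
                f"{self.matrix.shape[0]} rows"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[1]

    @property
    def prevalence(self) -> pd.Series:
        """Per-condition marginal prevalence."""
        return pd.Series(
            self.matrix.mean(axis=0), index=self.condition_names, name="prevalence"
        )

    def condition_counts(self) -> np.ndarray:
        """Number of conditions present per patient (row sums)."""
        return self.matrix.sum(axis=1)

    def subset(self, rows: np.ndarray) -> "BinaryCohort":
        """Row-subset preserving order; ``rows`` is a boolean mask or index array."""
        rows = np.asarray(rows)
        ids = np.asarray(self.patient_ids, dtype=object)[rows]
        return BinaryCohort(self.matrix[rows], self.condition_names, list(ids))

    # -- round-trips ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.condition_names,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinaryCohort":
        return cls(frame.to_numpy(), list(frame.columns), [str(i) for i in frame.index])

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text: header of condition names, first column patient ID."""
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinaryCohort":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame)


def validate_binary_matrix(X) -> np.ndarray:
    """Coerce clusterer input (BinaryCohort, DataFrame or array) to a
    validated 0/1 float array."""
    if isinstance(X, BinaryCohort):
        X = X.matrix
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-d patients x conditions matrix")
    if not np.isin(np.unique(X), [0, 1]).all():
        raise ValueError("expected a binary (0/1) matrix")
    return X.astype(float, copy=False)
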