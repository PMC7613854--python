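"""Multiple correspondence analysis of binary condition data.

Each condition is expanded into a present/absent indicator pair (the
complete disjunctive table), and a correspondence-analysis SVD of the
centred, chi-square-weighted table yields row principal coordinates.  For
Q binary variables with J = 2Q categories the total non-trivial inertia is
(J - Q)/Q = 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import validate_binary_matrix


class MCA(TransformerMixin, BaseEstimator):
    """Multiple correspondence analysis on a 0/1 condition matrix.

    Parameters
    ----------
    n_components : int, default=2
        Number of non-trivial dimensions to retain; clipped (with a
        warning) to the number available.

    Attributes
    ----------
    eigenvalues_ : ndarray
        Principal inertias (squared singular values) of the retained
        dimensions.
    explained_inertia_ : ndarray
        Eigenvalues as shares of the total inertia (J - Q)/Q.
    kept_columns_ : ndarray
        Indices of the non-constant input columns actually analysed;
        constant columns carry no chi-square inertia and are dropped with
        a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def _indicator(self, X: np.ndarray) -> np.ndarray:
        # present/absent pair per condition: [x, 1-x] interleaved
        n, q = X.shape
        Z = np.empty((n, 2 * q))
        Z[:, 0::2] = X
        Z[:, 1::2] = 1.0 - X
        return Z

    def fit(self, X, y=None):
        X = validate_binary_matrix(X)
        col_var = X.var(axis=0)
        keep = col_var > 0
        if not keep.all():
            warnings.warn(
                f"dropping {np.sum(~keep)} constant condition column(s) from MCA",
                UserWarning)
        if not keep.any():
            raise ValueError("all condition columns are constant; MCA undefined")
        self.kept_columns_ = np.flatnonzero(keep)
        Z = self._indicator(X[:, keep])
        n, j = Z.shape
        q = j // 2
        P = Z / Z.sum()
        r = P.sum(axis=1)            # uniform: each row sums to q
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, s, Vt = np.linalg.svd(S, full_matrices=False)
        # the trivial dimension is removed by the centring; discard
        # numerically-zero tail dimensions as well
        nontrivial = s > 1e-12
        U, s, Vt = U[:, nontrivial], s[nontrivial], Vt[nontrivial]
        available = len(s)
        n_comp = self.n_components
        if n_comp > available:
            warnings.warn(
                f"n_components={n_comp} exceeds the {available} available "
                "dimensions; clipping", UserWarning)
            n_comp = available
        self.n_components_ = n_comp
        self.row_masses_ = r
        self.col_masses_ = c
        self.eigenvalues_ = s[:n_comp] ** 2
        self.total_inertia_ = (j - q) / q
        self.explained_inertia_ = self.eigenvalues_ / self.total_inertia_
        # column standard coordinates used to project (new) rows
        self._col_std_coords = Vt[:n_comp].T / np.sqrt(c)[:, None]
        self._singular_values = s[:n_comp]
        return self

    def transform(self, X) -> np.ndarray:
        """Row principal coordinates of ``X`` (supplementary-row formula
        for data not seen at fit time)."""
        check_is_fitted(self, "kept_columns_")
        X = validate_binary_matrix(X)
        Z = self._indicator(X[:, self.kept_columns_])
        profiles = Z / Z.sum(axis=1, keepdims=True)
        # centring term vanishes: sqrt(col masses) spans the trivial axis
        return profiles @ self._col_std_coords

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
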