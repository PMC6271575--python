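"""Correlation-matrix PCA of binary feature columns.

Unlike the rank-weighted similarity used for classification, ordination
works on the plain Pearson correlation matrix of the feature columns:
eigenvalues sum to the number of variables, each factor's share of
variance is lambda / n_vars, and the *profile* re-expresses each factor
as the percentage contribution of every variable (100 x squared
loading, rows summing to 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import PropertyVector

__all__ = ["PcaResult", "pca_correlation", "pca_profile"]


@dataclass
class PcaResult:
    """Eigenstructure of a correlation matrix, factors in decaying order."""

    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: np.ndarray  # variables x factors, unit-norm columns
    scores: np.ndarray  # items x factors
    variable_names: tuple[str, ...]
    factor_names: tuple[str, ...]

    @property
    def n_factors(self) -> int:
        return len(self.eigenvalues)

    def unexplained_pct(self, n_factors: int) -> float:
        """Variance left unexplained when keeping the first n factors."""
        return float(100.0 - self.cumulative_pct[n_factors - 1])


def pca_correlation(
    columns: Sequence[PropertyVector] | np.ndarray,
    variable_names: Sequence[str] | None = None,
) -> PcaResult:
    """PCA of the Pearson correlation matrix of an items x variables table.

    Accepts the item fingerprints (one vector per item; positions become
    variables) or any numeric 2-D array. Eigenvectors are oriented so
    that each one's largest-magnitude element is positive; scores are
    the standardized columns (mean 0, sd 1 with denominator n-1)
    projected onto the eigenvectors.

    Raises if any column has zero variance — its correlations are
    undefined and would silently distort the eigenstructure.
    """
    if isinstance(columns, np.ndarray):
        x = np.asarray(columns, dtype=float)
    else:
        x = np.stack([v.as_array() for v in columns]).astype(float)
    n_items, n_vars = x.shape
    if n_vars < 2:
        raise ValueError("need at least two variables")
    names = (
        tuple(variable_names)
        if variable_names is not None
        else tuple(f"i{j+1}" for j in range(n_vars))
    )
    sd = x.std(axis=0, ddof=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance column(s): {', '.join(names[j] for j in dead)}")

    corr = np.corrcoef(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # orient: largest-magnitude element of each eigenvector positive
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(n_vars)])
    eigvec = eigvec * flip
    var_pct = 100.0 * eigval / eigval.sum()
    z = (x - x.mean(axis=0)) / sd
    return PcaResult(
        eigenvalues=eigval,
        variance_pct=var_pct,
        cumulative_pct=np.cumsum(var_pct),
        loadings=eigvec,
        scores=z @ eigvec,
        variable_names=names,
        factor_names=tuple(f"F{j+1}" for j in range(n_vars)),
    )


def pca_profile(res: PcaResult) -> np.ndarray:
    """Factor profile: profile[f, v] = 100 * loading[v, f]**2.

    Each row distributes a factor's unit norm over the variables, so
    rows sum to 100 and the table is invariant to eigenvector sign.
    """
    return 100.0 * (res.loadings.T**2)
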