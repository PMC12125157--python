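"""Ordination of species metal profiles by principal component analysis.

The metal concentration matrix (species x metal) is log(x+1) transformed
and standardized per metal, then decomposed by eigendecomposition of the
correlation-scaled covariance matrix.  Loadings with absolute value above
a threshold (0.7 by convention) mark the metals that define each
component.

The PCA itself is implemented from first principles on purpose — the
variance decomposition, the sign convention, and the loading-threshold
labelling are part of the tested surface, and external PCA routines serve
only as cross-checks in the test suite.

Numerical conventions: natural log for the log(x+1) transform (the base
only rescales columns before standardization, so the decomposition is
base-invariant); standardization and covariance both use the n-1
denominator; each loading vector's sign is fixed so its
largest-magnitude entry is positive, pinning the otherwise arbitrary
eigenvector sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .harmonize import SpeciesProfile
from .toxdata import METALS, Metal

STRONG_LOADING_THRESHOLD = 0.7


@dataclass(frozen=True)
class OrdinationResult:
    """PCA output: explained variance, loadings, and sample scores.

    ``variance_explained`` is in percent and sums to 100 over all
    components; components are ordered by decreasing eigenvalue;
    ``loadings`` columns are orthonormal.
    """

    variance_explained: np.ndarray  # (k,) percentages
    loadings: pd.DataFrame  # metal x component
    scores: pd.DataFrame  # sample x component
    eigenvalues: np.ndarray

    def strong_loadings(
        self, threshold: float = STRONG_LOADING_THRESHOLD
    ) -> dict[str, list[str]]:
        return label_clusters(self, threshold)


def transform(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """log(x+1) then per-column standardization (mean 0, sd 1, ddof=1).

    Constant columns cannot be scaled; they become all-zero and a warning
    is issued so the degeneracy is visible.
    """
    df = pd.DataFrame(matrix).astype(float)
    if (df.values < 0).any():
        raise ValueError("concentrations must be non-negative")
    logged = np.log1p(df)
    centered = logged - logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = list(df.columns[constant])
        warnings.warn(
            f"constant columns set to zero after standardization: {names}",
            stacklevel=2,
        )
        sd = sd.replace(0, 1.0)
    return centered / sd


def pca(transformed: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Eigendecomposition of the covariance of an already-transformed matrix."""
    df = pd.DataFrame(transformed).astype(float)
    x = df.to_numpy()
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError(f"need >=2 samples and >=2 variables, got {n}x{p}")
    if np.isnan(x).any():
        raise ValueError("missing cells must be removed upstream (listwise deletion)")

    cov = (x.T @ x) / (n - 1)  # x is column-centered by transform()
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # pin eigenvector signs: largest-|.| entry of each loading vector positive
    for j in range(p):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    total = eigvals.sum()
    variance = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    components = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(eigvecs, index=df.columns, columns=components)
    scores = pd.DataFrame(x @ eigvecs, index=df.index, columns=components)
    return OrdinationResult(
        variance_explained=variance,
        loadings=loadings,
        scores=scores,
        eigenvalues=eigvals,
    )


def label_clusters(
    result: OrdinationResult, threshold: float = STRONG_LOADING_THRESHOLD
) -> dict[str, list[str]]:
    """Metals whose |loading| strictly exceeds the threshold, per component."""
    out = {}
    for comp in result.loadings.columns:
        col = result.loadings[comp]
        out[comp] = [str(i) for i in col.index[np.abs(col.values) > threshold]]
    return out


def ordinate_profiles(
    profiles: Iterable[SpeciesProfile],
    metals: Sequence[Metal] = METALS,
) -> tuple[OrdinationResult, int]:
    """Transform + PCA over species profiles; rows with missing metals dropped.

    Returns the ordination and the number of listwise-deleted profiles.
    """
    rows, index = [], []
    dropped = 0
    for p in profiles:
        if all(m in p.conc for m in metals):
            rows.append([p.conc[m] for m in metals])
            index.append(f"{p.species} [{p.habitat.value}]")
        else:
            dropped += 1
    df = pd.DataFrame(rows, index=index, columns=[m.value for m in metals])
    return pca(transform(df)), dropped
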