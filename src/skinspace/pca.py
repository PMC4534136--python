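"""Mean-centering, covariance and eigendecomposition for hybrid-space PCA.

The pipeline is deliberately the explicit covariance route: center the data,
form the d x d sample covariance (n - 1 denominator), eigendecompose it with
a symmetric solver, and keep the top-k eigenvectors as loading rows.  No
variance scaling is applied (centering only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .skn import HybridSpace

__all__ = [
    "CenteredMatrix",
    "CovarianceMatrix",
    "PcaModel",
    "center",
    "covariance",
    "eigendecompose",
    "explained_variance",
    "make_space",
    "fit_pca",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class CenteredMatrix:
    """Column-centered data with the subtracted means recorded."""

    values: np.ndarray
    column_means: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        means = np.asarray(self.column_means, dtype=np.float64)
        if values.ndim != 2 or means.shape != (values.shape[1],):
            raise ValueError("values must be n x d with one mean per column")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "column_means", means)


@dataclass(frozen=True)
class CovarianceMatrix:
    cov: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=np.float64)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError("covariance must be square")
        asym = np.max(np.abs(cov - cov.T)) if cov.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"covariance asymmetric beyond tolerance ({asym:.3e})")
        object.__setattr__(self, "cov", (cov + cov.T) / 2.0)


@dataclass(frozen=True)
class PcaModel:
    """Eigenpairs of a component covariance, sorted by eigenvalue descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns paired with eigenvalues
    column_means: np.ndarray
    component_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.eigenvalues, dtype=np.float64)
        vecs = np.asarray(self.eigenvectors, dtype=np.float64)
        d = vals.shape[0]
        if vecs.shape != (d, d):
            raise ValueError("eigenvectors must be d x d")
        if np.any(np.diff(vals) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        object.__setattr__(self, "eigenvalues", vals)
        object.__setattr__(self, "eigenvectors", vecs)
        object.__setattr__(self, "column_means", np.asarray(self.column_means, dtype=np.float64))
        object.__setattr__(self, "component_ids", tuple(self.component_ids))

    @property
    def d(self) -> int:
        return self.eigenvalues.shape[0]


def center(matrix: np.ndarray) -> CenteredMatrix:
    """Subtract each column's mean; requires at least two rows."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to center")
    means = matrix.mean(axis=0)
    return CenteredMatrix(values=matrix - means, column_means=means)


def covariance(centered: CenteredMatrix) -> CovarianceMatrix:
    """Sample covariance of centered data (n - 1 denominator)."""
    v = centered.values
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows for a sample covariance")
    return CovarianceMatrix(cov=v.T @ v / (n - 1))


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude entry is positive.

    ``argmax`` returns the first maximal index, which breaks magnitude ties
    toward the lowest index.
    """
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def eigendecompose(
    cov: CovarianceMatrix | np.ndarray,
    column_means: np.ndarray | None = None,
    component_ids: Sequence[str] | None = None,
) -> PcaModel:
    """Eigendecompose a symmetric covariance into a :class:`PcaModel`."""
    if not isinstance(cov, CovarianceMatrix):
        cov = CovarianceMatrix(np.asarray(cov))
    vals, vecs = np.linalg.eigh(cov.cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], _fix_signs(vecs[:, order])
    d = vals.shape[0]
    if column_means is None:
        column_means = np.zeros(d)
    if component_ids is None:
        component_ids = tuple(f"c{i}" for i in range(d))
    return PcaModel(
        eigenvalues=vals,
        eigenvectors=vecs,
        column_means=np.asarray(column_means),
        component_ids=tuple(component_ids),
    )


def explained_variance(model: PcaModel, k: int) -> float:
    """Cumulative fraction of variance captured by the first k components."""
    if not 1 <= k <= model.d:
        raise ValueError(f"k must be in [1, {model.d}], got {k}")
    total = float(model.eigenvalues.sum())
    if total == 0.0:
        return 0.0
    if k == model.d:
        return 1.0
    return float(model.eigenvalues[:k].sum() / total)


def make_space(model: PcaModel, k: int = 3, name: str = "pca") -> HybridSpace:
    """Build a k-output hybrid space from the top-k principal components."""
    if not 1 <= k <= model.d:
        raise ValueError(f"k must be in [1, {model.d}], got {k}")
    return HybridSpace(
        component_ids=model.component_ids,
        means=model.column_means,
        loadings=model.eigenvectors[:, :k].T,
        name=name,
    )


def fit_pca(matrix: np.ndarray, component_ids: Sequence[str] | None = None) -> PcaModel:
    """Convenience: center -> covariance -> eigendecomposition."""
    c = center(matrix)
    return eigendecompose(covariance(c), c.column_means, component_ids)
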