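"""Principal component analysis of spectral matrices.

Computed by singular value decomposition of the mean-centered matrix,
which is numerically safer than eigendecomposition of the covariance on
long (3072-point) spectra.  The component sign is fixed by making the
largest-magnitude loading element positive, so repeated runs agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraMatrix, ValidationError

__all__ = ["PCAModel", "fit_pca", "project"]


@dataclass(frozen=True)
class PCAModel:
    n_components: int
    scores: np.ndarray               # n x k
    loadings: np.ndarray             # p x k, orthonormal columns
    explained_variance_pct: np.ndarray  # k, percent of total variance
    column_means: np.ndarray         # p
    singular_values: np.ndarray      # all min(n-1, p) singular values


def fit_pca(X: SpectraMatrix | np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA with ``n_components`` components on the centered matrix."""
    A = X.X if isinstance(X, SpectraMatrix) else np.asarray(X, dtype=float)
    n, p = A.shape
    k_max = min(n - 1, p)
    if not 1 <= n_components <= k_max:
        raise ValidationError(
            f"n_components={n_components} outside 1..{k_max} for {n}x{p} data"
        )
    means = A.mean(axis=0)
    U, s, Vt = np.linalg.svd(A - means, full_matrices=False)
    U, s, Vt = U[:, :k_max], s[:k_max], Vt[:k_max]
    # sign convention: largest-|.| element of each loading is positive
    flip = np.sign(Vt[np.arange(k_max), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    total = float(s @ s)
    if total == 0:
        raise ValidationError("matrix has zero variance after centering")
    evp = 100.0 * s**2 / total
    k = n_components
    return PCAModel(
        n_components=k,
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T.copy(),
        explained_variance_pct=evp[:k].copy(),
        column_means=means,
        singular_values=s.copy(),
    )


def project(model: PCAModel, X_new: SpectraMatrix | np.ndarray) -> np.ndarray:
    """Scores of new rows: (X_new - column_means) @ loadings."""
    A = np.asarray(X_new.X if isinstance(X_new, SpectraMatrix) else X_new,
                   dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    if A.shape[1] != model.column_means.size:
        raise ValidationError(
            f"grid mismatch: {A.shape[1]} columns vs model's "
            f"{model.column_means.size}"
        )
    return (A - model.column_means) @ model.loadings
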