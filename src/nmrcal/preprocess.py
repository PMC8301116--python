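"""Spectral pretreatments: SNV, MSC, mean-centering and ppm windowing.

The modeling pipeline applies pretreatments in a fixed order:
windowing -> (MSC | SNV | none) -> mean-centering.  Parameters that
depend on data (the MSC reference spectrum, the column means) are
learned on the calibration set only and reused for validation and
unknown samples, so external error estimates stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import SpectraMatrix, ValidationError

__all__ = [
    "WindowSet",
    "Pretreatment",
    "snv_transform",
    "msc_fit_transform",
    "msc_transform",
    "mean_center",
    "apply_windows",
]

_MSC_MIN_SLOPE = 1e-12


@dataclass(frozen=True)
class WindowSet:
    """Closed ppm intervals given as (high_ppm, low_ppm) pairs."""

    windows: tuple

    def __post_init__(self):
        pairs = tuple((float(h), float(l)) for h, l in self.windows)
        if not pairs:
            raise ValidationError("WindowSet needs at least one window")
        for h, l in pairs:
            if h <= l:
                raise ValidationError(
                    f"window ({h}, {l}): high_ppm must exceed low_ppm"
                )
        ordered = sorted(pairs, key=lambda w: -w[0])
        for (h1, l1), (h2, l2) in zip(ordered, ordered[1:]):
            if h2 > l1:
                raise ValidationError(
                    f"windows ({h1}, {l1}) and ({h2}, {l2}) overlap"
                )
        object.__setattr__(self, "windows", pairs)

    def mask(self, grid: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points falling inside any window."""
        grid = np.asarray(grid, dtype=float)
        m = np.zeros(grid.shape, dtype=bool)
        for h, l in self.windows:
            m |= (grid >= l) & (grid <= h)
        return m

    @classmethod
    def from_ranges(cls, ranges) -> "WindowSet":
        """Build from config-style ``[[high, low], ...]`` lists."""
        return cls(tuple((float(h), float(l)) for h, l in ranges))


def snv_transform(X: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: scale each row to mean 0, sd 1 (n-1)."""
    mu = X.X.mean(axis=1, keepdims=True)
    sd = X.X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValidationError(
            f"constant spectrum for sample {X.sample_ids[flat[0]]!r}: "
            "SNV undefined"
        )
    return SpectraMatrix(X.sample_ids, X.grid, (X.X - mu) / sd)


def _msc_correct(X: SpectraMatrix, reference: np.ndarray) -> SpectraMatrix:
    ref = np.asarray(reference, dtype=float)
    refc = ref - ref.mean()
    denom = refc @ refc
    if denom <= 0:
        raise ValidationError("MSC reference has zero variance")
    out = np.empty_like(X.X)
    for i, x in enumerate(X.X):
        # OLS of x on ref: slope b, intercept a; corrected row = (x - a)/b
        b = (x - x.mean()) @ refc / denom
        if abs(b) < _MSC_MIN_SLOPE:
            raise ValidationError(
                f"sample {X.sample_ids[i]!r}: near-zero MSC slope {b:.3g}"
            )
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return SpectraMatrix(X.sample_ids, X.grid, out)


def msc_fit_transform(X: SpectraMatrix, reference="mean"):
    """Multiplicative scatter correction.

    Each row is regressed on the reference spectrum (OLS) and the fitted
    affine distortion is inverted.  Returns the corrected matrix and the
    reference used, which must be stored to correct validation samples.
    ``reference="mean"`` uses the mean spectrum of ``X``.
    """
    if isinstance(reference, str) and reference == "mean":
        if X.n_samples < 2:
            raise ValidationError("MSC mean reference needs n >= 2 spectra")
        reference = X.X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.size != X.n_points:
        raise ValidationError("MSC reference length does not match the grid")
    return _msc_correct(X, reference), reference


def msc_transform(X: SpectraMatrix, reference: np.ndarray) -> SpectraMatrix:
    """Apply MSC with a previously fitted reference spectrum."""
    return _msc_correct(X, reference)


def mean_center(X: SpectraMatrix):
    """Column mean-centering; returns the centered matrix and the means."""
    if X.n_samples < 2:
        raise ValidationError("mean-centering needs n >= 2 samples")
    means = X.X.mean(axis=0)
    return SpectraMatrix(X.sample_ids, X.grid, X.X - means), means


def apply_windows(X: SpectraMatrix, w: WindowSet) -> SpectraMatrix:
    """Keep only grid columns inside the window set, preserving order."""
    m = w.mask(X.grid)
    if m.sum() < 2:
        raise ValidationError(
            f"windows {w.windows} select {int(m.sum())} grid points; "
            "need at least 2"
        )
    return SpectraMatrix(X.sample_ids, X.grid[m], X.X[:, m])


@dataclass(frozen=True)
class Pretreatment:
    """A fitted pretreatment: windowing plus optional MSC or SNV.

    ``kind`` is one of ``"none"``, ``"msc"``, ``"snv"``.  Mean-centering
    is always applied downstream by the PLS fit itself (which stores the
    calibration column means), so it is not duplicated here.
    """

    kind: str = "none"
    windows: WindowSet | None = None
    msc_reference: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind not in ("none", "msc", "snv"):
            raise ValidationError(f"unknown pretreatment kind {self.kind!r}")

    @property
    def fitted(self) -> bool:
        return self.kind != "msc" or self.msc_reference is not None

    def fit_transform(self, X: SpectraMatrix):
        """Fit on calibration data; returns (transformed, fitted self)."""
        if self.windows is not None:
            X = apply_windows(X, self.windows)
        if self.kind == "snv":
            return snv_transform(X), self
        if self.kind == "msc":
            Xt, ref = msc_fit_transform(X, "mean")
            return Xt, replace(self, msc_reference=ref)
        return X, self

    def transform(self, X: SpectraMatrix) -> SpectraMatrix:
        """Apply to validation/unknown samples with calibration parameters."""
        if not self.fitted:
            raise ValidationError("MSC pretreatment not fitted")
        if self.windows is not None:
            X = apply_windows(X, self.windows)
        if self.kind == "snv":
            return snv_transform(X)
        if self.kind == "msc":
            return msc_transform(X, self.msc_reference)
        return X

    def transform_array(self, A: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """Array-level :meth:`transform` for any number of rows (even one).

        Both SNV and MSC act on each row independently, so this is exact
        for single held-out samples during cross-validation.
        """
        if not self.fitted:
            raise ValidationError("MSC pretreatment not fitted")
        A = np.atleast_2d(np.asarray(A, dtype=float))
        if self.windows is not None:
            m = self.windows.mask(grid)
            if m.sum() < 2:
                raise ValidationError("windows select fewer than 2 points")
            A = A[:, m]
        if self.kind == "snv":
            sd = A.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0):
                raise ValidationError("constant row: SNV undefined")
            return (A - A.mean(axis=1, keepdims=True)) / sd
        if self.kind == "msc":
            ref = self.msc_reference
            refc = ref - ref.mean()
            denom = refc @ refc
            out = np.empty_like(A)
            for i, x in enumerate(A):
                b = (x - x.mean()) @ refc / denom
                if abs(b) < _MSC_MIN_SLOPE:
                    raise ValidationError(f"row {i}: near-zero MSC slope")
                out[i] = (x - (x.mean() - b * ref.mean())) / b
            return out
        return A
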