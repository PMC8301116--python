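"""PLS1 regression by NIPALS, leave-one-out cross-validation and VIP.

The calibration model is the classical latent-variable decomposition

    X = T P' + E_X        y = T q + e_y

fit one property at a time (PLS1).  NIPALS extracts components
sequentially: the weight vector w_a maximizes covariance between the
X-scores and the residual y, and X is deflated by the rank-one
approximation t_a p_a' after each component.  Predictions use the
equivalent regression vector

    B = W (P' W)^{-1} q,        y_hat = (X - x_mean) B + y_mean

so a fitted model is a single vector plus centering constants.

X and y are mean-centered internally with calibration means; the means
are stored so validation samples are centered consistently.  Component
signs are fixed by making the largest-magnitude element of each weight
vector positive, which makes fits reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import Pretreatment, WindowSet
from .spectra_io import SpectraMatrix, ValidationError

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "predict_spectra",
           "loo_cv", "select_n_lv", "vip_scores",
           "save_model", "load_model"]

_RANK_TOL = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 calibration for one property."""

    n_lv: int
    weights: np.ndarray        # p x a, unit columns
    x_loadings: np.ndarray     # p x a
    x_scores: np.ndarray       # n x a, mutually orthogonal columns
    y_loadings: np.ndarray     # a
    coef: np.ndarray           # p, regression vector B
    x_mean: np.ndarray         # p
    y_mean: float
    property_name: str = ""
    pretreatment: Pretreatment | None = field(default=None, compare=False)
    grid: np.ndarray | None = field(default=None, compare=False)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out cross-validation summary."""

    rmsecv_by_lv: np.ndarray   # RMSECV for 1..a_max latent variables
    chosen_lv: int
    r_cv: float                # Pearson r of LOO predictions at chosen_lv
    loo_predictions: np.ndarray     # LOO predictions at chosen_lv
    predictions_by_lv: np.ndarray   # n x a_max LOO predictions


def _as_array(X) -> np.ndarray:
    A = X.X if isinstance(X, SpectraMatrix) else np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    if not np.all(np.isfinite(A)):
        raise ValidationError("X contains non-finite values")
    return A


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int,
                 strict: bool = True):
    """Core NIPALS loop on centered data; returns (W, P, T, q).

    With ``strict=False``, extraction stops quietly once the residual
    X'y covariance vanishes (the data's effective rank is exhausted) and
    however many components were found are returned.
    """
    n, p = Xc.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    q = np.empty(n_lv)
    Xd = Xc.copy()
    yd = yc.copy()
    x_scale = np.linalg.norm(Xc) * np.linalg.norm(yc) + _RANK_TOL
    a = 0
    while a < n_lv:
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _RANK_TOL * x_scale:
            if strict:
                raise ValidationError(
                    f"component {a + 1}: residual covariance vanished; "
                    f"n_lv={n_lv} exceeds the effective rank"
                )
            break
        w /= nw
        # reproducible sign: largest-|.| weight element positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xd @ w
        tt = t @ t
        if tt <= _RANK_TOL:
            if strict:
                raise ValidationError(
                    f"component {a + 1}: zero score variance; rank exceeded"
                )
            break
        pa = Xd.T @ t / tt
        qa = (yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        a += 1
    if a == 0:
        raise ValidationError("X carries no covariance with y")
    return W[:, :a], P[:, :a], T[:, :a], q[:a]


def _coef_from_wpq(W, P, q) -> np.ndarray:
    # B = W (P'W)^{-1} q ; P'W is upper-triangular with unit diagonal
    a = q.size
    return W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])


def fit_pls(X, y, n_lv: int, property_name: str = "",
            pretreatment: Pretreatment | None = None,
            grid: np.ndarray | None = None,
            cap_to_rank: bool = False) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    ``X`` (matrix or :class:`SpectraMatrix`) must already carry any
    windowing and scatter correction; centering is done here.  If the
    data's effective rank is below ``n_lv`` this is an error unless
    ``cap_to_rank`` is set, in which case the model keeps as many
    components as the data supports.
    """
    A = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = A.shape
    if y.size != n:
        raise ValidationError(f"y has {y.size} values for {n} spectra")
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite values")
    if n_lv < 1:
        raise ValidationError("n_lv must be >= 1")
    if n < n_lv + 1:
        raise ValidationError(f"need n >= n_lv + 1 samples (n={n}, n_lv={n_lv})")
    if np.ptp(y) == 0:
        raise ValidationError("y is constant; nothing to calibrate")
    x_mean = A.mean(axis=0)
    y_mean = float(y.mean())
    W, P, T, q = _nipals_pls1(A - x_mean, y - y_mean, n_lv,
                              strict=not cap_to_rank)
    if isinstance(X, SpectraMatrix) and grid is None:
        grid = X.grid
    return PLSModel(n_lv=q.size, weights=W, x_loadings=P, x_scores=T,
                    y_loadings=q, coef=_coef_from_wpq(W, P, q),
                    x_mean=x_mean, y_mean=y_mean,
                    property_name=property_name,
                    pretreatment=pretreatment, grid=grid)


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict from pretreated spectra: (X - x_mean) B + y_mean."""
    A = X_new.X if isinstance(X_new, SpectraMatrix) else \
        np.atleast_2d(np.asarray(X_new, dtype=float))
    if A.shape[1] != model.coef.size:
        raise ValidationError(
            f"grid mismatch: {A.shape[1]} columns vs model's "
            f"{model.coef.size}"
        )
    return (A - model.x_mean) @ model.coef + model.y_mean


def predict_spectra(model: PLSModel, X_raw: SpectraMatrix) -> np.ndarray:
    """Predict from raw spectra, applying the stored pretreatment first."""
    if model.pretreatment is None:
        return predict(model, X_raw)
    A = model.pretreatment.transform_array(X_raw.X, X_raw.grid)
    return predict(model, A)


def loo_cv(X, y, a_max: int, pretreatment: Pretreatment | None = None,
           parsimony_tol: float = 0.02) -> CVResult:
    """Leave-one-out cross-validation over 1..a_max latent variables.

    For every left-out sample the pretreatment (if given) and the PLS
    model are refit from scratch on the remaining n-1 samples, so no
    information leaks from the held-out spectrum.  When a pretreatment
    is supplied, ``X`` must be the raw (untransformed) matrix.
    """
    raw = _as_array(X)
    grid = X.grid if isinstance(X, SpectraMatrix) else None
    y = np.asarray(y, dtype=float).ravel()
    n = raw.shape[0]
    if y.size != n:
        raise ValidationError("X and y lengths differ")
    if n < a_max + 2:
        raise ValidationError(f"need n >= a_max + 2 (n={n}, a_max={a_max})")
    preds = np.empty((n, a_max))
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = raw[keep], y[keep]
        xte = raw[i:i + 1]
        if pretreatment is not None:
            if grid is None:
                raise ValidationError(
                    "pretreatment in LOO requires a SpectraMatrix input"
                )
            sub = SpectraMatrix(
                tuple(f"s{j}" for j in np.flatnonzero(keep)), grid, Xtr)
            sub_t, fitted = pretreatment.fit_transform(sub)
            Xtr = sub_t.X
            xte = fitted.transform_array(xte, grid)
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, T, q = _nipals_pls1(Xtr - x_mean, ytr - y_mean, a_max,
                                  strict=False)
        for a in range(1, a_max + 1):
            a_eff = min(a, q.size)  # rank-exhausted folds stop improving
            B = _coef_from_wpq(W[:, :a_eff], P[:, :a_eff], q[:a_eff])
            preds[i, a - 1] = (xte[0] - x_mean) @ B + y_mean
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = select_n_lv_from_curve(rmsecv, parsimony_tol)
    loo_pred = preds[:, chosen - 1]
    r_cv = float(np.corrcoef(loo_pred, y)[0, 1])
    return CVResult(rmsecv_by_lv=rmsecv, chosen_lv=chosen, r_cv=r_cv,
                    loo_predictions=loo_pred, predictions_by_lv=preds)


def select_n_lv_from_curve(rmsecv_by_lv, parsimony_tol: float = 0.02) -> int:
    """Smallest LV count whose RMSECV is within ``parsimony_tol`` of the
    minimum.

    The bare argmin tends to overfit on small calibration sets; the
    plateau rule picks the most parsimonious model that is statistically
    indistinguishable (within the tolerance) from the best one.
    """
    curve = np.asarray(rmsecv_by_lv, dtype=float).ravel()
    if curve.size == 0:
        raise ValidationError("empty RMSECV curve")
    threshold = curve.min() * (1.0 + parsimony_tol)
    return int(np.flatnonzero(curve <= threshold)[0]) + 1


def select_n_lv(cv: CVResult, parsimony_tol: float = 0.02) -> int:
    """Apply the parsimony plateau rule to a CV result."""
    return select_n_lv_from_curve(cv.rmsecv_by_lv, parsimony_tol)


def vip_scores(model: PLSModel, y=None) -> np.ndarray:
    """Variable importance in projection (Wold VIP).

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ), where
    SS_a = q_a^2 t_a' t_a is the y-variance explained by component a and
    the weight columns are unit length.  The mean squared VIP equals 1,
    so scores above ~1 flag influential ppm regions.  ``y`` is accepted
    for interface symmetry but not needed: the explained sums of squares
    are recoverable from the stored scores and loadings.
    """
    W, T, q = model.weights, model.x_scores, model.y_loadings
    p = W.shape[0]
    ss = q**2 * np.einsum("ia,ia->a", T, T)
    total = ss.sum()
    if total <= 0:
        raise ValidationError("model explains no y-variance; VIP undefined")
    return np.sqrt(p * (W**2 @ ss) / total)


# ---------------------------------------------------------------------------
# plain-text model persistence

def save_model(model: PLSModel, sink) -> None:
    """Serialize a model to self-describing JSON text.

    Stores everything needed to predict new spectra bit-reproducibly:
    the regression vector, centering constants, pretreatment parameters
    and the expected ppm grid.
    """
    pre = model.pretreatment
    doc = {
        "format": "nmrcal-pls-model",
        "version": 1,
        "property_name": model.property_name,
        "n_lv": model.n_lv,
        "coef": model.coef.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "x_scores": model.x_scores.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "grid": None if model.grid is None else model.grid.tolist(),
        "pretreatment": None if pre is None else {
            "kind": pre.kind,
            "windows": None if pre.windows is None else
                       [list(w) for w in pre.windows.windows],
            "msc_reference": None if pre.msc_reference is None else
                             pre.msc_reference.tolist(),
        },
    }
    text = json.dumps(doc)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def load_model(source) -> PLSModel:
    if hasattr(source, "read"):
        doc = json.loads(source.read())
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    if doc.get("format") != "nmrcal-pls-model":
        raise ValidationError("not an nmrcal PLS model file")
    pre = None
    if doc["pretreatment"] is not None:
        pd_ = doc["pretreatment"]
        pre = Pretreatment(
            kind=pd_["kind"],
            windows=None if pd_["windows"] is None else
                    WindowSet.from_ranges(pd_["windows"]),
            msc_reference=None if pd_["msc_reference"] is None else
                          np.array(pd_["msc_reference"]),
        )
    return PLSModel(
        n_lv=int(doc["n_lv"]),
        weights=np.array(doc["weights"]),
        x_loadings=np.array(doc["x_loadings"]),
        x_scores=np.array(doc["x_scores"]),
        y_loadings=np.array(doc["y_loadings"]),
        coef=np.array(doc["coef"]),
        x_mean=np.array(doc["x_mean"]),
        y_mean=float(doc["y_mean"]),
        property_name=doc["property_name"],
        pretreatment=pre,
        grid=None if doc["grid"] is None else np.array(doc["grid"]),
    )
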