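"""Calibration/validation sample selection.

The calibration set should span the composition space so that validation
is interpolative.  :func:`pca_coverage_split` selects it by running
Kennard-Stone maximin selection in PCA score space on many bootstrap
resamples and keeping the samples chosen most often; the per-component
extreme samples are always forced into calibration.  For 35 pollen
samples the conventional partition is 25 calibration / 10 validation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .pca import fit_pca
from .spectra_io import SpectraMatrix, ValidationError

__all__ = ["Split", "pca_coverage_split", "random_split",
           "kennard_stone", "save_split", "load_split"]


@dataclass(frozen=True)
class Split:
    calibration_ids: tuple
    validation_ids: tuple
    seed: int
    method: str

    def __post_init__(self):
        cal = tuple(str(s) for s in self.calibration_ids)
        val = tuple(str(s) for s in self.validation_ids)
        if set(cal) & set(val):
            raise ValidationError("calibration and validation sets overlap")
        object.__setattr__(self, "calibration_ids", cal)
        object.__setattr__(self, "validation_ids", val)


def kennard_stone(points: np.ndarray, n_select: int,
                  preselected=()) -> list:
    """Kennard-Stone maximin selection; returns selected row indices.

    Starts from ``preselected`` indices (or the point farthest from the
    mean) and repeatedly adds the candidate whose minimum distance to
    the already-selected set is largest.  Deterministic; ties break on
    the lower index.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not 1 <= n_select <= n:
        raise ValidationError(f"cannot select {n_select} of {n} points")
    selected = list(dict.fromkeys(int(i) for i in preselected))
    if not selected:
        d0 = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        selected = [int(np.argmax(d0))]
    if len(selected) >= n_select:
        return selected[:n_select]
    mind = cdist(pts, pts[selected]).min(axis=1)
    mind[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(mind))
        selected.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1))
        mind[nxt] = -np.inf
    return selected


def pca_coverage_split(X: SpectraMatrix, n_val: int, n_boot: int = 200,
                       k_pcs: int = 5, seed: int = 0) -> Split:
    """Bootstrap-stabilized Kennard-Stone split in PCA score space.

    For each bootstrap resample, Kennard-Stone picks calibration
    candidates among the resampled (unique) points; samples selected
    most frequently across resamples form the calibration set.  The
    per-PC extreme samples (min and max score on each of the ``k_pcs``
    components) are forced into calibration, so every validation sample
    lies inside the calibration bounding box in score space.

    The result depends only on the seed and the id->spectrum mapping,
    not on row order: rows are canonicalized by sample_id first.
    """
    n = X.n_samples
    if not 1 <= n_val < n:
        raise ValidationError(f"n_val={n_val} must be in 1..{n - 1}")
    n_cal = n - n_val
    order = sorted(range(n), key=lambda i: X.sample_ids[i])
    ids = [X.sample_ids[i] for i in order]
    k = min(k_pcs, n - 1, X.n_points)
    scores = fit_pca(X.X[order], k).scores
    # per-PC extremes must stay in calibration
    extremes: list[int] = []
    for j in range(k):
        extremes.append(int(np.argmin(scores[:, j])))
        extremes.append(int(np.argmax(scores[:, j])))
    extremes = list(dict.fromkeys(extremes))
    if len(extremes) > n_cal:
        raise ValidationError(
            f"{len(extremes)} per-PC extremes exceed calibration size {n_cal}"
        )
    rng = np.random.default_rng(seed)
    counts = np.zeros(n)
    for _ in range(n_boot):
        resample = np.unique(rng.integers(0, n, size=n))
        take = min(n_cal, resample.size)
        pre = [int(np.flatnonzero(resample == e)[0])
               for e in extremes if e in resample]
        chosen = kennard_stone(scores[resample], take, preselected=pre)
        counts[resample[chosen]] += 1
    # stable ranking: frequency desc, then id order
    rank = sorted(range(n), key=lambda i: (-counts[i], i))
    cal = set(extremes)
    for i in rank:
        if len(cal) >= n_cal:
            break
        cal.add(i)
    cal_ids = tuple(ids[i] for i in sorted(cal))
    val_ids = tuple(ids[i] for i in range(n) if i not in cal)
    return Split(cal_ids, val_ids, seed=seed, method="pca_coverage")


def random_split(ids, n_val: int, seed: int = 0) -> Split:
    """Uniform split without replacement (baseline for comparisons)."""
    ids = [str(s) for s in ids]
    n = len(ids)
    if not 1 <= n_val < n:
        raise ValidationError(f"n_val={n_val} must be in 1..{n - 1}")
    rng = np.random.default_rng(seed)
    val = set(rng.choice(n, size=n_val, replace=False).tolist())
    return Split(tuple(s for i, s in enumerate(ids) if i not in val),
                 tuple(s for i, s in enumerate(ids) if i in val),
                 seed=seed, method="random")


def save_split(split: Split, sink) -> None:
    """Write a split as two-column CSV (sample_id, role)."""

    def _write(fh):
        w = csv.writer(fh)
        w.writerow(["sample_id", "role"])
        for s in split.calibration_ids:
            w.writerow([s, "calibration"])
        for s in split.validation_ids:
            w.writerow([s, "validation"])

    if hasattr(sink, "write"):
        _write(sink)
    else:
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


def load_split(source, seed: int = -1, method: str = "loaded") -> Split:
    if hasattr(source, "read"):
        rows = list(csv.DictReader(source))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    cal = tuple(r["sample_id"] for r in rows if r["role"] == "calibration")
    val = tuple(r["sample_id"] for r in rows if r["role"] == "validation")
    if not cal or not val:
        raise ValidationError("split file must contain both roles")
    return Split(cal, val, seed=seed, method=method)
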