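"""Spectrum containers, file I/O and grid alignment.

A :class:`Spectrum` holds one 13C NMR spectrum as a (ppm, intensity) pair;
a :class:`SpectraMatrix` holds n spectra interpolated onto a shared ppm grid
(rows = samples), which is the predictor matrix X of the calibration problem.
A :class:`ReferenceTable` holds the per-sample reference assay values
(the response matrix Y).

Supported interchange formats are a minimal JCAMP-DX subset (single
spectrum, AFFN ``(XY..XY)`` point tables) and plain two-column xy text.
The ppm axis is stored in descending order, following NMR display
convention; ascending input is reversed on read.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraMatrix",
    "ReferenceTable",
    "PROPERTY_COLUMNS",
    "KJELDAHL_FACTOR",
    "read_spectrum",
    "write_spectrum",
    "assemble_matrix",
    "load_reference_table",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: Named property columns of the reference table, in canonical order.
PROPERTY_COLUMNS = (
    "tp",               # total polyphenols, mg GAE/g
    "abts",             # ABTS antioxidant activity, uM TE/g
    "reducing_sugars",  # %
    "protein",          # %
    "fat",              # %
    "nhcs",             # N+H+C+S elemental sum, %
    "c",                # carbon, %
    "n",                # nitrogen, %
    "s",                # sulfur, %
    "ph",               # unitless
)

#: Nitrogen-to-protein conversion factor (Kjeldahl).
KJELDAHL_FACTOR = 6.25

# Tolerance on protein == 6.25 * N: both columns are printed at two
# decimals, so the product can drift by half a unit in the last place.
_PROTEIN_TOL = 0.006


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass(frozen=True)
class Spectrum:
    """One 13C NMR spectrum.

    Parameters
    ----------
    sample_id
        Sample identifier.
    ppm
        Chemical-shift axis in ppm, strictly monotone.  Stored in
        descending order; ascending input is reversed together with the
        intensities.
    intensity
        Signal intensities (arbitrary units), same length as ``ppm``.
    meta
        Optional free-form metadata (e.g. JCAMP title, observed nucleus).
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or intensity.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D")
        if ppm.size != intensity.size:
            raise ValidationError(
                f"length mismatch: {ppm.size} ppm values vs "
                f"{intensity.size} intensities"
            )
        if ppm.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(intensity)):
            bad = int(np.flatnonzero(~np.isfinite(intensity))[0])
            raise ValidationError(f"non-finite intensity at index {bad}")
        if not np.all(np.isfinite(ppm)):
            bad = int(np.flatnonzero(~np.isfinite(ppm))[0])
            raise ValidationError(f"non-finite ppm at index {bad}")
        d = np.diff(ppm)
        if np.all(d < 0):
            pass  # already descending
        elif np.all(d > 0):
            ppm = ppm[::-1].copy()
            intensity = intensity[::-1].copy()
        else:
            bad = int(np.flatnonzero(d * d[0] <= 0)[0]) + 1
            raise ValidationError(f"ppm axis not monotone at index {bad}")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.ppm.size


@dataclass(frozen=True)
class SpectraMatrix:
    """n spectra aligned on a shared descending ppm grid (rows = samples)."""

    sample_ids: tuple
    grid: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        grid = np.asarray(self.grid, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate sample_ids: {dupes}")
        if X.ndim != 2 or X.shape != (len(ids), grid.size):
            raise ValidationError(
                f"X shape {X.shape} does not match {len(ids)} samples x "
                f"{grid.size} grid points"
            )
        if len(ids) < 2 or grid.size < 2:
            raise ValidationError("need n >= 2 samples and p >= 2 grid points")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        if not np.all(np.diff(grid) < 0):
            raise ValidationError("grid must be strictly descending")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "X", X)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_points(self) -> int:
        return self.grid.size

    def row(self, sample_id: str) -> np.ndarray:
        return self.X[self.sample_ids.index(str(sample_id))]

    def subset(self, sample_ids: Sequence[str]) -> "SpectraMatrix":
        """Rows restricted to ``sample_ids``, in the given order."""
        idx = [self.sample_ids.index(str(s)) for s in sample_ids]
        return SpectraMatrix(tuple(self.sample_ids[i] for i in idx),
                             self.grid, self.X[idx])


class ReferenceTable:
    """Per-sample reference property values (the Y block).

    Wraps a DataFrame indexed by ``sample_id`` with the ten canonical
    property columns.  Validates on construction: all values positive,
    protein consistent with 6.25 x N (Kjeldahl conversion, to printed
    precision), and the NHCS elemental sum at least C + N + S so the
    implied hydrogen share is nonnegative.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if "sample_id" in df.columns:
            df["sample_id"] = df["sample_id"].astype(str)
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        missing = [c for c in PROPERTY_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing property columns: {missing}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample_ids in reference table")
        num = df[list(PROPERTY_COLUMNS)].astype(float)
        if num.isna().any().any():
            raise ValidationError("reference table contains missing values")
        for col in PROPERTY_COLUMNS:
            if (num[col] <= 0).any():
                row = num.index[num[col] <= 0][0]
                raise ValidationError(
                    f"row {row!r}: property {col!r} must be positive"
                )
        dev = (num["protein"] - KJELDAHL_FACTOR * num["n"]).abs()
        if (dev > _PROTEIN_TOL).any():
            row = dev.index[dev > _PROTEIN_TOL][0]
            raise ValidationError(
                f"row {row!r}: protein {num.at[row, 'protein']} inconsistent "
                f"with {KJELDAHL_FACTOR} x N = "
                f"{KJELDAHL_FACTOR * num.at[row, 'n']:.4f}"
            )
        h = num["nhcs"] - (num["c"] + num["n"] + num["s"])
        if (h < 0).any():
            row = h.index[h < 0][0]
            raise ValidationError(
                f"row {row!r}: NHCS sum below C + N + S (negative H share)"
            )
        self.frame = df

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def property_values(self, name: str,
                        sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Values of one property, optionally for a subset of samples."""
        if name not in PROPERTY_COLUMNS:
            raise KeyError(f"unknown property {name!r}")
        col = self.frame[name].astype(float)
        if sample_ids is not None:
            col = col.loc[[str(s) for s in sample_ids]]
        return col.to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "ReferenceTable":
        return ReferenceTable(
            self.frame.loc[[str(s) for s in sample_ids]].reset_index()
        )


# ---------------------------------------------------------------------------
# single-spectrum I/O

def _parse_xy(text: str, sample_id: str) -> Spectrum:
    ppm, intensity = [], []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValidationError(
                f"line {lineno}: expected two columns, got {line!r}"
            )
        try:
            ppm.append(float(parts[0]))
            intensity.append(float(parts[1]))
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
    return Spectrum(sample_id, np.array(ppm), np.array(intensity))


def _parse_jcamp(text: str, sample_id: str) -> Spectrum:
    """Parse the AFFN ``(XY..XY)`` point-table subset of JCAMP-DX."""
    meta: dict = {}
    ppm: list[float] = []
    intensity: list[float] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key, value = key.strip().upper(), value.strip()
            if key == "XYPOINTS" or key == "XYDATA":
                in_data = True
                continue
            in_data = False
            if key == "END":
                break
            if key == "TITLE":
                meta["title"] = value
            elif key == ".OBSERVE NUCLEUS":
                meta["nucleus"] = value
            elif key:
                meta[key.lower()] = value
        elif in_data:
            for pair in line.split(";"):
                parts = pair.replace(",", " ").split()
                if not parts:
                    continue
                if len(parts) != 2:
                    raise ValidationError(
                        f"malformed JCAMP data pair: {pair!r}"
                    )
                ppm.append(float(parts[0]))
                intensity.append(float(parts[1]))
    if not ppm:
        raise ValidationError("no XY data found in JCAMP-DX input")
    sid = meta.get("title", sample_id) if sample_id == "" else sample_id
    return Spectrum(sid or "spectrum", np.array(ppm), np.array(intensity),
                    meta=meta)


def read_spectrum(source, dialect: str = "xy", sample_id: str = "") -> Spectrum:
    """Read a single spectrum from a file path or text stream.

    ``dialect`` is ``"xy"`` (two-column text, whitespace or comma
    separated) or ``"jcamp"`` (JCAMP-DX with an AFFN point table).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        path = Path(source)
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise IOError(f"cannot read {path}: {exc}") from exc
        if not sample_id:
            sample_id = path.stem
    if dialect in ("xy", "xy-delimited"):
        return _parse_xy(text, sample_id or "spectrum")
    if dialect in ("jcamp", "jcamp-dx"):
        return _parse_jcamp(text, sample_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectrum(s: Spectrum, sink, dialect: str = "xy") -> None:
    """Write a spectrum so that :func:`read_spectrum` recovers it.

    Values are written with 17 significant digits, which round-trips
    IEEE double precision exactly.
    """
    if dialect in ("xy", "xy-delimited"):
        lines = [f"{x:.17g} {y:.17g}" for x, y in zip(s.ppm, s.intensity)]
        text = "\n".join(lines) + "\n"
    elif dialect in ("jcamp", "jcamp-dx"):
        header = [
            f"##TITLE={s.meta.get('title', s.sample_id)}",
            "##JCAMP-DX=5.01",
            "##DATA TYPE=NMR SPECTRUM",
            f"##.OBSERVE NUCLEUS={s.meta.get('nucleus', '^13C')}",
            "##XUNITS=PPM",
            "##YUNITS=ARBITRARY UNITS",
            f"##NPOINTS={len(s)}",
            f"##FIRSTX={s.ppm[0]:.17g}",
            f"##LASTX={s.ppm[-1]:.17g}",
            "##XYPOINTS=(XY..XY)",
        ]
        data = [f"{x:.17g}, {y:.17g}" for x, y in zip(s.ppm, s.intensity)]
        text = "\n".join(header + data + ["##END="]) + "\n"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        try:
            Path(sink).write_text(text, encoding="utf-8")
        except OSError as exc:
            raise IOError(f"cannot write {sink}: {exc}") from exc


# ---------------------------------------------------------------------------
# matrix assembly and I/O

def assemble_matrix(spectra: Iterable[Spectrum],
                    grid="intersection") -> SpectraMatrix:
    """Interpolate spectra onto a common descending ppm grid.

    ``grid="intersection"`` takes the densest input grid restricted to
    the ppm span shared by all spectra.  Interpolation is linear and
    never extrapolates: a target grid extending beyond any spectrum's
    span is an error.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValidationError("need at least 2 spectra")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_ids: {dupes}")
    hi = min(s.ppm[0] for s in spectra)
    lo = max(s.ppm[-1] for s in spectra)
    if hi <= lo:
        raise ValidationError("spectra have disjoint ppm ranges")
    if isinstance(grid, str) and grid == "intersection":
        densest = max(spectra, key=len)
        g = densest.ppm[(densest.ppm <= hi) & (densest.ppm >= lo)]
        if g.size < 2:
            raise ValidationError("common ppm span contains < 2 grid points")
    else:
        g = np.asarray(grid, dtype=float)
        if np.all(np.diff(g) > 0):
            g = g[::-1]
        if g.max() > hi or g.min() < lo:
            raise ValidationError(
                f"target grid [{g.min()}, {g.max()}] exceeds the common "
                f"span [{lo}, {hi}]; extrapolation is not supported"
            )
    rows = np.empty((len(spectra), g.size))
    for i, s in enumerate(spectra):
        # np.interp wants ascending abscissae
        rows[i] = np.interp(g[::-1], s.ppm[::-1], s.intensity[::-1])[::-1]
    return SpectraMatrix(tuple(ids), g, rows)


def read_matrix_csv(source) -> SpectraMatrix:
    """Read a SpectraMatrix CSV: header row = ppm grid, first column = ids."""
    df = pd.read_csv(source, index_col=0)
    grid = df.columns.to_numpy(dtype=float)
    return SpectraMatrix(tuple(str(i) for i in df.index), grid,
                         df.to_numpy(dtype=float))


def write_matrix_csv(m: SpectraMatrix, sink) -> None:
    df = pd.DataFrame(m.X, index=list(m.sample_ids),
                      columns=[f"{p:.6f}" for p in m.grid])
    df.index.name = "sample_id"
    df.to_csv(sink, float_format="%.10g")


def load_reference_table(source=None) -> ReferenceTable:
    """Load a reference table CSV; default is the packaged 35-sample table.

    The packaged fixture transcribes, at printed precision, the published
    characterization of 35 Polish bee-pollen samples: total polyphenols
    (mg GAE/g), ABTS antioxidant activity (uM TE/g), reducing sugars,
    protein, fat, the NHCS elemental sum, C, N, S (all %) and pH.
    """
    if source is None:
        ref = resources.files("nmrcal.data") / "table1_bee_pollen.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, dtype={"sample_id": str})
    else:
        df = pd.read_csv(source, dtype={"sample_id": str})
    return ReferenceTable(df)
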