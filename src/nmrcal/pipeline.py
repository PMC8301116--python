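"""End-to-end calibration workflow.

For each configured property: split samples into calibration and
validation sets (one shared split for all properties), window and
pretreat the calibration spectra, fit a PLS1 model (fixed or
cross-validation-chosen latent-variable count), predict both sets and
summarize RSEP, RMSE and correlation per property in a calibration
report.  Pretreatment parameters, centering constants and the split are
all learned on the calibration set only.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .pls import PLSModel, fit_pls, loo_cv, predict
from .preprocess import Pretreatment, WindowSet
from .spectra_io import (PROPERTY_COLUMNS, ReferenceTable, SpectraMatrix,
                         ValidationError)
from .split import Split, pca_coverage_split, random_split

__all__ = ["PropertyConfig", "RunConfig", "CalibrationReport",
           "run_calibration", "write_report", "read_report",
           "default_config"]

log = logging.getLogger("nmrcal")


@dataclass(frozen=True)
class PropertyConfig:
    property_name: str
    pretreatment: str = "none"          # none | msc | snv
    ranges: tuple | None = None         # ((high, low), ...) or None = full
    n_lv: int | str = "auto"
    a_max: int = 10
    parsimony_tol: float = 0.02

    def __post_init__(self):
        if self.property_name not in PROPERTY_COLUMNS:
            raise ValidationError(f"unknown property {self.property_name!r}")
        if self.pretreatment not in ("none", "msc", "snv"):
            raise ValidationError(
                f"{self.property_name}: bad pretreatment "
                f"{self.pretreatment!r}"
            )
        if isinstance(self.n_lv, str):
            if self.n_lv != "auto":
                raise ValidationError(
                    f"{self.property_name}: n_lv must be an integer or 'auto'"
                )
        elif self.n_lv < 1:
            raise ValidationError(f"{self.property_name}: n_lv must be >= 1")

    def window_set(self) -> WindowSet | None:
        if self.ranges is None:
            return None
        return WindowSet.from_ranges(self.ranges)


@dataclass(frozen=True)
class RunConfig:
    properties: tuple                   # PropertyConfig, ...
    split_method: str = "pca_coverage"  # pca_coverage | random
    n_val: int = 10
    n_boot: int = 200
    k_pcs: int = 5
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        props = []
        for name, block in (doc.get("properties") or {}).items():
            block = dict(block or {})
            ranges = block.pop("ranges", None)
            if ranges is not None:
                ranges = tuple((float(h), float(l)) for h, l in ranges)
            props.append(PropertyConfig(
                property_name=name,
                pretreatment=str(block.pop("pretreatment", "none")),
                ranges=ranges,
                n_lv=block.pop("n_lv", "auto"),
                a_max=int(block.pop("a_max", 10)),
                parsimony_tol=float(block.pop("parsimony_tol", 0.02)),
            ))
            if block:
                raise ValidationError(
                    f"{name}: unknown config keys {sorted(block)}"
                )
        if not props:
            raise ValidationError("config lists no properties")
        sp = doc.get("split") or {}
        return cls(
            properties=tuple(props),
            split_method=str(sp.get("method", "pca_coverage")),
            n_val=int(sp.get("n_val", 10)),
            n_boot=int(sp.get("n_boot", 200)),
            k_pcs=int(sp.get("k_pcs", 5)),
            seed=int(sp.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            with open(source, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        return cls.from_dict(doc)


def default_config() -> RunConfig:
    """The packaged per-property defaults (pretreatment, LV count, ranges)."""
    ref = resources.files("nmrcal.data") / "default_models.yaml"
    return RunConfig.from_yaml(ref.open("r", encoding="utf-8"))


@dataclass(frozen=True)
class CalibrationReport:
    """Per-property model summary plus the fitted models and the split."""

    frame: pd.DataFrame
    split: Split | None = None
    models: dict = field(default_factory=dict, compare=False)

    COLUMNS = ("property_name", "rsep_cal_pct", "rsep_val_pct",
               "r", "r_cv", "n_lv", "pretreatment")


def _make_split(X: SpectraMatrix, cfg: RunConfig) -> Split:
    if cfg.split_method == "pca_coverage":
        return pca_coverage_split(X, cfg.n_val, n_boot=cfg.n_boot,
                                  k_pcs=cfg.k_pcs, seed=cfg.seed)
    if cfg.split_method == "random":
        return random_split(X.sample_ids, cfg.n_val, seed=cfg.seed)
    raise ValidationError(f"unknown split method {cfg.split_method!r}")


def run_calibration(spectra: SpectraMatrix, refs: ReferenceTable,
                    cfg: RunConfig, split: Split | None = None
                    ) -> CalibrationReport:
    """Run the full workflow and return the calibration report."""
    if set(spectra.sample_ids) != set(refs.sample_ids):
        only_x = sorted(set(spectra.sample_ids) - set(refs.sample_ids))
        only_y = sorted(set(refs.sample_ids) - set(spectra.sample_ids))
        raise ValidationError(
            f"sample ids disagree (spectra only: {only_x[:3]}, "
            f"references only: {only_y[:3]})"
        )
    t0 = time.perf_counter()
    if split is None:
        split = _make_split(spectra, cfg)
    log.info("split: %d calibration / %d validation samples (%.2fs)",
             len(split.calibration_ids), len(split.validation_ids),
             time.perf_counter() - t0)
    X_cal = spectra.subset(split.calibration_ids)
    X_val = spectra.subset(split.validation_ids)
    rows = []
    models: dict[str, PLSModel] = {}
    for pc in cfg.properties:
        t1 = time.perf_counter()
        y_cal = refs.property_values(pc.property_name, split.calibration_ids)
        y_val = refs.property_values(pc.property_name, split.validation_ids)
        if np.ptp(y_cal) == 0:
            raise ValidationError(
                f"{pc.property_name}: constant in the calibration set"
            )
        pre = Pretreatment(kind=pc.pretreatment, windows=pc.window_set())
        Xc_t, pre_fitted = pre.fit_transform(X_cal)
        a_max = min(pc.a_max, len(split.calibration_ids) - 2)
        if pc.n_lv != "auto":
            a_max = max(a_max, int(pc.n_lv))
        cv = loo_cv(X_cal, y_cal, a_max, pretreatment=pre,
                    parsimony_tol=pc.parsimony_tol)
        n_lv = cv.chosen_lv if pc.n_lv == "auto" else int(pc.n_lv)
        model = fit_pls(Xc_t, y_cal, n_lv,
                        property_name=pc.property_name,
                        pretreatment=pre_fitted, grid=spectra.grid,
                        cap_to_rank=True)
        if model.n_lv < n_lv:
            log.warning("%s: effective rank supports only %d of the "
                        "requested %d latent variables",
                        pc.property_name, model.n_lv, n_lv)
            n_lv = model.n_lv
        pred_cal = predict(model, Xc_t)
        pred_val = predict(
            model, pre_fitted.transform_array(X_val.X, X_val.grid))
        # r_cv at the LV count actually used
        r_cv = float(np.corrcoef(cv.predictions_by_lv[:, n_lv - 1],
                                 y_cal)[0, 1])
        cal_rep = metrics.evaluate(pc.property_name, "calibration",
                                   pred_cal, y_cal)
        val_rep = metrics.evaluate(pc.property_name, "validation",
                                   pred_val, y_val)
        rows.append({
            "property_name": pc.property_name,
            "rsep_cal_pct": cal_rep.rsep_pct,
            "rsep_val_pct": val_rep.rsep_pct,
            "r": cal_rep.r,
            "r_cv": r_cv,
            "n_lv": n_lv,
            "pretreatment": pc.pretreatment,
        })
        models[pc.property_name] = model
        log.info("%-16s %d LV %-4s  RSEP cal/val %.2f/%.2f%%  "
                 "R %.3f  Rcv %.3f  (%.2fs)",
                 pc.property_name, n_lv, pc.pretreatment,
                 cal_rep.rsep_pct, val_rep.rsep_pct, cal_rep.r, r_cv,
                 time.perf_counter() - t1)
    frame = pd.DataFrame(rows, columns=list(CalibrationReport.COLUMNS))
    return CalibrationReport(frame=frame, split=split, models=models)


def write_report(report: CalibrationReport, sink) -> None:
    """Write the report as CSV; errors to 2 decimals, correlations to 3."""
    df = report.frame.copy()
    for col in ("rsep_cal_pct", "rsep_val_pct"):
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    for col in ("r", "r_cv"):
        df[col] = df[col].map(lambda v: f"{v:.3f}")
    df.to_csv(sink, index=False)


def read_report(source) -> CalibrationReport:
    df = pd.read_csv(source)
    missing = set(CalibrationReport.COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"report missing columns {sorted(missing)}")
    return CalibrationReport(frame=df[list(CalibrationReport.COLUMNS)])
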