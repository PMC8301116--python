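"""Error and agreement metrics for calibration models.

RSEP (relative standard error of prediction) is the unit-free percentage
error used to compare models across properties measured in different
units:

    RSEP% = 100 * sqrt( sum (C_i - C^A_i)^2 / sum (C^A_i)^2 )

where C are predicted and C^A reference values.  It relates to the RMSE
through RSEP% = 100 * sqrt(n / sum C^A_i^2) * RMSE, so rescaling
predictions and references jointly leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "rsep", "rmse", "pearson_r", "evaluate"]


def _pair(pred, ref):
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size:
        raise ValueError(
            f"length mismatch: {pred.size} predictions vs "
            f"{ref.size} references"
        )
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, ref


def rsep(pred, ref) -> float:
    """Relative standard error of prediction, in percent."""
    pred, ref = _pair(pred, ref)
    denom = float(ref @ ref)
    if denom == 0:
        raise ValueError("reference values are all zero; RSEP undefined")
    return 100.0 * float(np.sqrt((pred - ref) @ (pred - ref) / denom))


def rmse(pred, ref) -> float:
    """Root mean square error, in the property's own units."""
    pred, ref = _pair(pred, ref)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation coefficient."""
    a, b = _pair(a, b)
    if a.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class EvalReport:
    """Prediction quality of one model on one sample set."""

    property_name: str
    set_label: str  # "calibration" | "validation"
    rsep_pct: float
    rmse: float
    r: float

    def __post_init__(self):
        if self.set_label not in ("calibration", "validation"):
            raise ValueError(f"bad set_label {self.set_label!r}")


def evaluate(property_name: str, set_label: str, pred, ref) -> EvalReport:
    """Bundle RSEP, RMSE and Pearson r for one prediction set."""
    return EvalReport(property_name, set_label,
                      rsep_pct=rsep(pred, ref),
                      rmse=rmse(pred, ref),
                      r=pearson_r(pred, ref))
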