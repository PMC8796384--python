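"""Evaluation metrics: MAE and Pearson R over the two %PPB ranges.

MAE = sum_i |y_i - yhat_i| / n and R is the Pearson product-moment
correlation between experimental and predicted values.  Two evaluation
ranges are reported: the full clamped range 50-95, and 80-95, where only
peptides whose *experimental* value is at least 80% are scored (predictions
never drive the filter).  Predictions are clamped to [50, 95] in both
ranges before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import PPB_CEIL, PPB_FLOOR

__all__ = ["MetricsReport", "evaluate"]

RANGES = ("50-95", "80-95")


@dataclass
class MetricsReport:
    range: str
    mae: float
    r: float | None  # None when undefined (fewer than 2 records, zero variance)
    n_evaluated: int


def evaluate(y_exp, y_pred, range: str = "50-95") -> MetricsReport:
    """Score predictions against experimental %PPB over the given range."""
    if range not in RANGES:
        raise ValueError(f"range must be one of {RANGES}")
    y = np.asarray(y_exp, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError("experimental and predicted vectors differ in length")
    if range == "80-95":
        keep = y >= 80.0
        y, p = y[keep], p[keep]
    if y.size == 0:
        raise ValueError("no records left after range filtering")
    p = np.clip(p, PPB_FLOOR, PPB_CEIL)
    mae = float(np.mean(np.abs(y - p)))
    if y.size < 2 or y.std() == 0 or p.std() == 0:
        r = None
    else:
        r = float(np.corrcoef(y, p)[0, 1])
    return MetricsReport(range=range, mae=mae, r=r, n_evaluated=int(y.size))
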