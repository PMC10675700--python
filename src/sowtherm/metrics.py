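"""Evaluation metrics: IoU for segmentation masks, MSE/MAE/R² for regression.

IoU compares a predicted binary mask D with a ground-truth mask M by pixel
counting, |D ∩ M| / |D ∪ M|.  The regression metrics score predicted rectal
temperatures against thermometer readings:

    MSE = (1/n) Σ (T_i − T̂_i)²          (units °C²)
    MAE = (1/n) Σ |T_i − T̂_i|           (units °C)
    R²  = 1 − Σ(T_i − T̂_i)² / Σ(T_i − T̄)²

MSE is mathematically °C² even though field reports often label it °C;
report writers in this package label it ``mse_c2``.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, ShapeMismatchError

__all__ = ["iou", "mse", "mae", "r2", "regression_report"]


def iou(d, m) -> float:
    """Intersection-over-union of two binary masks of identical shape.

    Accepts anything array-like with values interpretable as truthy pixels
    (0/1 grids, boolean arrays, 0/255 images).  Two empty masks agree
    vacuously and score 1.0.
    """
    d = np.asarray(d) != 0
    m = np.asarray(m) != 0
    if d.shape != m.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {d.shape} vs {m.shape}"
        )
    union = int(np.count_nonzero(d | m))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(d & m))
    return inter / union


def _pairs(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if t.shape != p.shape:
        raise ShapeMismatchError(
            f"truth has {t.size} values, prediction has {p.size}"
        )
    if t.size == 0:
        raise DomainError("metrics are undefined for zero prediction pairs")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
        raise DomainError("non-finite value in prediction pairs")
    return t, p


def mse(truth, predicted) -> float:
    """Mean squared error, ≥ 0, zero iff the prediction is perfect."""
    t, p = _pairs(truth, predicted)
    return float(np.mean((t - p) ** 2))


def mae(truth, predicted) -> float:
    """Mean absolute error (signed errors do not cancel)."""
    t, p = _pairs(truth, predicted)
    return float(np.mean(np.abs(t - p)))


def r2(truth, predicted) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot; ≤ 1, unbounded below.

    Requires at least two observations and non-constant truth (the total
    sum of squares must be positive for the ratio to be defined).
    """
    t, p = _pairs(truth, predicted)
    if t.size < 2:
        raise DomainError("r2 requires at least two prediction pairs")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("r2 is undefined for constant truth values")
    ss_res = float(np.sum((t - p) ** 2))
    return 1.0 - ss_res / ss_tot


def regression_report(truth, predicted) -> dict:
    """All three regression metrics in one dict (keys mse_c2, mae_c, r2)."""
    return {
        "mse_c2": mse(truth, predicted),
        "mae_c": mae(truth, predicted),
        "r2": r2(truth, predicted),
        "n": int(np.asarray(truth).ravel().size),
    }
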