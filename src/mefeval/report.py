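"""Validation summaries for a MEF evaluation.

Mirrors the standard reporting around a methane-efficiency launch: contrasts
of predicted and recorded CH4 across low/medium/high RBV classes, the
regression of sire-daughter CH4 averages on sire RBV (translating RBV points
into g/d), and proof correlations between MEF and other published proofs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: RBV class bounds: low < 95, medium in [95, 105], high > 105 (boundaries
#: belong to the medium class).
CLASS_BOUNDS = (95.0, 105.0)


@dataclass
class RBVClassSummary:
    table: pd.DataFrame   # class, n, mean_predicted, se_predicted, mean_recorded, se_recorded


def rbv_class_of(rbv: np.ndarray, bounds: tuple = CLASS_BOUNDS) -> np.ndarray:
    lo, hi = bounds
    r = np.asarray(rbv, dtype=float)
    out = np.full(r.shape, "medium", dtype=object)
    out[r < lo] = "low"
    out[r > hi] = "high"
    return out


def rbv_class_summary(
    rbv: np.ndarray,
    predicted_ch4: np.ndarray,
    recorded_ch4: np.ndarray,
    bounds: tuple = CLASS_BOUNDS,
) -> RBVClassSummary:
    """Per-class means and standard errors (SE = SD / sqrt(n))."""
    df = pd.DataFrame(
        {
            "cls": rbv_class_of(rbv, bounds),
            "predicted": np.asarray(predicted_ch4, float),
            "recorded": np.asarray(recorded_ch4, float),
        }
    )
    rows = []
    for cls in ("low", "medium", "high"):
        sub = df[df.cls == cls]
        n = len(sub)
        if n == 0:
            rows.append((cls, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        rows.append(
            (
                cls, n,
                sub.predicted.mean(),
                sub.predicted.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                sub.recorded.mean(),
                sub.recorded.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            )
        )
    return RBVClassSummary(
        pd.DataFrame(
            rows,
            columns=["class", "n", "mean_predicted", "se_predicted",
                     "mean_recorded", "se_recorded"],
        )
    )


def daughter_regression(sire_rbv: np.ndarray, daughter_ch4_mean: np.ndarray) -> dict:
    """Least-squares slope of daughter CH4 average on sire RBV.

    Returns the slope in g/d per RBV point and the expected CH4 reduction
    for a 5-point (one SD) RBV increase; a favourable (negative) slope gives
    a positive reduction.
    """
    x = np.asarray(sire_rbv, dtype=float)
    y = np.asarray(daughter_ch4_mean, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 sires with daughter averages")
    if x.std() == 0:
        return {"slope_per_point": np.nan, "reduction_per_5_points": np.nan,
                "degenerate": True}
    slope = float(np.polyfit(x, y, 1)[0])
    return {
        "slope_per_point": slope,
        "reduction_per_5_points": -5.0 * slope,
        "degenerate": False,
    }


def proof_correlations(mef_rbv: np.ndarray, proofs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of MEF RBV with other proof vectors
    (pairwise-complete; constant vectors are flagged as undefined)."""
    x = np.asarray(mef_rbv, dtype=float)
    rows = []
    for col in proofs.columns:
        y = proofs[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3:
            rows.append((col, n, np.nan, "insufficient overlap"))
            continue
        if x[ok].std() == 0 or y[ok].std() == 0:
            rows.append((col, n, np.nan, "zero variance"))
            continue
        rows.append((col, n, float(np.corrcoef(x[ok], y[ok])[0, 1]), ""))
    return pd.DataFrame(rows, columns=["proof", "n", "r", "flag"])
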