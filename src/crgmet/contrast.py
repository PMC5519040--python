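"""Two-tissue contribution contrast for a single metabolite.

For a metabolite measured in both tissues, the response and the two
tissue abundance series are linearly detrended over the patient-index
order of the input table, and the detrended response is regressed on both
detrended predictors jointly.  Comparing |beta_tumor| with |beta_benign|
indicates which tissue's abundance contributes more strongly to the
association.  With cross-sectional data the detrending is
order-sensitive; the ordering used is recorded with the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend

__all__ = ["detrend", "fit_contrast", "ContrastResult"]


@dataclass
class ContrastResult:
    metabolite_id: str
    beta_tumor: float
    beta_benign: float
    abs_comparison: str  # "tumor" | "benign"
    delta: float  # |beta_tumor| - |beta_benign|

    def to_dict(self) -> dict:
        return {
            "metabolite_id": self.metabolite_id,
            "beta_tumor": self.beta_tumor,
            "beta_benign": self.beta_benign,
            "abs_comparison": self.abs_comparison,
            "delta": self.delta,
        }


def detrend(series) -> np.ndarray:
    """Remove the least-squares straight line over the index order.

    The result has zero mean and zero linear trend; the operation is
    idempotent and linear.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("detrend expects a 1-d series")
    if x.shape[0] < 3:
        raise ValueError("detrend needs at least 3 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("detrend input contains non-finite values")
    return _linear_detrend(x, type="linear")


def fit_contrast(
    y,
    x_tumor,
    x_benign,
    metabolite_id: str = "",
    detrend_inputs: bool = True,
    collinearity_limit: float = 0.999,
) -> ContrastResult:
    """Joint OLS of the detrended response on both detrended tissue series.

    Raises when the two predictors are (near-)collinear
    (|r| > ``collinearity_limit``), where the coefficient split is not
    identifiable.
    """
    y = np.asarray(y, dtype=float)
    xt = np.asarray(x_tumor, dtype=float)
    xb = np.asarray(x_benign, dtype=float)
    if not (y.shape == xt.shape == xb.shape):
        raise ValueError("response and predictors must have equal lengths")
    if detrend_inputs:
        y, xt, xb = detrend(y), detrend(xt), detrend(xb)
    for name, v in (("x_tumor", xt), ("x_benign", xb)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant after detrending")
    r = np.corrcoef(xt, xb)[0, 1]
    if abs(r) > collinearity_limit:
        raise ValueError(f"predictors are collinear (|r| = {abs(r):.4f}); contrast not identifiable")
    design = np.column_stack([np.ones_like(y), xt, xb])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    bt, bb = float(beta[1]), float(beta[2])
    delta = abs(bt) - abs(bb)
    return ContrastResult(
        metabolite_id=str(metabolite_id),
        beta_tumor=bt,
        beta_benign=bb,
        abs_comparison="tumor" if delta > 0 else "benign",
        delta=float(delta),
    )
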