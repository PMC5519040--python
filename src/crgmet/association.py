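"""Univariable reference regressions, FDR adjustment and significance calls.

Each variable (metabolite or covariate column) is regressed against the
response independently by ordinary least squares; the slope's two-sided
t-test p-value, adjusted across the whole family by the
Benjamini-Hochberg step-up procedure, is combined with the multivariable
model's VIP score into the dual criterion used throughout:

* significant: VIP > 1 and FDR-adjusted p < 0.05 (direction from the
  sign of the OPLS effect);
* suggestive: VIP > 1 but FDR-adjusted p >= 0.05;
* not significant otherwise.

The FDR family is all variables of one analysis jointly (metabolites plus
covariates); separate analyses (benign, tumor, fold-change, long-term)
are separate families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .opls import OPLSRegressor
from .preprocess import DesignMatrix

__all__ = [
    "univariable_regressions",
    "adjust_fdr",
    "classify",
    "build_association_table",
    "CLASSES",
]

CLASSES = ("significant_positive", "significant_negative", "suggestive", "not_significant")


def univariable_regressions(variables: pd.DataFrame, y) -> pd.DataFrame:
    """Per-column OLS of ``y ~ x``: slope and two-sided slope p-value.

    Zero-variance columns get NaN slope and p (recorded as missing).
    Requires at least 3 observations (no residual degrees of freedom
    otherwise).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if variables.shape[0] != n:
        raise ValueError("variables and response lengths differ")
    if n < 3:
        raise ValueError("univariable regression needs at least 3 observations")
    X = variables.to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        syy = float(yc @ yc)
        rss = syy - slope * sxy
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = slope / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    zero_var = sxx <= 0
    slope[zero_var] = np.nan
    pvals[zero_var] = np.nan
    return pd.DataFrame({"name": variables.columns, "slope": slope, "p": pvals})


def adjust_fdr(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg (default) step-up adjusted p-values.

    NaN entries (untestable variables) are passed through as NaN and do
    not count toward the family size.  ``method`` may be any
    statsmodels multiple-testing method name (e.g. "fdr_by").
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method=method)[1]
    return out


def classify(
    vip,
    fdr_p,
    effect,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Dual-criterion significance classes (vectorized).

    Significant calls need both VIP strictly above the threshold and
    adjusted p strictly below alpha; direction is the sign of the effect.
    """
    vip = np.atleast_1d(np.asarray(vip, dtype=float))
    fdr_p = np.atleast_1d(np.asarray(fdr_p, dtype=float))
    effect = np.atleast_1d(np.asarray(effect, dtype=float))
    out = np.full(vip.shape, "not_significant", dtype=object)
    high_vip = vip > vip_threshold
    sig = high_vip & (fdr_p < alpha)
    out[high_vip & ~sig] = "suggestive"
    out[sig & (effect >= 0)] = "significant_positive"
    out[sig & (effect < 0)] = "significant_negative"
    return out


def build_association_table(
    design: DesignMatrix,
    model: OPLSRegressor,
    y,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Combine OPLS importance with univariable reference fits.

    Univariable slopes are computed on the uncentered columns (slopes are
    invariant to centering of the response side anyway); the FDR family
    is every column of the design jointly.
    """
    raw = design.raw if design.raw is not None else design.X
    uni = univariable_regressions(raw, y)
    table = design.meta.merge(uni, on="name", how="left")
    table["vip"] = model.vip_
    table["effect"] = model.effect_
    table["fdr_p"] = adjust_fdr(table["p"].to_numpy(), method=fdr_method)
    table["class"] = classify(
        table["vip"].to_numpy(), table["fdr_p"].to_numpy(), table["effect"].to_numpy(),
        vip_threshold=vip_threshold, alpha=alpha,
    )
    return table[["name", "source", "compound_id", "vip", "effect", "slope", "p", "fdr_p", "class"]]
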