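"""Metabolite matrix preprocessing and design assembly.

Non-targeted metabolomics abundances come with a below-limit-of-detection
(BDL) mask: cells where the platform could not quantify the compound.  The
pipeline applied here is

1. median normalization — each metabolite divided by the median of its
   *detected* values, putting compounds on a common scale (detected median
   becomes 1);
2. detection filter — metabolites with strictly more than 75% BDL
   measurements across the cohort are eliminated;
3. imputation — remaining BDL cells are set to the minimum detected
   normalized value of that metabolite across the cohort (the conventional
   "minimum observed" rule for censored metabolomics data).

The paper's text orders imputation before the filter; the order only
matters if imputation cleared the BDL flags, which it does not, so the
filter sees identical masks either way.

Categorical covariates are dummy-coded against declared reference levels,
combined with the metabolite columns, and mean-centered into the design
matrix fed to the OPLS fit.  No unit-variance scaling is applied by
default (the analysis centers only); scaling is exposed as an option since
VIP magnitudes depend on it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteMatrix",
    "DesignMatrix",
    "CovariateSchema",
    "TABLE1_SCHEMA",
    "median_normalize",
    "impute_below_lod",
    "filter_low_detection",
    "preprocess_matrix",
    "compute_fold_change",
    "encode_covariates",
    "assemble_design",
]

TISSUE_SUFFIX = {"benign": "benign", "tumor": "tumor", "fold_change": "benign_tumor_fc"}


@dataclass
class MetaboliteMatrix:
    """Patients x metabolites abundance matrix with a below-LOD mask.

    ``values`` and ``below_lod`` share index (patient ids) and columns
    (compound ids).  Values at masked cells are placeholders and must not
    be interpreted before imputation.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    tissue: str = "benign"

    def __post_init__(self):
        if self.values.shape != self.below_lod.shape:
            raise ValueError("values and below_lod shapes differ")
        if not (self.values.columns.equals(self.below_lod.columns) and self.values.index.equals(self.below_lod.index)):
            raise ValueError("values and below_lod must share index and columns")
        if self.tissue not in TISSUE_SUFFIX:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        detected = self.values.to_numpy(dtype=float)[~self.below_lod.to_numpy(dtype=bool)]
        if detected.size and (np.any(~np.isfinite(detected)) or np.any(detected < 0)):
            raise ValueError("detected abundances must be finite and non-negative")

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.columns)

    @property
    def patients(self) -> list:
        return list(self.values.index)

    def subset(self, metabolite_ids: Sequence | None = None, patients: Sequence | None = None) -> "MetaboliteMatrix":
        v, m = self.values, self.below_lod
        if metabolite_ids is not None:
            v, m = v[list(metabolite_ids)], m[list(metabolite_ids)]
        if patients is not None:
            v, m = v.loc[list(patients)], m.loc[list(patients)]
        return MetaboliteMatrix(v, m, self.tissue)


@dataclass
class DesignMatrix:
    """Centered design matrix with per-column provenance metadata.

    ``meta`` has one row per column of ``X`` with fields ``name``,
    ``source`` (metabolite | covariate_dummy | covariate_continuous) and
    ``compound_id`` (NaN for covariates).
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    raw: pd.DataFrame = field(repr=False, default=None)  # uncentered columns, for univariable fits

    def __post_init__(self):
        if list(self.meta["name"]) != list(self.X.columns):
            raise ValueError("meta rows must match design columns")


def median_normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each metabolite by the median of its detected values.

    Metabolites with no detected values are left unscaled (they are
    removed by the detection filter).
    """
    detected = matrix.values.where(~matrix.below_lod)
    med = detected.median(axis=0)
    n_undetectable = int(med.isna().sum())
    if n_undetectable:
        logger.warning("%d metabolites have no detected values; left unscaled", n_undetectable)
    scale = med.where(med.notna() & (med > 0), 1.0)
    return MetaboliteMatrix(matrix.values / scale, matrix.below_lod.copy(), matrix.tissue)


def impute_below_lod(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Set BDL cells to the per-metabolite minimum detected value.

    The matrix should already be median normalized.  BDL flags are
    preserved so provenance is not lost.
    """
    detected = matrix.values.where(~matrix.below_lod)
    col_min = detected.min(axis=0)
    fill = pd.DataFrame(
        np.broadcast_to(col_min.values, matrix.values.shape),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    values = matrix.values.mask(matrix.below_lod, fill)
    return MetaboliteMatrix(values, matrix.below_lod.copy(), matrix.tissue)


def filter_low_detection(matrix: MetaboliteMatrix, max_bdl_fraction: float = 0.75) -> list:
    """Return ids of metabolites with BDL fraction <= ``max_bdl_fraction``.

    Metabolites with *strictly more* than the threshold fraction of BDL
    measurements are eliminated.
    """
    if matrix.values.shape[1] == 0:
        warnings.warn("empty metabolite matrix; nothing to filter")
        return []
    frac = matrix.below_lod.mean(axis=0)
    retained = list(frac.index[frac.values <= max_bdl_fraction])
    logger.info(
        "detection filter (%s): %d of %d metabolites retained",
        matrix.tissue, len(retained), matrix.values.shape[1],
    )
    return retained


def preprocess_matrix(matrix: MetaboliteMatrix, max_bdl_fraction: float = 0.75) -> MetaboliteMatrix:
    """Full preprocessing: normalize -> detection filter -> impute."""
    normalized = median_normalize(matrix)
    retained = filter_low_detection(normalized, max_bdl_fraction)
    return impute_below_lod(normalized.subset(metabolite_ids=retained))


def compute_fold_change(benign: MetaboliteMatrix, tumor: MetaboliteMatrix) -> MetaboliteMatrix:
    """Benign/tumor abundance fold change on the intersection of metabolites.

    Both inputs must be preprocessed (normalized and imputed, hence
    strictly positive).  A fold-change cell is flagged when either
    constituent was below LOD.
    """
    ids = [c for c in benign.values.columns if c in set(tumor.values.columns)]
    patients = [p for p in benign.values.index if p in set(tumor.values.index)]
    b = benign.subset(ids, patients)
    t = tumor.subset(ids, patients)
    if np.any(t.values.values <= 0) or np.any(b.values.values <= 0):
        raise ValueError("fold change requires strictly positive imputed abundances")
    values = b.values / t.values
    mask = b.below_lod | t.below_lod
    return MetaboliteMatrix(values, mask, "fold_change")


@dataclass(frozen=True)
class CovariateSchema:
    """Declares continuous covariates and categorical reference levels."""

    continuous: tuple
    categorical: Mapping[str, str]  # name -> reference level
    excluded: tuple = ()

    def check(self, table: pd.DataFrame) -> None:
        missing = [c for c in (*self.continuous, *self.categorical) if c not in table.columns]
        if missing:
            raise ValueError(f"covariate table lacks columns {missing}")


#: Cohort covariate layout: continuous clinical measures plus categoricals
#: with their declared reference levels.  Nephrectomy type and imaging
#: modality are recorded but never used as covariates; N and M stage are
#: folded into the composite AJCC stage.
TABLE1_SCHEMA = CovariateSchema(
    continuous=("age", "preop_gfr", "bmi", "pack_years", "tumor_volume_cc"),
    categorical={
        "gender": "female",
        "race": "afro_american",
        "diabetes": "no",
        "hyperlipidemia": "no",
        "coronary_artery_disease": "no",
        "hypertension": "no",
        "smoking": "no",
        "t_stage": "pT1a",
        "fuhrman_grade": "2",
        "ajcc_stage": "1",
    },
    excluded=("nephrectomy_type", "imaging", "n_stage", "m_stage"),
)


def encode_covariates(
    covariates: pd.DataFrame,
    schema: CovariateSchema = TABLE1_SCHEMA,
    levels: Mapping[str, Sequence] | None = None,
    drop_constant: bool = True,
) -> pd.DataFrame:
    """Dummy-code categoricals against their reference; pass continuous through.

    ``levels`` optionally declares the admissible levels per categorical;
    a value outside the declared levels raises an error naming it.
    Zero-variance columns (e.g. a stage level with no patients) are
    dropped with a warning: predictive weights are undefined for them.
    """
    schema.check(covariates)
    cols = {}
    for name in schema.continuous:
        col = pd.to_numeric(covariates[name], errors="raise").astype(float)
        if col.isna().any():
            raise ValueError(f"missing values in continuous covariate {name!r}")
        cols[name] = col
    for name, ref in schema.categorical.items():
        values = covariates[name].astype(str)
        allowed = None if levels is None or name not in levels else {str(v) for v in levels[name]}
        observed = sorted(set(values))
        if allowed is not None:
            unseen = sorted(set(observed) - allowed - {str(ref)})
            if unseen:
                raise ValueError(f"unseen level(s) {unseen} in covariate {name!r}")
            observed = sorted(allowed | set(observed))
        for level in observed:
            if level == str(ref):
                continue
            cols[f"{name}={level}"] = (values == level).astype(float)
    out = pd.DataFrame(cols, index=covariates.index)
    if drop_constant:
        const = [c for c in out.columns if out[c].nunique() <= 1]
        if const:
            warnings.warn(f"dropping zero-variance covariate columns: {const}")
            out = out.drop(columns=const)
    return out


def assemble_design(
    metabolites: MetaboliteMatrix,
    covariates: pd.DataFrame | None = None,
    scale: bool = False,
) -> DesignMatrix:
    """Concatenate metabolite and covariate columns and mean-center.

    Metabolite columns are renamed ``<compound_id>_<tissue suffix>`` (the
    supplementary-table convention).  With ``scale=True`` columns are also
    divided by their standard deviation.
    """
    suffix = TISSUE_SUFFIX[metabolites.tissue]
    metab = metabolites.values.copy()
    metab.columns = [f"{c}_{suffix}" for c in metab.columns]
    meta_rows = [
        {"name": name, "source": "metabolite", "compound_id": cid}
        for name, cid in zip(metab.columns, metabolites.values.columns)
    ]
    parts = [metab]
    if covariates is not None and covariates.shape[1]:
        if not covariates.index.equals(metab.index):
            if set(covariates.index) != set(metab.index):
                raise ValueError("patient sets of metabolites and covariates differ")
            covariates = covariates.loc[metab.index]
        parts.append(covariates.astype(float))
        for name in covariates.columns:
            source = "covariate_dummy" if "=" in name else "covariate_continuous"
            meta_rows.append({"name": name, "source": source, "compound_id": None})
    raw = pd.concat(parts, axis=1)
    zero_var = [c for c in raw.columns if raw[c].nunique() <= 1]
    if zero_var:
        warnings.warn(f"dropping zero-variance design columns: {zero_var}")
        raw = raw.drop(columns=zero_var)
        meta_rows = [r for r in meta_rows if r["name"] not in set(zero_var)]
    X = raw - raw.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    meta = pd.DataFrame(meta_rows).reset_index(drop=True)
    return DesignMatrix(X=X, meta=meta, raw=raw)
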