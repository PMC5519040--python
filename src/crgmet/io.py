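"""Cohort data container and the wide supplementary-table file layout.

A cohort bundle holds the long-format volume table, the covariate table,
the benign and tumor metabolite matrices (with below-LOD masks) and the
metabolite annotation table.  On disk the metabolite data uses the wide
convention of the study's supplementary cohort sheet: one row per
patient, one column per compound and tissue named
``<compound_id>_benign`` / ``<compound_id>_tumor`` /
``<compound_id>_benign_tumor_fc``, with below-LOD measurements as empty
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MetaboliteMatrix

__all__ = ["CohortData", "write_s1_layout", "load_s1_dir"]

METABOLITE_FILE = "cohort_metabolites.csv"
COVARIATE_FILE = "cohort_covariates.csv"
VOLUME_FILE = "cohort_volumes.csv"
ANNOTATION_FILE = "metabolite_annotations.csv"


@dataclass
class CohortData:
    """In-memory cohort bundle consumed by the analysis pipeline."""

    volumes: pd.DataFrame
    covariates: pd.DataFrame
    benign: MetaboliteMatrix
    tumor: MetaboliteMatrix
    annotations: pd.DataFrame


def _wide_block(matrix: MetaboliteMatrix, suffix: str) -> pd.DataFrame:
    block = matrix.values.where(~matrix.below_lod)
    block.columns = [f"{c}_{suffix}" for c in matrix.values.columns]
    return block


def write_s1_layout(data: CohortData, out_dir) -> dict:
    """Write the cohort bundle in the wide supplementary-table convention.

    Below-LOD cells are written as empty fields.  The fold-change block
    is the raw benign/tumor ratio, empty wherever either tissue was below
    LOD.  Returns the mapping of written file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    benign = _wide_block(data.benign, "benign")
    tumor = _wide_block(data.tumor, "tumor")
    shared = [c for c in data.benign.values.columns if c in set(data.tumor.values.columns)]
    patients = [p for p in data.benign.values.index if p in set(data.tumor.values.index)]
    fc_cols = {}
    for cid in shared:
        b = data.benign.values.loc[patients, cid].where(~data.benign.below_lod.loc[patients, cid])
        t = data.tumor.values.loc[patients, cid].where(~data.tumor.below_lod.loc[patients, cid])
        fc_cols[f"{cid}_benign_tumor_fc"] = b / t
    fc = pd.DataFrame(fc_cols, index=pd.Index(patients, name=data.benign.values.index.name))
    wide = pd.concat([benign, tumor, fc], axis=1)
    wide.index.name = "patient_id"
    paths = {
        "metabolites": out / METABOLITE_FILE,
        "covariates": out / COVARIATE_FILE,
        "volumes": out / VOLUME_FILE,
        "annotations": out / ANNOTATION_FILE,
    }
    wide.to_csv(paths["metabolites"])
    cov = data.covariates.copy()
    cov.index.name = "patient_id"
    cov.to_csv(paths["covariates"])
    data.volumes.to_csv(paths["volumes"], index=False)
    data.annotations.to_csv(paths["annotations"], index=False)
    return paths


def _matrix_from_wide(wide: pd.DataFrame, suffix: str, tissue: str) -> MetaboliteMatrix:
    tail = f"_{suffix}"
    cols = [c for c in wide.columns if c.endswith(tail)]
    if suffix in ("benign", "tumor"):
        cols = [c for c in cols if not c.endswith("_benign_tumor_fc")]
    block = wide[cols].apply(pd.to_numeric, errors="coerce")
    block.columns = [c[: -len(tail)] for c in cols]
    mask = block.isna()
    return MetaboliteMatrix(block.fillna(0.0), mask, tissue)


def load_s1_dir(path) -> CohortData:
    """Read a cohort bundle written by :func:`write_s1_layout`."""
    path = Path(path)
    wide = pd.read_csv(path / METABOLITE_FILE, index_col="patient_id")
    covariates = pd.read_csv(path / COVARIATE_FILE, index_col="patient_id")
    volumes = pd.read_csv(path / VOLUME_FILE)
    annotations = pd.read_csv(path / ANNOTATION_FILE, dtype={"compound_id": str})
    benign = _matrix_from_wide(wide, "benign", "benign")
    tumor = _matrix_from_wide(wide, "tumor", "tumor")
    return CohortData(
        volumes=volumes,
        covariates=covariates,
        benign=benign,
        tumor=tumor,
        annotations=annotations,
    )
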