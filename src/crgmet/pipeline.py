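"""End-to-end analyses: response construction through enrichment.

Four analyses mirror the study design, each pairing a metabolite matrix
with a CRG response:

* ``benign_preop`` — benign-tissue abundances vs pre-operative CRG;
* ``tumor_preop`` — tumor-tissue abundances vs pre-operative CRG;
* ``foldchange_preop`` — benign/tumor abundance fold change vs
  pre-operative CRG;
* ``benign_lt`` — benign-tissue abundances vs long-term CRG (radical
  nephrectomy patients with follow-up imaging only).

Each run executes volumetry QC, preprocessing, the OPLS fit with
cross-validation and response-permutation validation, the univariable
reference regressions with FDR, the dual-criterion significance calls,
and directional sub-pathway enrichment, then writes CSV outputs plus a
JSON manifest recording every setting.  Stage boundaries are logged with
row/column counts so filter effects leave an audit trail.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import enrichment as enrich_mod
from .contrast import ContrastResult, fit_contrast
from .io import CohortData
from .opls import OPLSRegressor, PermutationReport, permutation_test
from .preprocess import (
    TABLE1_SCHEMA,
    assemble_design,
    compute_fold_change,
    encode_covariates,
    preprocess_matrix,
)
from .volumetry import build_responses

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "run_contrast", "ANALYSES"]

ANALYSES = ("benign_preop", "tumor_preop", "foldchange_preop", "benign_lt")


@dataclass
class RunConfig:
    """Settings of one analysis run; hashed into the output manifest."""

    analysis: str = "benign_preop"
    vip_threshold: float = 1.0
    fdr_alpha: float = 0.05
    n_folds: int = 8
    n_perm_opls: int = 1000
    n_perm_enrich: int = 10000
    n_ortho: int | str = "auto"
    max_bdl_fraction: float = 0.75
    min_set_size: int = 3
    scaling: str = "center_scale"
    seed: int = 0

    def __post_init__(self):
        if self.analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}; choose from {ANALYSES}")
        if self.vip_threshold <= 0 or not (0 < self.fdr_alpha < 1):
            raise ValueError("thresholds must be positive (and alpha in (0,1))")
        if self.scaling not in ("center", "center_scale"):
            raise ValueError("scaling must be 'center' or 'center_scale'")

    def to_dict(self) -> dict:
        return asdict(self)

    def manifest_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisResult:
    config: RunConfig
    association: pd.DataFrame
    enrichment: pd.DataFrame
    permutation: PermutationReport
    model: OPLSRegressor = field(repr=False)
    response: pd.Series = field(repr=False)
    manifest: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.association[self.association["class"].str.startswith("significant")]

    def class_counts(self) -> dict:
        return self.association["class"].value_counts().to_dict()


def _select_response(data: CohortData, analysis: str) -> pd.Series:
    responses = build_responses(data.volumes)
    kind = "long_term" if analysis == "benign_lt" else "preop"
    sel = responses[(responses["kind"] == kind) & ~responses["qc_excluded"] & responses["crg"].notna()]
    n_excluded = int(responses[(responses["kind"] == "preop") & responses["qc_excluded"]].shape[0])
    logger.info("volumetry: %d %s responses (%d QC-excluded patients)", sel.shape[0], kind, n_excluded)
    return sel.set_index("patient_id")["crg"]


def _analysis_matrix(data: CohortData, config: RunConfig):
    benign = preprocess_matrix(data.benign, config.max_bdl_fraction)
    if config.analysis == "foldchange_preop":
        tumor = preprocess_matrix(data.tumor, config.max_bdl_fraction)
        return compute_fold_change(benign, tumor)
    if config.analysis == "tumor_preop":
        return preprocess_matrix(data.tumor, config.max_bdl_fraction)
    return benign


def run_analysis(config: RunConfig, data: CohortData, out_dir=None) -> AnalysisResult:
    """Execute one configured analysis on a cohort bundle."""
    y_all = _select_response(data, config.analysis)
    matrix = _analysis_matrix(data, config)
    logger.info(
        "preprocess (%s): %d of %d metabolites retained",
        matrix.tissue, len(matrix.metabolite_ids), len(data.benign.metabolite_ids),
    )

    patients = [p for p in matrix.patients if p in set(y_all.index)]
    if not patients:
        raise ValueError("no overlap between response patients and metabolite matrix")
    if len(patients) < 10:
        warnings.warn(f"only {len(patients)} overlapping patients; model will be unstable")
    y = y_all.loc[patients].to_numpy(dtype=float)

    covariates = encode_covariates(data.covariates.loc[patients], TABLE1_SCHEMA)
    design = assemble_design(
        matrix.subset(patients=patients), covariates,
        scale=(config.scaling == "center_scale"),
    )
    logger.info("design: %d patients x %d variables", *design.X.shape)

    model = OPLSRegressor(
        n_ortho=config.n_ortho, n_folds=min(config.n_folds, len(patients) // 2),
        random_state=config.seed,
    ).fit(design.X, y)
    logger.info("opls: n_ortho=%d R2Y=%.3f Q2=%.3f", model.n_ortho_, model.r2y_, model.q2_)

    table = assoc_mod.build_association_table(
        design, model, y, vip_threshold=config.vip_threshold, alpha=config.fdr_alpha,
    )
    ranked = enrich_mod.rank_variables(table, data.annotations)
    enrichment = enrich_mod.enrichment_significance(
        ranked, n_perm=config.n_perm_enrich, random_state=config.seed + 1,
        min_set_size=config.min_set_size,
    )
    report = permutation_test(
        design.X.to_numpy(), y, n_perm=config.n_perm_opls,
        n_folds=min(config.n_folds, len(patients) // 2),
        n_ortho=model.n_ortho_, random_state=config.seed + 2,
    )

    manifest = {
        "config": config.to_dict(),
        "manifest_hash": config.manifest_hash(),
        "n_patients": len(patients),
        "n_variables": int(design.X.shape[1]),
        "n_metabolites_input": len(data.benign.metabolite_ids),
        "n_metabolites_retained": len(matrix.metabolite_ids),
        "n_ortho": int(model.n_ortho_),
        "r2y": float(model.r2y_),
        "q2": float(model.q2_),
        "permutation": report.to_dict(),
        "class_counts": table["class"].value_counts().to_dict(),
    }
    result = AnalysisResult(
        config=config, association=table, enrichment=enrichment,
        permutation=report, model=model,
        response=pd.Series(y, index=pd.Index(patients, name="patient_id"), name="crg"),
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_csv_with_hash(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest_hash={manifest_hash}\n")
        df.to_csv(fh, index=False)


def _write_outputs(result: AnalysisResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = result.config.analysis
    h = result.manifest["manifest_hash"]
    _write_csv_with_hash(result.association, out_dir / f"{tag}_association.csv", h)
    _write_csv_with_hash(result.enrichment, out_dir / f"{tag}_enrichment.csv", h)
    (out_dir / f"{tag}_manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


def run_contrast(
    data: CohortData,
    metabolite_id: str,
    max_bdl_fraction: float = 0.75,
) -> ContrastResult:
    """Detrended two-tissue contribution contrast for one metabolite.

    Uses the pre-operative CRG response and the preprocessed benign and
    tumor abundances of the metabolite; series are ordered by the
    patient-index order of the metabolite table (recorded property of
    the result, as detrending is order-sensitive).
    """
    y_all = _select_response(data, "benign_preop")
    benign = preprocess_matrix(data.benign, max_bdl_fraction)
    tumor = preprocess_matrix(data.tumor, max_bdl_fraction)
    metabolite_id = str(metabolite_id)
    for tissue, mat in (("benign", benign), ("tumor", tumor)):
        if metabolite_id not in mat.values.columns:
            raise KeyError(f"metabolite {metabolite_id!r} not retained in {tissue} matrix")
    patients = [p for p in benign.patients if p in set(tumor.patients) and p in set(y_all.index)]
    return fit_contrast(
        y_all.loc[patients].to_numpy(),
        tumor.values.loc[patients, metabolite_id].to_numpy(),
        benign.values.loc[patients, metabolite_id].to_numpy(),
        metabolite_id=metabolite_id,
    )
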