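"""Repeatable calibration experiments for the modeling machinery.

These experiments generate many small synthetic cohorts and measure
statistical operating characteristics of the pipeline:

* ``vip_recovery_experiment`` — how well VIP ranking recovers a handful
  of planted metabolites among hundreds of noise metabolites at the
  study's sample size;
* ``permutation_type_i_experiment`` — the rejection rate of the
  response-permutation model test on null cohorts (should match the
  nominal alpha);
* ``enrichment_power_experiment`` — how often a planted coordinated
  sub-pathway is detected by the directional enrichment test at FDR
  control.

They run on metabolite-only designs with the true (noise-free-response)
CRG so that each experiment isolates the statistical property of the
modeling step it targets rather than compounding volumetry noise.
"""

from __future__ import annotations

import numpy as np

from .association import build_association_table
from .enrichment import enrichment_significance, rank_variables
from .opls import OPLSRegressor, permutation_test
from .preprocess import assemble_design, preprocess_matrix
from .synthetic import SyntheticTruth, _compound_ids, generate_metabolome, make_annotations

__all__ = [
    "vip_recovery_experiment",
    "permutation_type_i_experiment",
    "enrichment_power_experiment",
]


def _metabolite_design(n_patients: int, n_metabolites: int, truth: SyntheticTruth, seed,
                       n_identified: int = 0):
    """Metabolite-only scaled design plus the true CRG response."""
    benign, _tumor, annotations, crg_true, _g = generate_metabolome(
        n_patients, n_metabolites, n_identified, truth, seed=seed, lod_quantile=0.0,
    )
    matrix = preprocess_matrix(benign)
    design = assemble_design(matrix, covariates=None, scale=True)
    return design, crg_true, annotations


def vip_recovery_experiment(
    n_seeds: int = 50,
    n_patients: int = 49,
    n_noise: int = 500,
    n_planted: int = 10,
    beta: float = 0.5,
    base_seed: int = 0,
) -> np.ndarray:
    """Median VIP rank of the planted metabolite set, one value per seed.

    ``n_planted`` metabolites with standardized loading ``beta`` on the
    CRG drive are hidden among ``n_noise`` noise metabolites; the OPLS
    fit (automatic orthogonal-component selection) ranks all variables
    by VIP and the planted set's median rank is recorded.
    """
    n_total = n_noise + n_planted
    planted_ids = _compound_ids(n_total)[:n_planted]
    ranks = np.empty(n_seeds)
    for s in range(n_seeds):
        seed = base_seed + s
        truth = SyntheticTruth(benign_effects={cid: beta for cid in planted_ids})
        design, y, _ = _metabolite_design(n_patients, n_total, truth, seed)
        model = OPLSRegressor(n_ortho="auto", random_state=seed).fit(design.X, y)
        order = np.argsort(-model.vip_)
        name_by_rank = design.X.columns.to_numpy()[order]
        planted_names = {f"{cid}_benign" for cid in planted_ids}
        positions = [i + 1 for i, name in enumerate(name_by_rank) if name in planted_names]
        ranks[s] = float(np.median(positions))
    return ranks


def permutation_type_i_experiment(
    n_cohorts: int = 200,
    n_patients: int = 49,
    n_metabolites: int = 500,
    n_perm: int = 199,
    n_folds: int = 8,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> np.ndarray:
    """Permutation-test p-values on null cohorts (no planted effects).

    The response is generated independently of every metabolite, so the
    empirical p-value is uniform by exchangeability and the rejection
    rate at ``alpha`` estimates the type-I error.  The number of
    orthogonal components is fixed at 0 so the measured property is the
    permutation p-value itself, not the component selection.
    """
    pvals = np.empty(n_cohorts)
    for s in range(n_cohorts):
        seed = base_seed + s
        design, y, _ = _metabolite_design(n_patients, n_metabolites, SyntheticTruth.empty(), seed)
        report = permutation_test(
            design.X.to_numpy(), y, n_perm=n_perm, n_folds=n_folds,
            n_ortho=0, random_state=seed,
        )
        pvals[s] = report.p_value
    return pvals


def enrichment_power_experiment(
    n_seeds: int = 50,
    n_patients: int = 49,
    n_metabolites: int = 500,
    beta: float = 0.5,
    n_perm: int = 2000,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> np.ndarray:
    """Per-seed FDR-adjusted p of one planted coordinated sub-pathway.

    All metabolites are identified and annotated; one sub-pathway's
    members are planted with a common positive loading (plus the shared
    set factor), the OPLS VIP ranking is computed, and the planted set's
    enrichment FDR is recorded.
    """
    results = np.empty(n_seeds)
    for s in range(n_seeds):
        seed = base_seed + s
        annotations = make_annotations(n_metabolites, n_metabolites, seed)
        by_size = annotations.groupby("sub_pathway")["compound_id"].apply(list)
        target = by_size.index[0]
        truth = SyntheticTruth(
            benign_effects={cid: beta for cid in by_size[target]},
            enriched_sets={"benign": {target: "positive"}},
        )
        benign, _t, annotations, y, _g = generate_metabolome(
            n_patients, n_metabolites, n_metabolites, truth,
            seed=seed, annotations=annotations, lod_quantile=0.0,
        )
        design = assemble_design(preprocess_matrix(benign), covariates=None, scale=True)
        model = OPLSRegressor(n_ortho="auto", random_state=seed).fit(design.X, y)
        table = build_association_table(design, model, y)
        ranked = rank_variables(table, annotations)
        enr = enrichment_significance(ranked, n_perm=n_perm, random_state=seed)
        row = enr[(enr["sub_pathway"] == target) & (enr["direction"] == "positive")]
        results[s] = float(row["fdr_p"].iloc[0])
    return results
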