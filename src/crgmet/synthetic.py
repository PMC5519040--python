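"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a nephrectomy cohort: clinical covariates drawn to
match the study population's marginals, kidney/tumor volumes with
dual-observer measurement noise, and benign/tumor metabolite matrices of
877 compounds (577 of them identified and annotated to sub-pathways) with
below-LOD censoring heavy enough that roughly the observed share of
metabolites fails the 75% detection filter.

The dependence structure is a single latent patient trait ``G`` (the
"CRG drive"): each planted metabolite's log-abundance loads on ``G`` with
a standardized coefficient beta, members of a planted sub-pathway share
an additional set factor (pathway co-regulation), and the log of the true
CRG is linear in ``G`` with Gaussian noise scaled so that ``G`` explains
a chosen population R^2 of it.  The marginal correlation of a planted
metabolite with CRG is therefore ``beta * sqrt(r2)`` (up to the mild
lognormal attenuation), which makes planted effect sizes directly
interpretable.

Ground truth (planted effects, enriched sets, landmark metabolites) is
returned alongside every dataset so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.utils import check_random_state

from .io import CohortData, write_s1_layout
from .preprocess import MetaboliteMatrix

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_metabolome",
    "generate_dataset",
    "emulate_s1_layout",
    "SUB_PATHWAY_CATALOG",
]

#: Sub-pathway vocabulary in the style of non-targeted metabolomics
#: annotation tables.
SUB_PATHWAY_CATALOG = (
    "carnitine metabolism",
    "fatty acid, medium chain",
    "fatty acid, monohydroxy",
    "long chain fatty acid",
    "monoacylglycerol",
    "dipeptide",
    "gamma-glutamyl amino acid",
    "glycolysis, gluconeogenesis, pyruvate metabolism",
    "lysolipid",
    "benzoate metabolism",
    "nucleotide sugar, pentose metabolism",
    "sphingolipid",
    "bile acid metabolism",
    "tca cycle",
    "purine metabolism",
    "pyrimidine metabolism",
    "glutathione metabolism",
    "tryptophan metabolism",
    "tyrosine metabolism",
    "branched chain amino acid metabolism",
    "urea cycle; arginine and proline metabolism",
    "glycine, serine and threonine metabolism",
    "phospholipid metabolism",
    "steroid",
    "tocopherol metabolism",
    "food component/plant",
    "hemoglobin and porphyrin metabolism",
    "xanthine metabolism",
)

#: Study-population marginals used as generator defaults.
COHORT_MARGINALS = {
    "age": (60.0, 11.6, 37.0, 86.0),  # mean, sd, min, max
    "male_fraction": 0.796,
    "race_probs": {"white": 0.877, "afro_american": 0.102, "other": 0.021},
    "preop_gfr": (69.0, 16.35),
    "diabetes": 0.184,
    "bmi": (30.9, 6.55),
    "hyperlipidemia": 0.408,
    "coronary_artery_disease": 0.143,
    "hypertension": 0.633,
    "smoking": 0.51,
    "tumor_volume_lognorm": (5.128, 0.807),  # fits mean 233.7 cc, sd 224.1 cc
    "t_stage_probs": {
        "pT1a": 0.122, "pT1b": 0.102, "pT2a": 0.082, "pT2b": 0.0,
        "pT3a": 0.204, "pT3b": 0.449, "pT4": 0.041,
    },
    "grade_probs": {"2": 0.352, "2~3": 0.020, "3": 0.508, "4": 0.120},
    "ajcc_probs": {"1": 0.224, "2": 0.082, "3": 0.653, "4": 0.041},
    "radical_fraction": 0.653,
    "ct_fraction": 0.939,
    "lt_fraction": 0.688,  # share of radical-nephrectomy patients with follow-up imaging
    "dual_fraction": 42.0 / 52.0,
}

#: Share of metabolites that are rarely detected (mostly below LOD) and
#: hence fail the 75% detection filter; calibrated to the study's
#: retention of 736 (benign) and 724 (tumor) of 877 metabolites.
RARE_BDL_FRACTION = {"benign": 141.0 / 877.0, "tumor": 153.0 / 877.0}

DEFAULT_OBSERVER_SIGMA = 0.095  # per-observer CRG log-sd; ~6.5% of ratios outside (0.75, 1.25)
DEFAULT_LOG_SIGMA = 0.5  # metabolite log-abundance dispersion
CRG_LOG_MEDIAN = np.log(1.15)
CRG_LOG_SCALE = 0.15
LT_CRG_LOG_MEDIAN = np.log(1.12)
LT_CRG_LOG_SCALE = 0.10


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset.

    ``benign_effects`` / ``tumor_effects`` map compound id to the
    standardized loading of that metabolite's log-abundance on the latent
    CRG drive.  ``enriched_sets`` maps tissue -> sub-pathway -> planted
    direction.  ``landmarks`` names special planted metabolites (the
    standout benign positive, the sole strong tumor negative, the
    anti-correlated fold-change compounds).
    """

    benign_effects: dict = field(default_factory=dict)
    tumor_effects: dict = field(default_factory=dict)
    enriched_sets: dict = field(default_factory=dict)
    landmarks: dict = field(default_factory=dict)
    r2: float = 0.75
    set_residual_corr: float = 0.15
    shared_residual_corr: float = 0.5
    seed: int | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def empty(cls, r2: float = 0.75) -> "SyntheticTruth":
        """No planted effects: the null cohort."""
        return cls(r2=r2)


# Planted structure of the default truth: (sub_pathway, n_members, beta).
_DEFAULT_BENIGN_SETS = (
    ("carnitine metabolism", 5, 0.90),
    ("fatty acid, medium chain", 4, 0.90),
    ("fatty acid, monohydroxy", 3, 0.85),
)
_DEFAULT_TUMOR_POS_SETS = (
    ("dipeptide", 12, 0.75),
    ("gamma-glutamyl amino acid", 10, 0.75),
)
_DEFAULT_TUMOR_NEG_SETS = (
    ("glycolysis, gluconeogenesis, pyruvate metabolism", 0, -0.25),
    ("lysolipid", 0, -0.25),
    ("benzoate metabolism", 0, -0.25),
    ("nucleotide sugar, pentose metabolism", 0, -0.25),
)
_MILD_BETA = 0.35  # sub-significant individually, drives set-level enrichment
_N_UNIDENTIFIED_TUMOR_POS = 8


def _compound_ids(n: int) -> list[str]:
    return [str(10000 + i) for i in range(n)]


def make_annotations(n_metabolites: int = 877, n_identified: int = 577, random_state=None) -> pd.DataFrame:
    """Annotation table: compound id, biochemical name, identified flag, sub-pathway.

    Identified metabolites carry a sub-pathway from the catalog (sizes
    drawn at random); unidentified ones have neither name nor
    sub-pathway, mirroring non-targeted platform output.
    """
    if n_identified > n_metabolites:
        raise ValueError("n_identified cannot exceed n_metabolites")
    rng = check_random_state(random_state)
    ids = _compound_ids(n_metabolites)
    identified = np.zeros(n_metabolites, dtype=bool)
    identified[:n_identified] = True
    sub = np.full(n_metabolites, None, dtype=object)
    if n_identified:
        # Every catalog pathway gets a guaranteed base membership; the
        # remainder is spread with random (Dirichlet-weighted) sizes.
        n_paths = len(SUB_PATHWAY_CATALOG)
        base = min(12, n_identified // n_paths)
        counts = np.full(n_paths, base)
        remainder = n_identified - int(counts.sum())
        if remainder > 0:
            weights = rng.dirichlet(np.full(n_paths, 2.0))
            extra = rng.choice(n_paths, size=remainder, p=weights)
            np.add.at(counts, extra, 1)
        assignment = np.repeat(np.asarray(SUB_PATHWAY_CATALOG, dtype=object), counts)
        sub[:n_identified] = rng.permutation(assignment)
    names = np.full(n_metabolites, None, dtype=object)
    names[:n_identified] = [f"metabolite-{i:04d}" for i in range(n_identified)]
    return pd.DataFrame({
        "compound_id": ids,
        "biochemical_name": names,
        "identified": identified,
        "sub_pathway": sub,
    })


def default_truth(annotations: pd.DataFrame, r2: float = 0.75, set_residual_corr: float = 0.15,
                  random_state=None) -> SyntheticTruth:
    """Default planted structure emulating the study's qualitative findings.

    Benign tissue: three positively associated fatty-acid/carnitine
    sub-pathways (12 members) plus one standout positive metabolite (13
    planted positives).  Tumor tissue: two strongly positive sub-pathways
    plus unidentified positives, several weakly negative sub-pathways
    (coordinated but individually sub-significant), and one strong sole
    negative metabolite.  Three metabolites get anti-correlated
    benign/tumor loadings so their fold change associates with CRG even
    though neither tissue alone is significant.
    """
    rng = check_random_state(random_state)
    ann = annotations.set_index("compound_id")
    by_sub: dict = {}
    for cid, row in ann.iterrows():
        if row["identified"] and row["sub_pathway"] is not None:
            by_sub.setdefault(row["sub_pathway"], []).append(cid)
    unidentified = list(ann.index[~ann["identified"].astype(bool)])

    used: set = set()

    def take(sub_pathway: str, k: int) -> list[str]:
        pool = [c for c in by_sub.get(sub_pathway, []) if c not in used]
        if len(pool) < k:
            raise ValueError(f"sub-pathway {sub_pathway!r} has only {len(pool)} free members, need {k}")
        picked = list(rng.choice(pool, size=k, replace=False))
        used.update(picked)
        return picked

    def spread(sub_pathway: str, effects: dict, mild_beta: float) -> None:
        # Pathway enrichment reflects a coordinated shift of (nearly) the
        # whole set, not just its headline members: the remaining free
        # members get a mild same-sign loading.
        rest = [c for c in by_sub.get(sub_pathway, []) if c not in used]
        for cid in rest:
            effects[cid] = mild_beta
        used.update(rest)

    benign: dict = {}
    tumor: dict = {}
    enriched = {"benign": {}, "tumor": {}}

    for sub_pathway, k, beta in _DEFAULT_BENIGN_SETS:
        for cid in take(sub_pathway, k):
            benign[cid] = beta
        spread(sub_pathway, benign, _MILD_BETA)
        enriched["benign"][sub_pathway] = "positive"
    for sub_pathway, k, beta in _DEFAULT_TUMOR_POS_SETS:
        for cid in take(sub_pathway, k):
            tumor[cid] = beta
        spread(sub_pathway, tumor, _MILD_BETA)
        enriched["tumor"][sub_pathway] = "positive"
    for sub_pathway, _k, beta in _DEFAULT_TUMOR_NEG_SETS:
        spread(sub_pathway, tumor, beta)
        enriched["tumor"][sub_pathway] = "negative"

    landmarks = {}
    standout = take("hemoglobin and porphyrin metabolism", 1)[0]
    benign[standout] = 0.95
    landmarks["standout_benign_positive"] = standout

    sole_neg = take("tryptophan metabolism", 1)[0]
    tumor[sole_neg] = -0.80
    landmarks["sole_negative_tumor"] = sole_neg

    fc_ids = take("tyrosine metabolism", 3)
    for i, cid in enumerate(fc_ids):
        benign[cid] = 0.55 if i == 0 else 0.50
        tumor[cid] = -0.60 if i == 0 else -0.50
    landmarks["fc_anticorrelated"] = fc_ids
    landmarks["fc_primary"] = fc_ids[0]

    if len(unidentified) >= _N_UNIDENTIFIED_TUMOR_POS:
        for cid in rng.choice(unidentified, size=_N_UNIDENTIFIED_TUMOR_POS, replace=False):
            tumor[cid] = 0.75

    return SyntheticTruth(
        benign_effects=benign,
        tumor_effects=tumor,
        enriched_sets=enriched,
        landmarks=landmarks,
        r2=r2,
        set_residual_corr=set_residual_corr,
    )


def _bdl_fractions(n_metabolites: int, rare_fraction: float, protected: np.ndarray, rng) -> np.ndarray:
    """Per-metabolite below-LOD fraction: mostly-detected bulk + rarely-detected tail."""
    common = 0.7 * rng.beta(0.7, 5.0, size=n_metabolites)
    rare = rng.uniform(0.78, 0.97, size=n_metabolites)
    # effect-carrying metabolites stay quantifiable; upweight the rare
    # probability among the rest so the cohort-level rare share holds
    n_free = n_metabolites - int(protected.sum())
    p_rare = min(1.0, rare_fraction * n_metabolites / max(1, n_free))
    is_rare = rng.random_sample(n_metabolites) < p_rare
    is_rare &= ~protected
    return np.where(is_rare, rare, common)


def _censor(values: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Mask the lowest round(f*n) values of each metabolite (empirical-quantile LOD)."""
    n = values.shape[0]
    mask = np.zeros_like(values, dtype=bool)
    counts = np.rint(fractions * n).astype(int)
    order = np.argsort(values, axis=0)
    for j, k in enumerate(counts):
        if k > 0:
            mask[order[:k, j], j] = True
    return mask


def _tissue_latents(
    n_patients: int,
    annotations: pd.DataFrame,
    effects: dict,
    planted_sets: dict,
    set_residual_corr: float,
    shared_residual_corr: float,
    g: np.ndarray,
    shared_noise: np.ndarray,
    rng,
) -> np.ndarray:
    """Standardized log-abundance latents for one tissue.

    ``z = beta*G + sqrt(rho)*eta_set + residual`` where the residual
    splits into a patient-level component shared between the two tissues
    of the same compound (fraction ``shared_residual_corr`` of residual
    variance — matched benign/tumor samples co-vary) and an
    idiosyncratic remainder.
    """
    ids = annotations["compound_id"].to_numpy(dtype=object)
    sub = annotations["sub_pathway"].to_numpy(dtype=object)
    beta = np.array([float(effects.get(cid, 0.0)) for cid in ids])
    if np.any(np.abs(beta) > 1.0):
        raise ValueError("standardized effects must lie in [-1, 1]")
    rho = np.zeros(len(ids))
    set_factor = np.zeros((n_patients, len(ids)))
    for sub_pathway in planted_sets:
        members = (sub == sub_pathway) & (beta != 0)
        if members.any():
            rho[members] = set_residual_corr
            set_factor[:, members] = rng.standard_normal(n_patients)[:, None]
    resid_var = 1.0 - beta**2 - rho
    if np.any(resid_var < 0):
        raise ValueError("beta^2 + set correlation exceeds 1; requested structure infeasible")
    if not (0.0 <= shared_residual_corr < 1.0):
        raise ValueError("shared_residual_corr must lie in [0, 1)")
    eps = rng.standard_normal((n_patients, len(ids)))
    resid = np.sqrt(shared_residual_corr) * shared_noise + np.sqrt(1.0 - shared_residual_corr) * eps
    return g[:, None] * beta[None, :] + np.sqrt(rho)[None, :] * set_factor + np.sqrt(resid_var)[None, :] * resid


def generate_metabolome(
    n_patients: int,
    n_metabolites: int = 877,
    n_identified: int = 577,
    truth: SyntheticTruth | None = None,
    seed=None,
    annotations: pd.DataFrame | None = None,
    g: np.ndarray | None = None,
    log_sigma: float = DEFAULT_LOG_SIGMA,
    rare_bdl_fraction: dict | float | None = None,
    lod_quantile: float | None = None,
    patient_ids=None,
):
    """Benign and tumor metabolite matrices plus annotations and true CRG.

    Abundances are lognormal around metabolite-specific baselines; the
    true CRG is exp-linear in the latent drive ``G`` with noise scaled so
    ``G`` explains ``truth.r2`` of log-CRG variance.  Censoring marks the
    lowest per-metabolite quantile as below LOD; ``lod_quantile`` forces
    one quantile for every metabolite (0 disables censoring), otherwise
    per-metabolite fractions are drawn with a rarely-detected tail sized
    by ``rare_bdl_fraction``.

    Returns ``(benign, tumor, annotations, crg_true, g)``.
    """
    rng = check_random_state(seed)
    if truth is None:
        truth = SyntheticTruth.empty()
    if annotations is None:
        annotations = make_annotations(n_metabolites, n_identified, rng)
    if g is None:
        g = rng.standard_normal(n_patients)
    if patient_ids is None:
        patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    if not (0.0 < truth.r2 <= 1.0):
        raise ValueError("requested R^2 must lie in (0, 1]")

    noise = np.sqrt(1.0 - truth.r2) * rng.standard_normal(n_patients)
    crg_true = np.exp(CRG_LOG_MEDIAN + CRG_LOG_SCALE * (np.sqrt(truth.r2) * g + noise))

    matrices = {}
    shared_noise = rng.standard_normal((n_patients, len(annotations)))
    for tissue, effects in (("benign", truth.benign_effects), ("tumor", truth.tumor_effects)):
        z = _tissue_latents(
            n_patients, annotations, effects,
            truth.enriched_sets.get(tissue, {}), truth.set_residual_corr,
            truth.shared_residual_corr, g, shared_noise, rng,
        )
        baseline = rng.normal(1.0, 0.8, size=z.shape[1])
        values = np.exp(baseline[None, :] + log_sigma * z)
        if lod_quantile is not None:
            fractions = np.full(z.shape[1], float(lod_quantile))
        else:
            rare = rare_bdl_fraction
            if rare is None:
                rare = RARE_BDL_FRACTION[tissue]
            elif isinstance(rare, dict):
                rare = rare[tissue]
            protected = np.array([cid in effects for cid in annotations["compound_id"]])
            fractions = _bdl_fractions(z.shape[1], float(rare), protected, rng)
        mask = _censor(values, fractions)
        idx = pd.Index(patient_ids, name="patient_id")
        cols = annotations["compound_id"].tolist()
        vdf = pd.DataFrame(values, index=idx, columns=cols)
        mdf = pd.DataFrame(mask, index=idx, columns=cols)
        vdf = vdf.mask(mdf, 0.0)  # censored cells carry no information
        matrices[tissue] = MetaboliteMatrix(vdf, mdf, tissue)

    return matrices["benign"], matrices["tumor"], annotations, crg_true, g


def generate_cohort(
    n_patients: int = 49,
    seed=None,
    crg_true: np.ndarray | None = None,
    lt_crg_true: np.ndarray | None = None,
    observer_sigma: float = DEFAULT_OBSERVER_SIGMA,
    dual_fraction: float = COHORT_MARGINALS["dual_fraction"],
    lt_fraction: float = COHORT_MARGINALS["lt_fraction"],
    patient_ids=None,
):
    """Covariate table and long-format volume records for ``n_patients``.

    Covariates are drawn to the study population's marginals.  Volumes
    satisfy VC/VI = true CRG, with independent multiplicative lognormal
    measurement noise per observer (``observer_sigma`` is the implied
    per-observer CRG log-sd).  A ``dual_fraction`` share of patients is
    measured by both observers; radical-nephrectomy patients may carry a
    follow-up scan implementing the long-term response.

    Returns ``(covariates, volumes)``.
    """
    if n_patients < 10:
        raise ValueError("cohort generator needs n_patients >= 10")
    rng = check_random_state(seed)
    m = COHORT_MARGINALS
    if patient_ids is None:
        patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    if crg_true is None:
        crg_true = np.exp(rng.normal(CRG_LOG_MEDIAN, CRG_LOG_SCALE, size=n_patients))
    crg_true = np.asarray(crg_true, dtype=float)

    mean, sd, lo, hi = m["age"]
    age = np.clip(rng.normal(mean, sd, n_patients), lo, hi).round(0)
    tumor_volume = np.exp(rng.normal(*m["tumor_volume_lognorm"], size=n_patients)).round(1)
    smoking = rng.random_sample(n_patients) < m["smoking"]
    pack_years = np.where(smoking, rng.gamma(1.5, 11.4, n_patients), 0.0).round(1)

    def categorical(probs: dict) -> np.ndarray:
        levels = list(probs)
        p = np.asarray([probs[k] for k in levels], dtype=float)
        return rng.choice(levels, size=n_patients, p=p / p.sum())

    def yesno(p: float) -> np.ndarray:
        return np.where(rng.random_sample(n_patients) < p, "yes", "no")

    covariates = pd.DataFrame({
        "age": age,
        "gender": np.where(rng.random_sample(n_patients) < m["male_fraction"], "male", "female"),
        "race": categorical(m["race_probs"]),
        "preop_gfr": np.clip(rng.normal(*m["preop_gfr"], size=n_patients), 5.0, None).round(1),
        "diabetes": yesno(m["diabetes"]),
        "bmi": np.clip(rng.normal(*m["bmi"], size=n_patients), 15.0, 60.0).round(1),
        "hyperlipidemia": yesno(m["hyperlipidemia"]),
        "coronary_artery_disease": yesno(m["coronary_artery_disease"]),
        "hypertension": yesno(m["hypertension"]),
        "smoking": np.where(smoking, "yes", "no"),
        "pack_years": pack_years,
        "tumor_volume_cc": tumor_volume,
        "t_stage": categorical(m["t_stage_probs"]),
        "fuhrman_grade": categorical(m["grade_probs"]),
        "ajcc_stage": categorical(m["ajcc_probs"]),
        "nephrectomy_type": np.where(rng.random_sample(n_patients) < m["radical_fraction"], "radical", "partial"),
        "imaging": np.where(rng.random_sample(n_patients) < m["ct_fraction"], "CT", "MRI"),
    }, index=pd.Index(patient_ids, name="patient_id"))

    vi_true = np.exp(rng.normal(np.log(150.0), 0.25, size=n_patients))
    vc_true = crg_true * vi_true
    sigma_v = observer_sigma / np.sqrt(2.0)  # per-volume noise; CRG log-sd = sigma_v*sqrt(2)
    n_dual = int(round(dual_fraction * n_patients))
    dual = np.zeros(n_patients, dtype=bool)
    dual[rng.choice(n_patients, size=n_dual, replace=False)] = True

    records = []
    for i, pid in enumerate(patient_ids):
        observers = ["obs1", "obs2"] if dual[i] else ["obs1"]
        for obs in observers:
            records.append({
                "patient_id": pid,
                "observer_id": obs,
                "timepoint": "baseline",
                "vc_cc": vc_true[i] * np.exp(rng.normal(0.0, sigma_v)),
                "vi_cc": vi_true[i] * np.exp(rng.normal(0.0, sigma_v)),
                "vtumor_cc": tumor_volume[i],
            })

    radical = covariates["nephrectomy_type"].to_numpy() == "radical"
    has_lt = radical & (rng.random_sample(n_patients) < lt_fraction)
    if lt_crg_true is None:
        lt_crg_true = np.exp(rng.normal(LT_CRG_LOG_MEDIAN, LT_CRG_LOG_SCALE, size=n_patients))
    lt_crg_true = np.asarray(lt_crg_true, dtype=float)
    for i, pid in enumerate(patient_ids):
        if has_lt[i]:
            records.append({
                "patient_id": pid,
                "observer_id": "obs1",
                "timepoint": "followup",
                "vc_cc": vc_true[i] * lt_crg_true[i] * np.exp(rng.normal(0.0, sigma_v)),
                "vi_cc": np.nan,
                "vtumor_cc": np.nan,
            })
    volumes = pd.DataFrame.from_records(records)
    return covariates, volumes


def generate_dataset(
    n_patients: int = 52,
    n_metabolites: int = 877,
    n_identified: int = 577,
    truth: SyntheticTruth | str | None = "default",
    seed=None,
    observer_sigma: float = DEFAULT_OBSERVER_SIGMA,
    r2: float | None = None,
    log_sigma: float = DEFAULT_LOG_SIGMA,
    rare_bdl_fraction: dict | float | None = None,
    lod_quantile: float | None = None,
):
    """Full synthetic cohort bundle plus its ground truth.

    The default ``n_patients`` of 52 mirrors the imaged cohort before
    observer-concordance QC (after which roughly 49 patients remain).
    ``truth="default"`` plants the study-like structure from
    :func:`default_truth`; pass a :class:`SyntheticTruth` for custom
    effects or ``None`` for a null cohort.

    Returns ``(CohortData, SyntheticTruth)``.
    """
    rng = check_random_state(seed)
    annotations = make_annotations(n_metabolites, n_identified, rng)
    if truth == "default":
        truth = default_truth(annotations, random_state=rng)
    elif truth is None:
        truth = SyntheticTruth.empty()
    if r2 is not None:
        truth.r2 = float(r2)
    truth.seed = seed if isinstance(seed, (int, np.integer)) else None

    benign, tumor, annotations, crg_true, g = generate_metabolome(
        n_patients, n_metabolites, n_identified, truth,
        seed=rng, annotations=annotations,
        log_sigma=log_sigma, rare_bdl_fraction=rare_bdl_fraction, lod_quantile=lod_quantile,
    )
    covariates, volumes = generate_cohort(
        n_patients, seed=rng, crg_true=crg_true,
        observer_sigma=observer_sigma,
        patient_ids=list(benign.values.index),
    )
    data = CohortData(
        volumes=volumes, covariates=covariates,
        benign=benign, tumor=tumor, annotations=annotations,
    )
    return data, truth


def emulate_s1_layout(data: CohortData, truth: SyntheticTruth | None, out_dir) -> dict:
    """Write a synthetic cohort to disk in the wide supplementary convention."""
    paths = write_s1_layout(data, out_dir)
    if truth is not None:
        truth_path = Path(out_dir) / "truth.json"
        truth.to_json(truth_path)
        paths["truth"] = truth_path
    return paths
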