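"""Kidney volumetry responses: compensatory renal growth (CRG) and its long-term variant.

Compensatory renal growth is the hypertrophic response of benign kidney
parenchyma to nephron loss or tumor burden.  Pre-operatively it is
surrogated by the ratio of contralateral kidney parenchyma volume (VC) to
the benign parenchyma volume on the tumor side (VI), so that VC/VI ~ 1
means no compensatory growth and VC/VI > 1 means the healthy kidney has
outgrown the tumor-bearing one.  Long-term CRG (LT-CRG) is the fold change
of the remaining kidney's volume between a follow-up scan and baseline,
defined only for radical-nephrectomy patients.

Volumes arrive as a long-format table (one row per patient, observer and
timepoint).  Patients measured independently by two observers pass a
concordance check: if the ratio of the two observers' CRG values falls
outside the (0.75, 1.25) band the patient is excluded from all downstream
analyses; otherwise the two CRG values are averaged.  Patients measured by
a single observer bypass the check.  Note the band is asymmetric on the
ratio scale (1/1.25 = 0.8 != 0.75), so the test is applied to a fixed,
configurable observer order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_crg",
    "compute_lt_crg",
    "observer_concordance",
    "build_responses",
]

#: Exclusion band for the ratio of the two observers' CRG measurements.
QC_LOWER = 0.75
QC_UPPER = 1.25

VOLUME_COLUMNS = ["patient_id", "observer_id", "timepoint", "vc_cc", "vi_cc", "vtumor_cc"]


def _check_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


def compute_crg(vc, vi):
    """Pre-operative CRG surrogate: VC / VI.

    Parameters
    ----------
    vc : float or array-like
        Contralateral kidney parenchyma volume in cc.
    vi : float or array-like
        Ipsilateral (tumor-side) benign parenchyma volume in cc.
    """
    _check_positive("vc", vc)
    _check_positive("vi", vi)
    return np.asarray(vc, dtype=float) / np.asarray(vi, dtype=float) if np.ndim(vc) or np.ndim(vi) else float(vc) / float(vi)


def compute_lt_crg(vc_followup, vc_baseline):
    """Long-term CRG: fold change of the remaining kidney volume vs baseline."""
    _check_positive("vc_followup", vc_followup)
    _check_positive("vc_baseline", vc_baseline)
    if np.ndim(vc_followup) or np.ndim(vc_baseline):
        return np.asarray(vc_followup, dtype=float) / np.asarray(vc_baseline, dtype=float)
    return float(vc_followup) / float(vc_baseline)


def observer_concordance(
    crg_obs1: pd.Series,
    crg_obs2: pd.Series,
    lower: float = QC_LOWER,
    upper: float = QC_UPPER,
) -> pd.DataFrame:
    """Concordance QC for dual-observer CRG measurements.

    Both inputs are indexed by patient id and must cover the same patients.
    The ratio obs1/obs2 is tested strictly against the (lower, upper) band
    exactly as stated (the band is asymmetric on the ratio scale); kept
    patients receive the average of the two observers' CRG values.

    Returns a frame indexed by patient id with columns ``crg``, ``ratio``
    and ``qc_excluded``; excluded patients carry ``crg = NaN``.
    """
    idx1, idx2 = set(crg_obs1.index), set(crg_obs2.index)
    if idx1 != idx2:
        orphans = sorted(idx1.symmetric_difference(idx2))
        raise ValueError(f"observer patient sets differ; orphan patients: {orphans}")
    crg_obs2 = crg_obs2.reindex(crg_obs1.index)
    ratio = crg_obs1 / crg_obs2
    excluded = (ratio > upper) | (ratio < lower)
    crg = (crg_obs1 + crg_obs2) / 2.0
    crg[excluded] = np.nan
    out = pd.DataFrame({"crg": crg, "ratio": ratio, "qc_excluded": excluded})
    out.index.name = "patient_id"
    return out


def _pivot_observers(baseline: pd.DataFrame, observer_order: Sequence | None):
    """CRG per patient per observer at baseline -> wide frame patients x observers."""
    crg = baseline.assign(crg=baseline["vc_cc"].values / baseline["vi_cc"].values)
    wide = crg.pivot_table(index="patient_id", columns="observer_id", values="crg")
    if observer_order is None:
        observer_order = sorted(wide.columns)
    else:
        missing = [o for o in observer_order if o not in wide.columns]
        if missing:
            raise ValueError(f"observer_order names unknown observers: {missing}")
    return wide[list(observer_order)]


def build_responses(
    volumes: pd.DataFrame,
    lower: float = QC_LOWER,
    upper: float = QC_UPPER,
    observer_order: Sequence | None = None,
) -> pd.DataFrame:
    """Construct per-patient CRG responses from a long-format volume table.

    Parameters
    ----------
    volumes : DataFrame
        Columns ``patient_id, observer_id, timepoint, vc_cc, vi_cc,
        vtumor_cc`` with timepoint in {"baseline", "followup"}.
    observer_order : sequence, optional
        Fixed order in which the concordance ratio is formed for
        dual-observed patients (first/second).  Defaults to sorted ids.

    Returns
    -------
    DataFrame with columns ``patient_id, crg, kind, n_observers,
    qc_excluded``; one row per patient for kind "preop" and an additional
    row for kind "long_term" for patients with a follow-up scan.  QC
    excluded patients carry no usable CRG (NaN) for either kind.
    """
    missing = [c for c in VOLUME_COLUMNS[:5] if c not in volumes.columns]
    if missing:
        raise ValueError(f"volume table lacks columns {missing}")
    baseline = volumes[volumes["timepoint"] == "baseline"]
    if baseline.empty:
        raise ValueError("no baseline volume records")
    _check_positive("vc_cc", baseline["vc_cc"].values)
    _check_positive("vi_cc", baseline["vi_cc"].values)

    wide = _pivot_observers(baseline, observer_order)
    n_obs = wide.notna().sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("patients with no baseline CRG measurement")

    dual = wide[n_obs >= 2]
    rows = []
    if not dual.empty:
        qc = observer_concordance(dual.iloc[:, 0], dual.iloc[:, 1], lower, upper)
        for pid, row in qc.iterrows():
            rows.append((pid, row["crg"], "preop", 2, bool(row["qc_excluded"])))
    single = wide[n_obs == 1]
    for pid, row in single.iterrows():
        rows.append((pid, row.dropna().iloc[0], "preop", 1, False))

    preop = pd.DataFrame(rows, columns=["patient_id", "crg", "kind", "n_observers", "qc_excluded"])
    excluded = set(preop.loc[preop["qc_excluded"], "patient_id"])

    # Long-term CRG: follow-up VC over the observer-mean baseline VC.
    followup = volumes[volumes["timepoint"] == "followup"]
    lt_rows = []
    if not followup.empty:
        _check_positive("vc_cc (followup)", followup["vc_cc"].values)
        base_vc = baseline.groupby("patient_id")["vc_cc"].mean()
        fu_vc = followup.groupby("patient_id")["vc_cc"].mean()
        for pid, vc_fu in fu_vc.items():
            if pid not in base_vc.index:
                raise ValueError(f"follow-up record without baseline for patient {pid!r}")
            qc_ex = pid in excluded
            lt = np.nan if qc_ex else compute_lt_crg(vc_fu, base_vc.loc[pid])
            n = int(followup[followup["patient_id"] == pid]["observer_id"].nunique())
            lt_rows.append((pid, lt, "long_term", n, qc_ex))
    if not lt_rows:
        return preop
    lt = pd.DataFrame(lt_rows, columns=preop.columns)
    return pd.concat([preop, lt], ignore_index=True)
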