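"""Directional metabolite-set (sub-pathway) enrichment over VIP-ranked lists.

Identified metabolites are ranked by a signed importance statistic
``VIP * sign(effect)`` in descending order, so metabolites positively
associated with the response sit at the top and negative ones at the
bottom (the metabolite analogue of up/down-regulated genes).  For each
annotated sub-pathway a weighted Kolmogorov-Smirnov running sum is
computed down the list: member positions add ``|s|^w`` (normalized over
the member total), non-members subtract ``1/(N - n)``.  The maximum of
the running sum measures enrichment of positive associations, the
minimum enrichment of negative associations.

Significance comes from a metabolite-label permutation null (random
member sets of the same size on the fixed ranked list); sample-level
permutation would require refitting the multivariable model per draw and
conflate model and set nulls.  Empirical p-values use the plus-one
convention and are Benjamini-Hochberg adjusted across all
(set, direction) pairs of one analysis.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.utils import check_random_state

from .association import adjust_fdr

__all__ = [
    "rank_variables",
    "enrichment_score",
    "running_sum_extrema",
    "enrichment_significance",
]

MIN_SET_SIZE = 3


def rank_variables(association: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Signed VIP ranking of identified metabolites.

    Parameters
    ----------
    association : frame with at least ``compound_id``, ``vip``, ``effect``
        (metabolite rows; other rows are ignored).
    annotations : frame with ``compound_id``, ``identified``, ``sub_pathway``.

    Returns a frame sorted by ``stat = vip * sign(effect)`` descending,
    ties broken by compound id (stable, deterministic across runs).
    """
    ann = annotations.set_index("compound_id")
    metab = association[association["compound_id"].notna()].copy()
    metab["compound_id"] = metab["compound_id"].astype(str)
    identified = ann.index[ann["identified"].astype(bool)].astype(str)
    metab = metab[metab["compound_id"].isin(set(identified))]
    if metab.empty:
        raise ValueError("no identified metabolites overlap the association table")
    sign = np.where(metab["effect"].to_numpy(dtype=float) < 0, -1.0, 1.0)
    metab["stat"] = metab["vip"].to_numpy(dtype=float) * sign
    metab["sub_pathway"] = ann.loc[metab["compound_id"], "sub_pathway"].to_numpy()
    metab = metab.sort_values(["stat", "compound_id"], ascending=[False, True], kind="mergesort")
    return metab[["compound_id", "sub_pathway", "vip", "effect", "stat"]].reset_index(drop=True)


def running_sum_extrema(stats: np.ndarray, member: np.ndarray, weight_exponent: float = 1.0):
    """(max, min) of the weighted KS running sum for one member set."""
    stats = np.asarray(stats, dtype=float)
    member = np.asarray(member, dtype=bool)
    N = stats.shape[0]
    n = int(member.sum())
    if n == 0 or n == N:
        raise ValueError("member set must be a proper non-empty subset of the universe")
    w = np.abs(stats) ** weight_exponent
    hit_total = w[member].sum()
    if hit_total == 0:
        raise ValueError("member weights sum to zero; cannot normalize")
    step = np.where(member, w / hit_total, -1.0 / (N - n))
    running = np.cumsum(step)
    return float(running.max()), float(running.min())


def enrichment_score(stats, member, weight_exponent: float = 1.0) -> float:
    """Signed enrichment score: the running-sum extremum of larger magnitude.

    ``stats`` must be sorted descending (the ranked list); ``member``
    marks the set members along it.  The score lies in [-1, 1]: +1 when
    every member sits at the very top, -1 at the very bottom.
    """
    hi, lo = running_sum_extrema(stats, member, weight_exponent)
    return hi if hi >= -lo else lo


def _null_extrema(
    w: np.ndarray, set_size: int, n_perm: int, rng, batch: int = 512
):
    """Permutation null of (max, min) running-sum extrema for one set size."""
    N = w.shape[0]
    miss = -1.0 / (N - set_size)
    maxs = np.empty(n_perm)
    mins = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # b random member subsets of the fixed ranked list
        keys = rng.random_sample((b, N))
        pos = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        step = np.full((b, N), miss)
        wm = w[pos]
        np.put_along_axis(step, pos, wm / wm.sum(axis=1, keepdims=True), axis=1)
        running = np.cumsum(step, axis=1)
        maxs[done:done + b] = running.max(axis=1)
        mins[done:done + b] = running.min(axis=1)
        done += b
    return maxs, mins


def enrichment_significance(
    ranked: pd.DataFrame,
    sets: Mapping[str, Sequence] | None = None,
    n_perm: int = 10000,
    random_state=None,
    min_set_size: int = MIN_SET_SIZE,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Directional enrichment of every sub-pathway with a permutation null.

    Parameters
    ----------
    ranked : output of :func:`rank_variables` (sorted descending by stat).
    sets : mapping sub-pathway -> compound ids; by default the
        ``sub_pathway`` column of ``ranked`` defines the sets.
    n_perm : permutations of set membership for the null.

    Returns one row per (sub_pathway, direction) with the direction's
    running-sum extremum as score, its plus-one empirical p-value and the
    BH-adjusted p over all pairs.
    """
    if n_perm < 1000:
        warnings.warn("n_perm < 1000 gives coarse enrichment p-values")
    rng = check_random_state(random_state)
    stats = ranked["stat"].to_numpy(dtype=float)
    ids = ranked["compound_id"].astype(str).to_numpy()
    universe = set(ids)
    if sets is None:
        sp = ranked["sub_pathway"]
        sets = {
            name: set(ranked.loc[sp == name, "compound_id"].astype(str))
            for name in sp.dropna().unique()
        }
    w = np.abs(stats) ** weight_exponent

    rows = []
    null_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for name in sorted(sets):
        members = {str(m) for m in sets[name]} & universe
        n = len(members)
        if n < min_set_size or n >= len(ids):
            continue
        member_mask = np.isin(ids, list(members))
        hi, lo = running_sum_extrema(stats, member_mask, weight_exponent)
        if n not in null_cache:
            null_cache[n] = _null_extrema(w, n, n_perm, rng)
        null_max, null_min = null_cache[n]
        # tie tolerance: many membership arrangements share an extremum
        # up to float round-off; count them as at least as extreme
        p_pos = (1.0 + np.sum(null_max >= hi - 1e-12)) / (1.0 + n_perm)
        p_neg = (1.0 + np.sum(null_min <= lo + 1e-12)) / (1.0 + n_perm)
        rows.append({"sub_pathway": name, "direction": "positive", "n_members": n, "es": hi, "p": p_pos})
        rows.append({"sub_pathway": name, "direction": "negative", "n_members": n, "es": lo, "p": p_neg})
    if not rows:
        return pd.DataFrame(columns=["sub_pathway", "direction", "n_members", "es", "p", "fdr_p"])
    out = pd.DataFrame(rows)
    out["fdr_p"] = adjust_fdr(out["p"].to_numpy())
    return out
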