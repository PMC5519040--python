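"""Orthogonal partial least squares (OPLS) regression for one continuous response.

OPLS splits predictor variation into a single component predictive of the
response and a small number of components orthogonal to it (orthogonal
signal correction).  Fitting follows the NIPALS recursion: for each
orthogonal component, compute the PLS weight ``w ~ X'y`` (unit norm),
scores ``t = Xw``, loadings ``p = X't/(t't)``, split off the part of ``p``
orthogonal to ``w`` as the orthogonal weight, and deflate ``X`` by the
resulting orthogonal score/loading pair.  After removing ``n_ortho``
orthogonal components a final single predictive PLS component is fitted
to the filtered matrix.

Variable importance is summarized by the VIP score (variable influence in
projection); for the single predictive component it reduces to
``sqrt(K) * |w_j|`` with ``K`` the number of variables, so the mean
squared VIP is exactly 1 and VIP > 1 flags above-average contributors.
The signed per-variable "effect" reported alongside is the predictive
loading scaled by the response loading, i.e. the OPLS regression
coefficient direction for each variable.

Model validation follows the study design: Q2 from k-fold
cross-validation (default 8 folds), and a response-permutation test in
which the model is refitted to random permutations of the response and
the real cross-validated RMSE is ranked within the permuted RMSE
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "OPLSRegressor",
    "PermutationReport",
    "fit_opls",
    "vip_scores",
    "cross_validate",
    "permutation_test",
]

_EPS = np.finfo(float).eps


def _pls_component(X: np.ndarray, y: np.ndarray):
    """One NIPALS PLS1 component on centered arrays: weight, score, loadings."""
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e3 * _EPS * max(1.0, np.linalg.norm(y)):
        raise ValueError("degenerate fit: X'y is numerically zero")
    w = w / nw
    t = X @ w
    tt = t @ t
    p = X.T @ t / tt
    c = (t @ y) / tt
    return w, t, p, c


def _fit_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int) -> dict:
    """Fit OPLS on centered arrays; returns component arrays and the filtered X."""
    X = Xc.copy() if n_ortho > 0 else Xc  # deflation mutates; skip copy otherwise
    W_o, T_o, P_o, c_o = [], [], [], []
    for _ in range(n_ortho):
        w, t, p, c = _pls_component(X, yc)
        w_orth = p - (w @ p) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-10 * max(1.0, np.linalg.norm(p)):
            break  # no orthogonal variation left
        w_orth = w_orth / norm
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)
        W_o.append(w_orth)
        T_o.append(t_orth)
        P_o.append(p_orth)
        c_o.append((t_orth @ yc) / (t_orth @ t_orth))
    w, t, p, c = _pls_component(X, yc)
    return {
        "w": w, "t": t, "p": p, "c": c,
        "W_ortho": np.array(W_o).T if W_o else np.empty((Xc.shape[1], 0)),
        "T_ortho": np.array(T_o).T if T_o else np.empty((Xc.shape[0], 0)),
        "P_ortho": np.array(P_o).T if P_o else np.empty((Xc.shape[1], 0)),
        "c_ortho": np.asarray(c_o),
        "X_filtered": X,
    }


def _filter_new(core: dict, Xc: np.ndarray) -> np.ndarray:
    """Apply the fitted orthogonal signal correction to new centered data."""
    X = Xc.copy()
    W_o, P_o = core["W_ortho"], core["P_ortho"]
    for k in range(W_o.shape[1]):
        t_o = X @ W_o[:, k]
        X = X - np.outer(t_o, P_o[:, k])
    return X


def _predict_core(core: dict, Xc: np.ndarray) -> np.ndarray:
    Xf = _filter_new(core, Xc)
    return (Xf @ core["w"]) * core["c"]


def _make_folds(n: int, n_folds: int, rng: np.random.RandomState) -> list[np.ndarray]:
    if n_folds > n:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    perm = rng.permutation(n)
    folds = [perm[k::n_folds] for k in range(n_folds)]
    if min(len(f) for f in folds) < 2:
        raise ValueError("cross-validation fold with fewer than 2 samples")
    return folds


def _prepare_folds(X: np.ndarray, folds: list[np.ndarray]):
    """Per-fold train/test matrices centered on the training split (y-independent)."""
    prepared = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx, assume_unique=False)
        Xtr = X[train_idx]
        xm = Xtr.mean(axis=0)
        prepared.append((train_idx, test_idx, Xtr - xm, X[test_idx] - xm))
    return prepared


def _cv_predictions(prepared, y: np.ndarray, n_ortho: int) -> np.ndarray:
    """Held-out predictions for every sample under the given fold split."""
    yhat = np.empty_like(y, dtype=float)
    for train_idx, test_idx, Xtr_c, Xte_c in prepared:
        ym = y[train_idx].mean()
        core = _fit_core(Xtr_c, y[train_idx] - ym, n_ortho)
        yhat[test_idx] = _predict_core(core, Xte_c) + ym
    return yhat


def _cv_stats(prepared, y: np.ndarray, n_ortho: int):
    yhat = _cv_predictions(prepared, y, n_ortho)
    press = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss
    fold_rmse = np.array([
        np.sqrt(np.mean((y[test] - yhat[test]) ** 2)) for _, test, _, _ in prepared
    ])
    return q2, fold_rmse


@dataclass
class PermutationReport:
    """Cross-validation vs response-permutation model validation summary.

    ``p_value`` is the empirical plus-one rank of the real mean
    cross-validated RMSE within the permuted-response RMSE sample (small
    when the real model predicts better than chance).  ``p_ranksum`` is a
    two-sided Wilcoxon rank-sum test between the per-fold real RMSEs and
    the permuted RMSEs, reported for reference.
    """

    n_perm: int
    n_folds: int
    rmse_cv_folds: np.ndarray
    rmse_perm: np.ndarray
    p_value: float
    p_ranksum: float
    q2: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "n_folds": self.n_folds,
            "rmse_cv_mean": float(np.mean(self.rmse_cv_folds)),
            "rmse_perm_mean": float(np.mean(self.rmse_perm)),
            "p_value": self.p_value,
            "p_ranksum": self.p_ranksum,
            "q2": self.q2,
            "seed": self.seed,
        }


class OPLSRegressor(RegressorMixin, BaseEstimator):
    """OPLS regression with one predictive and ``n_ortho`` orthogonal components.

    Parameters
    ----------
    n_ortho : int or "auto"
        Number of orthogonal components.  With "auto", components are
        added while cross-validated Q2 improves by more than
        ``delta_q2`` (up to ``max_ortho``).
    max_ortho : int
        Cap for automatic selection.
    delta_q2 : float
        Minimum Q2 improvement to accept another orthogonal component.
    n_folds : int
        Folds for the internal cross-validation (selection and ``q2_``).
    vip_mode : {"predictive", "total"}
        "predictive" uses the single predictive component (classic
        single-component VIP, ``sqrt(K)|w_j|``); "total" includes the
        orthogonal components weighted by their (small) share of
        explained response variance.
    random_state : int, RandomState or None
        Seeds the fold shuffle.

    Attributes
    ----------
    w_, t_, p_, c_ : predictive weights, scores, loadings, response loading
    W_ortho_, T_ortho_, P_ortho_ : orthogonal component matrices
    n_ortho_ : number of orthogonal components actually extracted
    vip_ : per-variable VIP scores (mean square 1)
    effect_ : signed per-variable association, ``p_ * c_``
    coef_ : equivalent linear regression coefficients in input space
    r2y_ : training R2;  q2_ : cross-validated R2;  rmse_train_ : training RMSE
    rmse_cv_folds_ : per-fold held-out RMSEs at the selected n_ortho
    """

    def __init__(
        self,
        n_ortho: int | str = "auto",
        max_ortho: int = 9,
        delta_q2: float = 0.01,
        n_folds: int = 8,
        vip_mode: str = "predictive",
        random_state=None,
    ):
        self.n_ortho = n_ortho
        self.max_ortho = max_ortho
        self.delta_q2 = delta_q2
        self.n_folds = n_folds
        self.vip_mode = vip_mode
        self.random_state = random_state

    def _validate(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < 3:
            raise ValueError("OPLS requires at least 3 samples")
        if np.ptp(y) == 0:
            raise ValueError("response is constant")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("design contains zero-variance columns; drop them first")
        return X, y

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = self._validate(X, y)
        rng = check_random_state(self.random_state)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(np.mean(y))
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        try:
            folds = _make_folds(X.shape[0], min(self.n_folds, max(2, X.shape[0] // 2)), rng)
            prepared = _prepare_folds(X, folds)
        except ValueError:
            if self.n_ortho == "auto":
                warnings.warn("too few samples for cross-validation; using n_ortho=0")
            folds, prepared = [], None

        if prepared is None:
            n_ortho = 0 if self.n_ortho == "auto" else int(self.n_ortho)
            q2, fold_rmse = np.nan, np.empty(0)
        elif self.n_ortho == "auto":
            n_ortho, q2 = self._select_n_ortho(prepared, y)
            _, fold_rmse = _cv_stats(prepared, y, n_ortho)
        else:
            n_ortho = int(self.n_ortho)
            if n_ortho < 0:
                raise ValueError("n_ortho must be >= 0")
            q2, fold_rmse = _cv_stats(prepared, y, n_ortho)

        core = _fit_core(Xc, yc, n_ortho)
        self._core_ = core
        self.w_, self.t_, self.p_, self.c_ = core["w"], core["t"], core["p"], core["c"]
        self.W_ortho_, self.T_ortho_, self.P_ortho_ = core["W_ortho"], core["T_ortho"], core["P_ortho"]
        self.n_ortho_ = self.W_ortho_.shape[1]
        self.q2_ = q2
        self.rmse_cv_folds_ = fold_rmse
        self.cv_folds_ = folds

        resid = yc - self.t_ * self.c_
        tss = float(yc @ yc)
        self.r2y_ = 1.0 - float(resid @ resid) / tss
        self.rmse_train_ = float(np.sqrt(np.mean(resid**2)))
        self.vip_ = self._vip(core, yc)
        self.effect_ = self.p_ * self.c_

        # Equivalent coefficients: propagate the predictive direction back
        # through the orthogonal filtering (each deflation is x -> x(I - w_o p_o')).
        v = self.w_ * self.c_
        for k in range(self.n_ortho_ - 1, -1, -1):
            v = v - self.W_ortho_[:, k] * (self.P_ortho_[:, k] @ v)
        self.coef_ = v
        self.n_features_in_ = X.shape[1]
        return self

    def _select_n_ortho(self, prepared, y):
        best_k, best_q2 = 0, -np.inf
        q2_path = []
        for k in range(0, self.max_ortho + 1):
            try:
                q2, _ = _cv_stats(prepared, y, k)
            except ValueError:  # ran out of orthogonal variation
                break
            q2_path.append(q2)
            if k == 0 or q2 > best_q2 + self.delta_q2:
                best_k, best_q2 = k, q2
            else:
                break
        self.q2_path_ = q2_path
        return best_k, best_q2

    def _vip(self, core, yc) -> np.ndarray:
        K = core["w"].shape[0]
        if self.vip_mode == "predictive":
            return np.sqrt(K) * np.abs(core["w"])
        if self.vip_mode != "total":
            raise ValueError(f"unknown vip_mode {self.vip_mode!r}")
        # Components: orthogonal then predictive, each weighted by its
        # share of explained response variance.
        weights = [core["W_ortho"][:, k] for k in range(core["W_ortho"].shape[1])] + [core["w"]]
        scores = [core["T_ortho"][:, k] for k in range(core["T_ortho"].shape[1])] + [core["t"]]
        cs = list(core["c_ortho"]) + [core["c"]]
        ssy = np.array([c**2 * (t @ t) for c, t in zip(cs, scores)])
        W2 = np.stack([w**2 for w in weights], axis=1)
        return np.sqrt(K * (W2 @ ssy) / ssy.sum())

    def predict(self, X):
        check_is_fitted(self, "w_")
        X = check_array(X)
        return _predict_core(self._core_, X - self.x_mean_) + self.y_mean_


def fit_opls(X, y, **kwargs) -> OPLSRegressor:
    """Fit an :class:`OPLSRegressor`; keyword arguments are estimator params."""
    return OPLSRegressor(**kwargs).fit(X, y)


def vip_scores(model: OPLSRegressor) -> np.ndarray:
    """Per-variable VIP scores of a fitted model (mean square exactly 1)."""
    check_is_fitted(model, "vip_")
    return model.vip_


def cross_validate(X, y, n_ortho: int = 0, n_folds: int = 8, random_state=None):
    """Cross-validated Q2 and per-fold held-out RMSEs at a fixed ``n_ortho``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = check_random_state(random_state)
    folds = _make_folds(X.shape[0], n_folds, rng)
    prepared = _prepare_folds(X, folds)
    return _cv_stats(prepared, y, n_ortho)


def permutation_test(
    X,
    y,
    n_perm: int = 1000,
    n_folds: int = 8,
    n_ortho: int | str = "auto",
    random_state=None,
) -> PermutationReport:
    """Response-permutation validation of the OPLS fit.

    The real response's mean cross-validated RMSE is ranked within the
    RMSEs of ``n_perm`` seeded permutations of the response, each
    evaluated with the identical fold split and number of orthogonal
    components (selected once on the unpermuted fit when ``n_ortho`` is
    "auto").  The plus-one empirical rank is the primary p-value.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation p-value")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = check_random_state(random_state)

    if n_ortho == "auto":
        model = OPLSRegressor(n_ortho="auto", n_folds=n_folds, random_state=rng).fit(X, y)
        n_ortho = model.n_ortho_

    folds = _make_folds(X.shape[0], n_folds, rng)
    prepared = _prepare_folds(X, folds)
    q2, fold_rmse = _cv_stats(prepared, y, int(n_ortho))
    rmse_real = float(np.mean(fold_rmse))

    rmse_perm = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        _, fr = _cv_stats(prepared, yp, int(n_ortho))
        rmse_perm[b] = np.mean(fr)

    p_emp = (1.0 + np.sum(rmse_perm <= rmse_real)) / (1.0 + n_perm)
    p_rs = float(stats.ranksums(fold_rmse, rmse_perm).pvalue)
    seed = random_state if isinstance(random_state, (int, np.integer)) else None
    return PermutationReport(
        n_perm=n_perm,
        n_folds=n_folds,
        rmse_cv_folds=fold_rmse,
        rmse_perm=rmse_perm,
        p_value=float(p_emp),
        p_ranksum=p_rs,
        q2=q2,
        seed=seed,
    )
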