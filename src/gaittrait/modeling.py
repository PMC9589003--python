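"""Trait regression: standardisation, greedy forward selection, seven
regressors, and 10-fold cross-validated evaluation on pooled out-of-fold
predictions.

The selection objective is the pooled cross-validated Pearson correlation
between out-of-fold predictions and the trait score (the headline metric of
the evaluation protocol); a mean-squared-error objective is available via
``scoring="mse"``. Selection can run nested inside each evaluation fold
(default, leakage-free) or once on all data before cross-validation
(``paper_mode=True``) for comparability with protocols that do not specify
the placement.

For linear regression the per-candidate cross-validation in the selection
scan is computed in closed form: with the currently selected design B fixed,
the OLS fit of (B, c) for every candidate column c follows from
residualising y and c on B (Frisch-Waugh), which vectorises over all
candidates and is numerically identical to refitting each candidate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular as scipy_solve_triangular
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import GaitTraitError, GaitWarning

ALGORITHMS: tuple[str, ...] = (
    "gp", "lr", "rfr", "svr_linear", "svr_poly", "svr_rbf", "svr_sigmoid")

#: Frozen hyperparameter defaults (none are reported by the protocol).
SVR_PARAMS = dict(C=1.0, epsilon=0.1, gamma="scale", degree=3)
RFR_TREES = 100
GP_NOISE_FLOOR = 1e-6


def make_estimator(algorithm: str, seed: int = 0):
    """Instantiate one of the seven supported regressors."""
    if algorithm == "lr":
        return LinearRegression()
    if algorithm == "gp":
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3)) \
            + WhiteKernel(1e-2, (GP_NOISE_FLOOR, 1e3))
        return GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                        random_state=seed)
    if algorithm == "rfr":
        return RandomForestRegressor(n_estimators=RFR_TREES, random_state=seed)
    if algorithm.startswith("svr_"):
        kernel = algorithm.split("_", 1)[1]
        if kernel in ("linear", "poly", "rbf", "sigmoid"):
            return SVR(kernel=kernel, **SVR_PARAMS)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

def standardize(features: pd.DataFrame,
                params: Optional[dict] = None) -> tuple[pd.DataFrame, dict]:
    """Z-score features; fit (mean, sd) unless ``params`` is supplied.

    Zero-variance columns are dropped at fit time with a warning. In
    transform-only mode unknown feature names are an error and the stored
    moments are never refitted.
    """
    if params is None:
        sd = features.std(ddof=0)
        keep = sd[sd > 0].index
        dropped = [c for c in features.columns if c not in set(keep)]
        if dropped:
            warnings.warn(f"dropping {len(dropped)} constant feature(s): "
                          f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                          GaitWarning, stacklevel=2)
        params = {"mean": features[keep].mean(), "sd": sd[keep],
                  "columns": list(keep)}
    cols = params["columns"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise GaitTraitError(f"features missing at transform time: {missing[:10]}")
    z = (features[cols] - params["mean"]) / params["sd"]
    return z, params


def _pearson_columns(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of P with y; non-finite/constant -> -inf."""
    Pc = P - P.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Pc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Pc.T @ yc) / denom
    r[~np.isfinite(r)] = -np.inf
    return r


def _score_pooled(P: np.ndarray, y: np.ndarray, scoring: str) -> np.ndarray:
    if scoring == "r":
        return _pearson_columns(P, y)
    if scoring == "mse":
        return -((P - y[:, None]) ** 2).mean(axis=0)
    raise ValueError("scoring must be 'r' or 'mse'")


def _ols_multi(B: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Least-squares solve via thin QR (fast for many right-hand sides)."""
    Q, R = np.linalg.qr(B)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):  # rank-deficient base
        sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
        return sol
    return scipy_solve_triangular(R, Q.T @ rhs)


def _candidate_scan_lr(Xs: np.ndarray, y: np.ndarray, base: list[int],
                       cand: np.ndarray, folds: list, scoring: str) -> np.ndarray:
    """Pooled-CV score of (base + each candidate) under OLS, vectorised."""
    n = len(y)
    preds = np.empty((n, len(cand)))
    for tr, te in folds:
        B_tr = np.column_stack([np.ones(len(tr))] + [Xs[tr, j] for j in base])
        B_te = np.column_stack([np.ones(len(te))] + [Xs[te, j] for j in base])
        rhs = np.column_stack([y[tr], Xs[np.ix_(tr, cand)]])
        sol = _ols_multi(B_tr, rhs)
        beta, delta = sol[:, 0], sol[:, 1:]
        resid_y = y[tr] - B_tr @ beta
        base_pred = B_te @ beta
        R = Xs[np.ix_(tr, cand)] - B_tr @ delta
        s2 = (R ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            bc = np.where(s2 > 1e-10, (R.T @ resid_y) / np.where(s2 > 0, s2, 1.0), 0.0)
        preds[te] = base_pred[:, None] + (Xs[np.ix_(te, cand)] - B_te @ delta) * bc[None, :]
    return _score_pooled(preds, y, scoring)


def _candidate_scan_generic(Xs: np.ndarray, y: np.ndarray, base: list[int],
                            cand: np.ndarray, folds: list, scoring: str,
                            est_factory: Callable) -> np.ndarray:
    scores = np.empty(len(cand))
    for k, j in enumerate(cand):
        cols = base + [int(j)]
        preds = np.empty(len(y))
        for tr, te in folds:
            est = est_factory()
            est.fit(Xs[np.ix_(tr, cols)], y[tr])
            preds[te] = est.predict(Xs[np.ix_(te, cols)])
        scores[k] = _score_pooled(preds[:, None], y, scoring)[0]
    return scores


def sequential_forward_selection(X, y, algorithm: str = "lr", k_folds: int = 10,
                                 max_k: int = 10, tol: float = 1e-2,
                                 seed: int = 0, scoring: str = "r",
                                 feature_names: Optional[Sequence[str]] = None,
                                 ) -> tuple[list[str], list[tuple[str, float]]]:
    """Greedy forward selection maximising the pooled k-fold CV score.

    Stops when the best improvement falls below ``tol`` or ``max_k`` features
    are selected; exact ties break toward the smaller canonical column index.
    Deterministic given ``seed`` (which fixes the fold shuffle).
    Returns (selected feature names, per-step (name, score) trace).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xs = X.to_numpy(dtype=float)
    else:
        Xs = np.asarray(X, dtype=float)
        feature_names = list(feature_names) if feature_names is not None \
            else [f"x{i}" for i in range(Xs.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise GaitTraitError("target has zero variance")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    n, p = Xs.shape
    k_folds = min(k_folds, n)
    folds = list(KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(Xs))
    est_factory = None if algorithm == "lr" else (lambda: make_estimator(algorithm, seed))

    selected: list[int] = []
    trace: list[tuple[str, float]] = []
    current = -np.inf
    while len(selected) < min(max_k, p):
        cand = np.array([j for j in range(p) if j not in selected])
        if algorithm == "lr":
            scores = _candidate_scan_lr(Xs, y, selected, cand, folds, scoring)
        else:
            scores = _candidate_scan_generic(Xs, y, selected, cand, folds,
                                             scoring, est_factory)
        best = int(np.argmax(scores))  # first max -> smallest column index on ties
        if scores[best] - current < tol:
            break
        selected.append(int(cand[best]))
        current = float(scores[best])
        trace.append((feature_names[cand[best]], current))
    if not selected:
        raise GaitTraitError("forward selection accepted no feature")
    return [feature_names[j] for j in selected], trace


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class TraitRegressor(BaseEstimator, RegressorMixin):
    """Standardise -> forward-select -> fit one of the seven regressors.

    Parameters
    ----------
    algorithm : {"gp", "lr", "rfr", "svr_linear", "svr_poly", "svr_rbf", "svr_sigmoid"}
    max_features : int
        Upper bound on selected features (forward selection budget).
    tol : float
        Minimum pooled-CV score improvement to accept another feature.
    cv : int
        Folds of the selection objective's internal cross-validation.
    scoring : {"r", "mse"}
    select : bool
        When False, skip selection and fit on all (non-constant) features.
    random_state : int

    Fitted attributes: ``selected_features_``, ``selection_trace_``,
    ``scaler_params_``, ``estimator_``, ``feature_names_in_``.
    """

    def __init__(self, algorithm: str = "lr", max_features: int = 10,
                 tol: float = 1e-2, cv: int = 10, scoring: str = "r",
                 select: bool = True, random_state: int = 0):
        self.algorithm = algorithm
        self.max_features = max_features
        self.tol = tol
        self.cv = cv
        self.scoring = scoring
        self.select = select
        self.random_state = random_state

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y) -> "TraitRegressor":
        Xf = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(Xf) != len(y):
            raise ValueError("X and y length mismatch")
        if len(Xf) < 2:
            raise GaitTraitError("need at least 2 samples")
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        Z, params = standardize(Xf)
        self.scaler_params_ = params
        if self.select:
            sel, trace = sequential_forward_selection(
                Z, y, algorithm=self.algorithm, k_folds=self.cv,
                max_k=self.max_features, tol=self.tol,
                seed=self.random_state, scoring=self.scoring)
        else:
            sel, trace = list(Z.columns), []
        self.selected_features_ = sel
        self.selection_trace_ = trace
        self.estimator_ = make_estimator(self.algorithm, self.random_state)
        self.estimator_.fit(Z[sel].to_numpy(), y)
        return self

    def predict(self, X) -> np.ndarray:
        Xf = self._as_frame(X)
        missing = [c for c in self.selected_features_ if c not in Xf.columns]
        if missing:
            raise GaitTraitError(f"missing selected features: {missing[:10]}")
        sub = {"mean": self.scaler_params_["mean"][self.selected_features_],
               "sd": self.scaler_params_["sd"][self.selected_features_],
               "columns": self.selected_features_}
        Z, _ = standardize(Xf, sub)
        return self.estimator_.predict(Z.to_numpy())

    @property
    def coef_(self) -> pd.Series:
        """Standardised coefficients (linear algorithm only), indexed by feature."""
        if self.algorithm != "lr":
            raise GaitTraitError("coefficients are defined only for algorithm='lr'")
        return pd.Series(self.estimator_.coef_, index=self.selected_features_)


def save_model(model: TraitRegressor, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TraitRegressor:
    return joblib.load(path)


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Pooled out-of-fold evaluation of one algorithm on one cohort."""

    algorithm: str
    r_all: float
    p_all: float
    mse: float
    r_by_group: dict[str, float]
    pooled_predictions: pd.Series
    y_true: pd.Series
    fold_assignment: pd.Series
    selection_traces: list = field(default_factory=list)
    paper_mode: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm, "r_all": self.r_all, "p_all": self.p_all,
            "mse": self.mse, "r_by_group": self.r_by_group,
            "paper_mode": self.paper_mode, "seed": self.seed,
            "pooled_predictions": {str(k): float(v)
                                   for k, v in self.pooled_predictions.items()},
        }


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def cross_validate(X, y, algorithm: str = "lr", k: int = 10, seed: int = 0,
                   subgroup_labels: Optional[Sequence] = None,
                   paper_mode: bool = False, max_k: int = 10, tol: float = 1e-2,
                   scoring: str = "r") -> EvalReport:
    """k-fold CV with pooled out-of-fold scoring.

    Per fold, standardisation is fitted on the training part only. Feature
    selection runs nested inside each fold by default; with
    ``paper_mode=True`` it runs once on all data before the folds (the
    leakier but simpler protocol).
    """
    Xf = TraitRegressor._as_frame(X)
    y_arr = np.asarray(y, dtype=float)
    n = len(y_arr)
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    if y_arr.std() == 0:
        raise GaitTraitError("target has zero variance")
    index = Xf.index

    fixed_features = None
    traces = []
    if paper_mode:
        Z_all, _ = standardize(Xf)
        fixed_features, trace = sequential_forward_selection(
            Z_all, y_arr, algorithm=algorithm, k_folds=k, max_k=max_k, tol=tol,
            seed=seed, scoring=scoring)
        traces.append(trace)

    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(Xf))
    preds = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(folds):
        fold_of[te] = f
        Xtr, Xte = Xf.iloc[tr], Xf.iloc[te]
        if paper_mode:
            model = TraitRegressor(algorithm=algorithm, select=False,
                                   random_state=seed)
            model.fit(Xtr[fixed_features], y_arr[tr])
        else:
            model = TraitRegressor(algorithm=algorithm, max_features=max_k,
                                   tol=tol, cv=k, scoring=scoring,
                                   random_state=seed + f)
            model.fit(Xtr, y_arr[tr])
            traces.append(model.selection_trace_)
        preds[te] = model.predict(Xte)

    r_all, p_all = _safe_pearson(preds, y_arr)
    mse = float(((preds - y_arr) ** 2).mean())
    r_by_group: dict[str, float] = {}
    if subgroup_labels is not None:
        labels = np.asarray(subgroup_labels)
        for g in pd.unique(labels):
            m = labels == g
            if m.sum() < 3:
                warnings.warn(f"subgroup {g!r} has <3 members; r undefined",
                              GaitWarning, stacklevel=2)
                r_by_group[str(g)] = float("nan")
            else:
                r_by_group[str(g)] = _safe_pearson(preds[m], y_arr[m])[0]
    return EvalReport(algorithm=algorithm, r_all=r_all, p_all=p_all, mse=mse,
                      r_by_group=r_by_group,
                      pooled_predictions=pd.Series(preds, index=index),
                      y_true=pd.Series(y_arr, index=index),
                      fold_assignment=pd.Series(fold_of, index=index),
                      selection_traces=traces, paper_mode=paper_mode, seed=seed)
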