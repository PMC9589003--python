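import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.model_selection import KFold

from gaittrait import (
    ALGORITHMS,
    TraitRegressor,
    cross_validate,
    load_model,
    make_estimator,
    save_model,
    sequential_forward_selection,
    standardize,
)
from gaittrait.errors import GaitTraitError, GaitWarning
from gaittrait.modeling import _candidate_scan_generic, _candidate_scan_lr


def _toy(n=60, p=10, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    driver = f"f{min(7, p - 1)}"
    y = 2.0 * X[driver].to_numpy() + noise * rng.normal(size=n)
    return X, y


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

def test_standardize_moments_and_inversion():
    X, _ = _toy(40)
    Z, params = standardize(X)
    np.testing.assert_allclose(Z.mean(), 0, atol=1e-10)
    np.testing.assert_allclose(Z.std(ddof=0), 1, atol=1e-10)
    # params fitted on A applied to B then inverted recover B exactly
    B, _ = _toy(20, seed=5)
    Zb, _ = standardize(B, params)
    back = Zb * params["sd"] + params["mean"]
    np.testing.assert_allclose(back.to_numpy(), B.to_numpy(), atol=1e-10)


def test_constant_column_dropped_with_warning():
    X, _ = _toy(30)
    X["flat"] = 3.14
    with pytest.warns(GaitWarning, match="constant"):
        Z, params = standardize(X)
    assert "flat" not in params["columns"]


def test_transform_time_missing_feature_is_error():
    X, _ = _toy(30)
    _, params = standardize(X)
    with pytest.raises(GaitTraitError, match="missing"):
        standardize(X.drop(columns=["f3"]), params)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def test_sfs_finds_the_planted_feature():
    X, y = _toy(80, noise=0.0)
    selected, trace = sequential_forward_selection(X, y, max_k=3, tol=1e-6)
    assert selected[0] == "f7"
    # brute-force single-feature CV scan agrees with the first step
    folds = list(KFold(10, shuffle=True, random_state=0).split(X))
    best, best_r = None, -np.inf
    for col in X.columns:
        preds = np.empty(len(y))
        for tr, te in folds:
            x = X[col].to_numpy()
            A = np.column_stack([np.ones(len(tr)), x[tr]])
            beta, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
            preds[te] = beta[0] + beta[1] * x[te]
        r = np.corrcoef(preds, y)[0, 1]
        if r > best_r:
            best, best_r = col, r
    assert best == "f7"
    assert trace[0][1] == pytest.approx(best_r, abs=1e-12)


def test_sfs_stopping_and_monotonicity():
    X, y = _toy(60, noise=0.5, seed=2)
    sel_one, _ = sequential_forward_selection(X, y, tol=np.inf)
    assert len(sel_one) == 1
    _, trace = sequential_forward_selection(X, y, max_k=6, tol=1e-8)
    scores = [s for _, s in trace]
    assert scores == sorted(scores)


def test_sfs_zero_variance_target_rejected():
    X, _ = _toy(30)
    with pytest.raises(GaitTraitError, match="zero variance"):
        sequential_forward_selection(X, np.ones(30))


def test_fast_lr_scan_matches_naive_refit():
    """The residualised candidate scan equals per-candidate OLS refits."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(45, 14))
    y = X[:, 2] - 0.5 * X[:, 9] + 0.3 * rng.normal(size=45)
    folds = list(KFold(5, shuffle=True, random_state=1).split(X))
    for base in ([], [2], [2, 9]):
        cand = np.array([j for j in range(14) if j not in base])
        fast = _candidate_scan_lr(X, y, base, cand, folds, "r")
        slow = _candidate_scan_generic(X, y, base, cand, folds, "r",
                                       lambda: make_estimator("lr"))
        np.testing.assert_allclose(fast, slow, atol=1e-10)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def test_all_algorithms_instantiate_and_fit():
    X, y = _toy(30, p=3, noise=0.3)
    for algo in ALGORITHMS:
        model = TraitRegressor(algorithm=algo, select=False, random_state=0)
        model.fit(X, y)
        assert len(model.predict(X)) == 30


def test_linear_fit_is_exact_ols():
    rng = np.random.default_rng(4)
    x = rng.normal(size=50)
    X = pd.DataFrame({"x": x})
    y = 2.0 * x + 1.0
    est = make_estimator("lr").fit(X[["x"]].to_numpy(), y)
    assert est.coef_[0] == pytest.approx(2.0, abs=1e-8)
    assert est.intercept_ == pytest.approx(1.0, abs=1e-8)


def test_rfr_is_deterministic_given_seed():
    X, y = _toy(40, p=10, noise=0.5, seed=6)
    p1 = TraitRegressor("rfr", select=False, random_state=7).fit(X, y).predict(X)
    p2 = TraitRegressor("rfr", select=False, random_state=7).fit(X, y).predict(X)
    np.testing.assert_array_equal(p1, p2)


def test_gp_interpolates_noiseless_smooth_function():
    x = np.linspace(-2, 2, 60)
    X = pd.DataFrame({"x": x})
    y = np.sin(x)
    model = TraitRegressor("gp", select=False, random_state=0).fit(X, y)
    np.testing.assert_allclose(model.predict(X), y, atol=1e-2)


def test_predict_missing_features_listed():
    X, y = _toy(30, noise=0.1)
    model = TraitRegressor("lr", max_features=2, tol=1e-6).fit(X, y)
    with pytest.raises(GaitTraitError, match="missing selected"):
        model.predict(X.drop(columns=model.selected_features_[:1]))


def test_model_serialization_round_trip(tmp_path):
    X, y = _toy(40, noise=0.2)
    model = TraitRegressor("lr", max_features=3, tol=1e-6).fit(X, y)
    save_model(model, tmp_path / "m.joblib")
    back = load_model(tmp_path / "m.joblib")
    np.testing.assert_array_equal(model.predict(X), back.predict(X))
    assert back.selected_features_ == model.selected_features_


def test_sklearn_params_protocol():
    model = TraitRegressor(algorithm="svr_rbf", max_features=5)
    params = model.get_params()
    assert params["algorithm"] == "svr_rbf"
    clone(model).set_params(algorithm="lr")


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def test_perfectly_linear_target_scores_r_one():
    X, y = _toy(60, noise=0.0)
    rep = cross_validate(X, y, "lr", k=10, seed=0, tol=1e-6)
    assert rep.r_all == pytest.approx(1.0, abs=1e-9)
    assert rep.mse == pytest.approx(0.0, abs=1e-12)
    assert len(rep.pooled_predictions) == 60
    assert sorted(rep.fold_assignment.unique()) == list(range(10))


def test_pooled_r_invariant_to_positive_affine_target():
    X, y = _toy(50, noise=0.8, seed=8)
    r1 = cross_validate(X, y, "lr", k=5, seed=1).r_all
    r2 = cross_validate(X, 3.0 * y + 11.0, "lr", k=5, seed=1).r_all
    assert r2 == pytest.approx(r1, abs=1e-9)


def test_subgroup_reporting_and_small_group_warning():
    X, y = _toy(50, noise=0.5, seed=9)
    labels = np.array(["a"] * 48 + ["b"] * 2)
    with pytest.warns(GaitWarning, match="<3 members"):
        rep = cross_validate(X, y, "lr", k=5, seed=0, subgroup_labels=labels)
    assert np.isnan(rep.r_by_group["b"])
    assert -1 <= rep.r_by_group["a"] <= 1


def test_paper_mode_selects_once_before_folds():
    X, y = _toy(50, noise=0.5, seed=10)
    rep = cross_validate(X, y, "lr", k=5, seed=0, paper_mode=True)
    assert rep.paper_mode and len(rep.selection_traces) == 1
    rep2 = cross_validate(X, y, "lr", k=5, seed=0, paper_mode=False)
    assert len(rep2.selection_traces) == 5
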