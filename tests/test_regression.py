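"""PLS fitting against independent oracles, CV mechanics, sweep and benchmark."""

import numpy as np
import pytest

from ncaabind.regression import (
    benchmark,
    component_sweep,
    cross_validate,
    fit_pls,
    load_model,
    make_folds,
    predict,
    r_squared,
    rmse,
    save_model,
)


def nipals_pls1(X, y, A):
    """Reference single-response NIPALS PLS with X-deflation, centred, unscaled.

    Written independently of the package implementation: accumulates weights,
    loadings and scores one component at a time and composes the coefficient
    vector as W (PᵀW)⁻¹ q.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    E = X - x_mean
    f = y - y_mean
    W, P, Q = [], [], []
    for _ in range(A):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = f @ t / tt
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    beta = W @ np.linalg.solve(P.T @ W, Q)

    def predict_fn(Xnew):
        return (np.atleast_2d(Xnew) - x_mean) @ beta + y_mean

    return beta, predict_fn


def test_pls_matches_nipals_oracle(rng):
    X = rng.standard_normal((20, 5))
    y = X @ rng.standard_normal(5) + 0.3 * rng.standard_normal(20)
    for A in (1, 2, 3):
        model = fit_pls(X, y, n_components=A)
        _, oracle = nipals_pls1(X, y, A)
        assert np.allclose(model.predict(X), oracle(X).ravel(), atol=1e-8)
        Xnew = rng.standard_normal((7, 5))
        assert np.allclose(model.predict(Xnew), oracle(Xnew).ravel(), atol=1e-8)


def test_pls_exact_fit_noise_free(rng):
    # orthogonal design with distinct column variances: a noise-free target on
    # three columns spans a 3-dimensional Krylov space, so 3 components fit it
    M = rng.standard_normal((40, 8))
    Q, _ = np.linalg.qr(M - M.mean(axis=0))
    X = Q * np.arange(1.0, 9.0)
    beta = np.zeros(8)
    beta[[1, 4, 6]] = [2.0, -1.0, 0.5]
    y = X @ beta
    model = fit_pls(X, y, n_components=3)
    assert np.max(np.abs(model.predict(X) - y)) <= 1e-8


def test_pls_single_column_equals_univariate_slope(rng):
    x = rng.standard_normal(30)
    y = 2.5 * x + rng.standard_normal(30)
    X = x[:, None]
    model = fit_pls(X, y, n_components=1)
    xc, yc = x - x.mean(), y - y.mean()
    slope = (xc @ yc) / (xc @ xc)
    assert model.coef[0] == pytest.approx(slope, abs=1e-10)


def test_pls_full_rank_equals_ols(rng):
    X = rng.standard_normal((25, 6))
    y = X @ rng.standard_normal(6) + rng.standard_normal(25)
    model = fit_pls(X, y, n_components=6)
    Xc = X - X.mean(axis=0)
    beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
    pred_ols = Xc @ beta_ols + y.mean()
    assert np.allclose(model.predict(X), pred_ols, atol=1e-6)


def test_pls_duplicated_column_invariance_at_full_rank(rng):
    # duplicating a column leaves the column space unchanged; at full rank the
    # PLS fit coincides with the least-squares projection, so predictions match
    X = rng.standard_normal((30, 5))
    y = X @ rng.standard_normal(5) + 0.1 * rng.standard_normal(30)
    Xdup = np.hstack([X, X[:, [2]]])
    m1 = fit_pls(X, y, n_components=5)
    m2 = fit_pls(Xdup, y, n_components=5)
    assert np.allclose(m1.predict(X), m2.predict(Xdup), atol=1e-6)


def test_pls_input_validation(rng):
    X = rng.standard_normal((10, 4))
    with pytest.raises(ValueError, match="zero variance"):
        fit_pls(X, np.ones(10), n_components=2)
    with pytest.raises(ValueError, match="n_components"):
        fit_pls(X, rng.standard_normal(10), n_components=0)
    with pytest.raises(ValueError, match="n_components"):
        fit_pls(X, rng.standard_normal(10), n_components=5)
    model = fit_pls(X, rng.standard_normal(10), n_components=2)
    with pytest.raises(ValueError, match="features"):
        model.predict(rng.standard_normal((3, 7)))


def test_predict_centered_input_gives_mean(rng):
    X = rng.standard_normal((15, 4))
    y = rng.standard_normal(15)
    model = fit_pls(X, y, n_components=2)
    assert predict(model, X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-10)


# -- metrics ------------------------------------------------------------ #

def test_metric_hand_examples():
    y = np.array([0.0, 1.0, 2.0])
    yhat = np.array([0.0, 1.0, 3.0])
    assert rmse(y, yhat) == pytest.approx(np.sqrt(1 / 3), abs=1e-12)
    assert r_squared(y, yhat) == pytest.approx(0.5, abs=1e-12)
    assert r_squared(y, y) == 1.0
    assert rmse(y, y) == 0.0
    assert r_squared(y, np.full(3, y.mean())) == 0.0
    with pytest.raises(ValueError):
        r_squared(np.ones(3), np.ones(3))


# -- cross-validation ---------------------------------------------------- #

def test_folds_partition_indices():
    folds = make_folds(23, 5, seed=0)
    all_idx = np.concatenate(folds)
    assert len(all_idx) == 23
    assert set(all_idx) == set(range(23))
    sizes = sorted(len(f) for f in folds)
    assert sizes[-1] - sizes[0] <= 1
    with pytest.raises(ValueError):
        make_folds(3, 5, seed=0)


def test_cross_validate_recovers_noiseless_linear(rng):
    X = rng.standard_normal((60, 5))
    y = X @ rng.standard_normal(5)
    rep = cross_validate(X, y, k=5, seed=0,
                         model_factory=lambda Xt, yt: fit_pls(Xt, yt, 5))
    assert rep.mean_r2 >= 0.999
    assert rep.mean_rmse <= 1e-6
    assert len(rep.per_fold) == 5
    assert rep.mean_r2 == pytest.approx(np.mean([r for r, _ in rep.per_fold]), abs=1e-12)


def test_cross_validate_deterministic(rng):
    X = rng.standard_normal((40, 6))
    y = X @ rng.standard_normal(6) + rng.standard_normal(40)
    r1 = cross_validate(X, y, k=5, seed=3)
    r2 = cross_validate(X, y, k=5, seed=3)
    assert r1 == r2


def test_cross_validate_out_of_fold_predictions(rng):
    X = rng.standard_normal((30, 4))
    y = X @ rng.standard_normal(4) + rng.standard_normal(30)
    rep, oof = cross_validate(X, y, k=3, seed=1, return_predictions=True)
    assert oof.shape == (30, 2)
    assert np.all(np.isfinite(oof))
    assert set(oof[:, 1]) == {0.0, 1.0, 2.0}


# -- sweep & benchmark --------------------------------------------------- #

def test_sweep_selects_true_rank_on_noiseless_data(rng):
    T = rng.standard_normal((60, 2))
    X = T @ rng.standard_normal((2, 8))
    y = T @ np.array([1.5, -2.0])
    table = component_sweep(X, y, A_range=range(2, 8), k=5, seed=0)
    assert table.selected_A == 2     # larger A cannot beat a perfect rank-2 fit
    assert len(table.rows) == 6


def test_sweep_table_shape(rng):
    X = rng.standard_normal((50, 12))
    y = X @ rng.standard_normal(12) + rng.standard_normal(50)
    table = component_sweep(X, y, A_range=range(2, 11), k=5, seed=0)
    assert len(table.rows) == 9
    best_r2 = max(r for _, r, _ in table.rows)
    selected_rows = [a for a, r, _ in table.rows if r == best_r2]
    assert table.selected_A == min(selected_rows)


def test_benchmark_easy_problem_and_determinism(rng):
    X = rng.standard_normal((400, 3))
    y = X @ np.array([2.0, 0.4, 0.2])
    t1 = benchmark(X, y, k=5, seed=0)
    t2 = benchmark(X, y, k=5, seed=0)
    assert t1 == t2
    assert {name for name, _, _ in t1.rows} == {
        "PLS (3 components)", "SVR", "Random Forest", "Extra Trees", "AdaBoost"
    }
    for name, r2, e in t1.rows:
        assert r2 >= 0.9, f"{name} underperforms on noiseless linear data"
    r2s = [r for _, r, _ in t1.rows]
    assert r2s == sorted(r2s, reverse=True)


def test_model_persistence_round_trip(tmp_path, rng):
    X = rng.standard_normal((20, 5))
    y = X @ rng.standard_normal(5)
    model = fit_pls(X, y, n_components=2)
    save_model(tmp_path / "m.json", model, config={"A": 2}, data_hash="abc")
    loaded = load_model(tmp_path / "m.json")
    assert np.allclose(loaded.predict(X), model.predict(X), atol=1e-12)
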