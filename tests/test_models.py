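import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from math import comb

from conftest import make_linear_problem
from terradom import models as mod
from terradom.metrics import nrmse, rmse, sem, wilcoxon_compare
from terradom.preprocess import PreprocessSpec, zscore_target


# --- grids -----------------------------------------------------------------

def test_default_glm_grid():
    g = mod.default_grid("GLM_elastic_net")
    assert len(g) == 21 * 41
    alphas = {p["alpha"] for p in g.points}
    lams = {p["lam"] for p in g.points}
    assert min(alphas) == 0 and max(alphas) == 1 and 0.05 in alphas
    assert min(lams) == 0 and max(lams) == 2 and 1.95 in lams


def test_default_rf_grid():
    g = mod.default_grid("RF", n_features=60)
    mtries = sorted({p["mtry"] for p in g.points})
    assert mtries == [10, 20, 30, 40, 50, 60]
    assert sorted({p["min_node_size"] for p in g.points}) == [3, 5, 7, 10, 15]
    assert all(p["n_trees"] == 1000 for p in g.points)


def test_default_svr_grids():
    poly = mod.default_grid("SVR_poly")
    assert sorted({p["degree"] for p in poly.points}) == [1, 2, 3, 4, 5]
    assert all(p["scale"] == 1.0 for p in poly.points)
    rbf = mod.default_grid("SVR_rbf")
    sigmas = sorted({p["sigma"] for p in rbf.points})
    assert sigmas[0] == 1e-6 and sigmas[-1] == 1.0
    assert {2.5e-6, 2e-5, 5e-5, 2.5e-4, 5e-4} <= set(sigmas)
    assert len({p["cost"] for p in rbf.points}) == 9


# --- elastic net -----------------------------------------------------------

def test_glm_lambda_zero_equals_least_squares():
    rng = np.random.default_rng(2)
    for _ in range(10):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = mod.fit_glm_elastic_net(X, y, alpha=rng.uniform(), lam=0.0)
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(model.coef_, expected, atol=1e-6)


def test_lasso_zeroes_one_of_duplicated_columns():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(40, 1))
    X = np.hstack([x, x, rng.normal(size=(40, 1))])
    y = 2 * x[:, 0] + 0.5 * X[:, 2]
    model = mod.fit_glm_elastic_net(X, y, alpha=1.0, lam=0.05)
    assert min(abs(model.coef_[0]), abs(model.coef_[1])) < 1e-8


def test_huge_lambda_shrinks_all_weights():
    X, y, *_ = make_linear_problem(seed=4)
    model = mod.fit_glm_elastic_net(X, y, alpha=0.5, lam=1e6)
    np.testing.assert_allclose(model.coef_, 0.0, atol=1e-6)


def test_glm_rejects_non_finite():
    with pytest.raises(ValueError, match="finite"):
        mod.fit_glm_elastic_net(np.array([[np.nan]]), np.array([1.0]), 0.5, 0.1)


# --- SVR -------------------------------------------------------------------

def test_svr_poly_degree_one_fits_linear_data():
    X, y, *_ = make_linear_problem(n=60, p=5, seed=5)
    model = mod.fit_svr(X[:45], y[:45], kernel="poly", cost=1.0, degree=1,
                        epsilon=0.005)
    err = rmse(y[45:], model.predict(X[45:]))
    assert nrmse(err, y) < 1.0


def test_svr_rbf_tiny_sigma_is_mean_like():
    X, y, *_ = make_linear_problem(n=40, p=3, seed=6)
    model = mod.fit_svr(X, y, kernel="rbf", cost=1.0, sigma=1e-12)
    preds = model.predict(X)
    assert np.std(preds) < 0.05 * np.std(y)


def test_svr_invalid_kernel_params():
    X, y, *_ = make_linear_problem(seed=7)
    with pytest.raises(ValueError):
        mod.fit_svr(X, y, kernel="rbf", cost=1.0, sigma=-1.0)
    with pytest.raises(ValueError):
        mod.fit_svr(X, y, kernel="poly", cost=0.0, degree=2)


# --- random forest ---------------------------------------------------------

def test_rf_seed_determinism_and_leaf_means():
    rng = np.random.default_rng(8)
    X = np.sort(rng.uniform(0, 1, size=(60, 1)), axis=0)
    y = np.floor(X[:, 0] * 4)  # staircase
    a = mod.fit_rf(X, y, n_trees=50, mtry=1, min_node_size=3, seed=9)
    b = mod.fit_rf(X, y, n_trees=50, mtry=1, min_node_size=3, seed=9)
    np.testing.assert_array_equal(a.predict(X), b.predict(X))
    assert a.predict(X).min() >= y.min() and a.predict(X).max() <= y.max()


def test_rf_oob_error_tracks_test_error():
    X, y, *_ = make_linear_problem(n=150, p=8, n_informative=4, noise_sd=0.3,
                                   seed=10)
    rf = mod.fit_rf(X[:100], y[:100], n_trees=300, mtry=3, min_node_size=5, seed=1)
    from terradom.importance import _oob_indices
    oob_pred = np.zeros(100)
    oob_n = np.zeros(100)
    for tree, oob in zip(rf.estimators_, _oob_indices(rf, 100)):
        oob_pred[oob] += tree.predict(X[:100][oob])
        oob_n[oob] += 1
    mask = oob_n > 0
    oob_rmse = rmse(y[:100][mask], oob_pred[mask] / oob_n[mask])
    test_rmse = rmse(y[100:], rf.predict(X[100:]))
    assert abs(oob_rmse - test_rmse) / test_rmse < 0.25


# --- split and CV ----------------------------------------------------------

def test_stratified_split_counts_and_determinism():
    target = pd.Series(np.linspace(0, 1, 95))
    tr, te = mod.stratified_split(target, seed=0)
    assert len(tr) == 76 and len(te) == 19
    assert set(tr).isdisjoint(te)
    tr2, te2 = mod.stratified_split(target, seed=0)
    assert tr == tr2 and te == te2


def test_stratified_split_balances_target():
    rng = np.random.default_rng(12)
    gaps = []
    for seed in range(60):
        target = pd.Series(rng.lognormal(size=50))
        tr, te = mod.stratified_split(target, seed=seed)
        pooled = target.std(ddof=1)
        gaps.append(abs(target[tr].mean() - target[te].mean()) / pooled)
    assert np.median(gaps) < 0.5


def test_cv_folds_span_target_range():
    rng = np.random.default_rng(13)
    y = np.sort(rng.normal(size=40))
    folds = mod.cv_fold_ids(y, 10, rng)
    assert sorted(np.unique(folds)) == list(range(10))
    for f in range(10):
        vals = y[folds == f]
        assert vals.min() < np.median(y) < vals.max() or len(vals) < 4


def test_grid_search_single_point_and_determinism():
    X, y, *_ = make_linear_problem(n=40, p=6, seed=14)
    grid = mod.ModelGrid("GLM_elastic_net", ({"alpha": 0.5, "lam": 0.1},))
    res = mod.grid_search_cv("GLM_elastic_net", grid, X, y, k=5, repeats=2, seed=3)
    assert res.best_params == {"alpha": 0.5, "lam": 0.1}
    res2 = mod.grid_search_cv("GLM_elastic_net", grid, X, y, k=5, repeats=2, seed=3)
    assert res.cv_rmse == res2.cv_rmse


def test_grid_search_recovers_linear_model():
    X, y, *_ = make_linear_problem(n=60, p=10, noise_sd=0.0, seed=15)
    grid = mod.ModelGrid("GLM_elastic_net",
                         tuple({"alpha": a, "lam": l}
                               for a in (0.0, 1.0) for l in (0.0, 0.1)))
    res = mod.grid_search_cv("GLM_elastic_net", grid, X[:48], y[:48], k=5,
                             repeats=2, seed=4)
    err = rmse(y[48:], res.model.predict(X[48:]))
    assert nrmse(err, y) < 1.0


def test_grid_search_tie_breaks_to_regularization():
    # duplicated grid points give an exact RMSE tie; the preference order
    # (larger lambda, then larger alpha) must pick a deterministic winner
    X = np.random.default_rng(16).normal(size=(30, 3))
    y_lin = X @ np.array([1.0, 0.0, 0.0])
    dup = mod.ModelGrid(
        "GLM_elastic_net",
        ({"alpha": 0.0, "lam": 0.0}, {"alpha": 1.0, "lam": 0.0}),
    )
    res = mod.grid_search_cv("GLM_elastic_net", dup, X, y_lin, k=5, repeats=1, seed=5)
    assert res.best_params == {"alpha": 1.0, "lam": 0.0}


def test_grid_search_constant_target_errors():
    X = np.random.default_rng(17).normal(size=(20, 2))
    grid = mod.ModelGrid("GLM_elastic_net", ({"alpha": 0.5, "lam": 0.1},))
    with pytest.raises(ValueError, match="constant"):
        mod.grid_search_cv("GLM_elastic_net", grid, X, np.ones(20), k=5,
                           repeats=1, seed=0)


# --- metrics ---------------------------------------------------------------

def test_nrmse_worked_example():
    # 0.3 per-mil error over the -27.7..-21.9 per-mil range
    value = nrmse(0.3, [-27.7, -21.9])
    assert value == pytest.approx(5.17, abs=0.01)
    assert round(value, 1) in (5.1, 5.2)


def test_nrmse_properties():
    assert nrmse(0.0, [0, 1]) == 0.0
    assert nrmse(0.6, [0, 2]) == nrmse(0.3, [0, 1])
    with pytest.raises(ValueError):
        nrmse(0.1, [1.0, 1.0])


def test_sem():
    assert sem([1, 1, 1, 1]) == 0.0
    assert sem([0, 2]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sem([1.0])


def test_sem_scales_inverse_sqrt_n():
    rng = np.random.default_rng(18)
    small = [sem(rng.normal(size=50)) for _ in range(200)]
    large = [sem(rng.normal(size=200)) for _ in range(200)]
    assert np.mean(small) / np.mean(large) == pytest.approx(2.0, rel=0.15)


def test_wilcoxon_identical_unpaired():
    a = np.arange(10.0)
    assert wilcoxon_compare(a, a, paired=False) >= 0.99


def test_wilcoxon_paired_against_enumeration():
    """n=6, all differences positive: compare the continuity-corrected
    approximation with the exact sign-flip tail of the signed-rank statistic."""
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = a - np.array([0.4, 0.3, 0.7, 0.2, 0.9, 0.5])
    ranks = np.array([3, 2, 5, 1, 6, 4])  # ranks of |differences|
    observed = ranks.sum()  # all differences positive -> W+ = 21
    tail = 0
    for r in range(7):
        for subset in combinations(ranks, r):
            w = sum(subset)
            if w >= observed or w <= ranks.sum() - observed:
                tail += 1
    exact_p = tail / 2**6  # two-sided: 2/64
    approx_p = wilcoxon_compare(a, b, paired=True)
    assert exact_p == pytest.approx(2 / 64)
    assert approx_p == pytest.approx(exact_p, abs=0.01)
    assert approx_p < 0.05


def test_wilcoxon_monotone_invariance():
    # the rank-sum statistic only sees value ranks, so a common monotone
    # transform of both vectors leaves the unpaired p unchanged
    rng = np.random.default_rng(19)
    a, b = rng.normal(size=20), rng.normal(0.5, 1, size=20)
    p1 = wilcoxon_compare(a, b, paired=False)
    p2 = wilcoxon_compare(np.exp(a), np.exp(b), paired=False)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_wilcoxon_all_zero_differences_errors():
    with pytest.raises(ValueError):
        wilcoxon_compare(np.ones(5), np.ones(5), paired=True)


# --- benchmark -------------------------------------------------------------

SMALL_GLM = mod.ModelGrid("GLM_elastic_net",
                          tuple({"alpha": a, "lam": l}
                                for a in (0.0, 1.0) for l in (0.05, 0.5)))
SMALL_POLY = mod.ModelGrid("SVR_poly", ({"cost": 1.0, "degree": 1, "scale": 1.0},))


def test_run_benchmark_grid_shape(long_table):
    specs = [PreprocessSpec("time_aware", "ubiquitous", "SUM"),
             PreprocessSpec("time_agnostic", "none", "DOC-N")]
    results, fits = mod.run_benchmark(
        long_table, specs, families=("GLM_elastic_net", "SVR_poly"), seed=5,
        grids={"GLM_elastic_net": SMALL_GLM, "SVR_poly": SMALL_POLY},
        k=5, repeats=1,
    )
    assert len(results) == 4
    assert (results["error"] == "").all()
    assert set(fits) == {(s.key, f) for s in specs
                         for f in ("GLM_elastic_net", "SVR_poly")}
    heat = mod.heatmap_table(results)
    assert heat.shape == (2, 2)


def test_benchmark_test_set_never_in_training(long_table):
    specs = [PreprocessSpec("time_aware", "ubiquitous", "SUM")]
    tr, te = mod.stratified_split(long_table.c475, seed=5)
    assert set(tr).isdisjoint(te)
    results, fits = mod.run_benchmark(
        long_table, specs, families=("GLM_elastic_net",), seed=5,
        grids={"GLM_elastic_net": SMALL_GLM}, k=5, repeats=1,
    )
    fr = fits[(specs[0].key, "GLM_elastic_net")]
    assert fr.test_nrmse > 0


def test_benchmark_deterministic_for_glm(long_table):
    specs = [PreprocessSpec("time_agnostic", "ubiquitous", "SUM")]
    kwargs = dict(families=("GLM_elastic_net",), seed=9,
                  grids={"GLM_elastic_net": SMALL_GLM}, k=5, repeats=1)
    r1, _ = mod.run_benchmark(long_table, specs, **kwargs)
    r2, _ = mod.run_benchmark(long_table, specs, **kwargs)
    assert r1["nrmse_pct"].iloc[0] == r2["nrmse_pct"].iloc[0]


def test_mean_predictor_never_beats_tuned_glm(long_table, sum_ubiquitous):
    z, scaler = zscore_target(long_table.c475)
    tr, te = mod.stratified_split(long_table.c475, seed=2)
    X = sum_ubiquitous.values
    res = mod.grid_search_cv("GLM_elastic_net", SMALL_GLM, X.loc[tr],
                             z.loc[tr].to_numpy(), k=5, repeats=1, seed=2)
    pred = scaler.inverse(res.model.predict(X.loc[te]))
    glm_err = rmse(long_table.c475.loc[te], pred)
    mean_err = rmse(long_table.c475.loc[te],
                    np.full(len(te), long_table.c475.loc[tr].mean()))
    assert nrmse(mean_err, long_table.c475) >= nrmse(glm_err, long_table.c475)


def test_noise_monotonically_degrades_fit():
    """More target noise cannot improve the attainable test error."""
    from terradom.simulate import GeneratorConfig, generate_dataset
    from terradom.tables import build_time_agnostic
    from terradom.preprocess import preprocess_table
    levels = [0.0, 0.004, 0.012]
    mean_rmse = []
    for noise in levels:
        errs = []
        for seed in (21, 22, 23):
            ds = generate_dataset(GeneratorConfig(n_samples=50, n_formulas=80,
                                                  noise_sd=noise, seed=seed))
            table = preprocess_table(build_time_agnostic(ds.long),
                                     PreprocessSpec("time_agnostic", "ubiquitous", "SUM"),
                                     doc=ds.long.doc)
            z, scaler = zscore_target(ds.long.c475)
            tr, te = mod.stratified_split(ds.long.c475, seed=seed)
            res = mod.grid_search_cv("GLM_elastic_net", SMALL_GLM,
                                     table.values.loc[tr], z.loc[tr].to_numpy(),
                                     k=5, repeats=1, seed=seed)
            pred = scaler.inverse(res.model.predict(table.values.loc[te]))
            errs.append(rmse(ds.long.c475.loc[te], pred))
        mean_rmse.append(np.mean(errs))
    assert mean_rmse[0] < mean_rmse[2]
    assert mean_rmse[1] <= mean_rmse[2] * 1.2


def test_glm_beta_signs_match_generative_contrast():
    """Top GLM weights should point features that rise with the latent
    terrestrial fraction positive and marine-leaning features negative."""
    from terradom.simulate import GeneratorConfig, generate_dataset
    from terradom.tables import build_time_agnostic
    from terradom.preprocess import preprocess_table
    from terradom.importance import beta_importance
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        ds = generate_dataset(GeneratorConfig(n_samples=50, n_formulas=80,
                                              seed=100 + seed))
        table = preprocess_table(build_time_agnostic(ds.long),
                                 PreprocessSpec("time_agnostic", "ubiquitous", "SUM"),
                                 doc=ds.long.doc)
        z, _ = zscore_target(ds.long.c475)
        model = mod.fit_glm_elastic_net(table.values, z.to_numpy(), alpha=0.5,
                                        lam=0.01)
        rep = beta_importance(model, table.values.columns)
        top = rep.top_k(5)
        if not top:
            continue
        # generative direction of a normalized feature = how it responds to tau
        agree = sum(
            np.sign(rep.scores[key])
            == np.sign(np.corrcoef(ds.tau, table.values[key])[0, 1])
            for key in top
        )
        if agree / len(top) >= 0.6:
            hits += 1
    assert hits >= 0.9 * n_seeds
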