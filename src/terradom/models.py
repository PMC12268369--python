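"""Model families, hyperparameter grids, and the split/CV/grid-search protocol.

Four regressors predict the z-scored C475 proxy from a preprocessed feature
table: a zero-intercept elastic-net linear model, random-forest regression,
and epsilon-insensitive support-vector regression with polynomial and
radial-basis-function kernels.  The default grids hold the full benchmark
ladders (elastic-net alpha 0..1 and lambda 0..2 in 0.05 steps; 1000-tree
forests with mtry in sixths of the feature count and minimum node sizes
3/5/7/10/15; polynomial cost x degree and RBF cost x sigma ladders); smaller
studies pass reduced grids through the same interface.

The train/test split and the CV folds are stratified by target quantile so
both sets span the C475 range; the grid search scores each point by the
mean RMSE over k-fold x repeats validation folds and breaks ties toward the
stronger regularization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge
from sklearn.svm import SVR

from .metrics import nrmse, rmse
from .preprocess import PreprocessSpec, preprocess_table, zscore_target
from .tables import LongTable, build_time_agnostic, build_time_aware

__all__ = [
    "FAMILIES",
    "ModelGrid",
    "default_grid",
    "FitResult",
    "stratified_split",
    "cv_fold_ids",
    "grid_search_cv",
    "fit_glm_elastic_net",
    "fit_rf",
    "fit_svr",
    "fit_model",
    "run_benchmark",
    "heatmap_table",
]

logger = logging.getLogger(__name__)

FAMILIES = ("GLM_elastic_net", "RF", "SVR_poly", "SVR_rbf")

#: RBF kernel width ladder: 1e-6..1e-5 in factor-2.5 steps, 2e-5, a coarser
#: factor-5 rung up to 5e-4, then decades up to 1.
RBF_SIGMA_LADDER = (
    1e-6, 2.5e-6, 6.25e-6, 1e-5, 2e-5, 5e-5, 2.5e-4, 5e-4, 1e-3, 1e-2, 1e-1, 1.0
)

#: Default width of the epsilon-insensitive tube on the z-scored target.
DEFAULT_SVR_EPSILON = 0.1


@dataclass(frozen=True)
class ModelGrid:
    """A hyperparameter grid for one model family."""

    family: str
    points: tuple  # tuple of dicts

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.points:
            raise ValueError("empty hyperparameter grid")

    def __len__(self):
        return len(self.points)


def _tie_key(family: str, params: dict):
    """Sort key so that, among RMSE ties, stronger regularization wins."""
    if family == "GLM_elastic_net":
        return (-params["lam"], -params["alpha"])
    if family == "RF":
        return (params["mtry"], -params["min_node_size"])
    if family == "SVR_poly":
        return (params["degree"], params["cost"])
    if family == "SVR_rbf":
        return (params["cost"], params["sigma"])
    raise ValueError(family)


def default_grid(family: str, n_features: int | None = None, n_trees: int = 1000) -> ModelGrid:
    """The full benchmark grid for ``family`` (RF needs the feature count)."""
    if family == "GLM_elastic_net":
        alphas = np.round(np.arange(0.0, 1.0001, 0.05), 2)
        lams = np.round(np.arange(0.0, 2.0001, 0.05), 2)
        pts = tuple({"alpha": float(a), "lam": float(l)} for a in alphas for l in lams)
    elif family == "RF":
        if n_features is None:
            raise ValueError("RF grid requires the feature count")
        mtries = sorted({min(n_features, math.ceil(k * n_features / 6)) for k in range(1, 7)})
        nodes = (3, 5, 7, 10, 15)
        pts = tuple(
            {"n_trees": n_trees, "mtry": m, "min_node_size": s}
            for m in mtries
            for s in nodes
        )
    elif family == "SVR_poly":
        costs = (0.01, 0.1, 0.25, 0.5, 0.75, 1.0)
        pts = tuple(
            {"cost": c, "degree": d, "scale": 1.0} for c in costs for d in range(1, 6)
        )
    elif family == "SVR_rbf":
        costs = (0.001, 0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99, 1.0)
        logger.info("RBF sigma grid: %s", list(RBF_SIGMA_LADDER))
        pts = tuple({"cost": c, "sigma": s} for c in costs for s in RBF_SIGMA_LADDER)
    else:
        raise ValueError(f"unknown family {family!r}")
    return ModelGrid(family=family, points=pts)


# ---------------------------------------------------------------------------
# model fitting

class GLMElasticNet:
    """Zero-intercept elastic net: (1/2n)|y - Xb|^2 + lam*((1-alpha)/2 |b|_2^2 + alpha |b|_1).

    ``alpha`` mixes the penalties (1 = lasso, 0 = ridge) and ``lam`` sets the
    overall strength; ``lam`` = 0 is exact unpenalized least squares.
    """

    def __init__(self, alpha: float, lam: float):
        if not (0 <= alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if lam < 0:
            raise ValueError("lam must be non-negative")
        self.alpha = alpha
        self.lam = lam
        self.intercept_ = 0.0
        self.coef_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in model inputs")
        n = X.shape[0]
        if self.lam == 0:
            inner = LinearRegression(fit_intercept=False)
        elif self.alpha == 0:
            # ridge limit: lam*(1/2)|b|^2 per (1/2n) loss == Ridge with n*lam
            inner = Ridge(alpha=n * self.lam, fit_intercept=False)
        else:
            inner = ElasticNet(
                alpha=self.lam, l1_ratio=self.alpha, fit_intercept=False,
                max_iter=20_000,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            inner.fit(X, y)
        self.coef_ = np.asarray(inner.coef_, dtype=float)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


def fit_glm_elastic_net(X, y, alpha: float, lam: float) -> GLMElasticNet:
    return GLMElasticNet(alpha=alpha, lam=lam).fit(X, y)


def fit_rf(X, y, n_trees: int = 1000, mtry: int | None = None,
           min_node_size: int = 5, seed: int = 0) -> RandomForestRegressor:
    """Variance-split random forest; per-tree bootstrap structure is retained
    so out-of-bag permutation importance can be computed downstream."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if mtry is None:
        mtry = p
    if not (1 <= mtry <= p):
        raise ValueError(f"mtry must be in [1, {p}]")
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        criterion="squared_error",
        max_features=mtry,
        min_samples_leaf=min_node_size,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(X, np.asarray(y, dtype=float))
    return rf


def fit_svr(X, y, kernel: str, cost: float, *, sigma: float | None = None,
            degree: int | None = None, scale: float = 1.0,
            epsilon: float = DEFAULT_SVR_EPSILON) -> SVR:
    """Epsilon-insensitive SVR with a polynomial or RBF kernel.

    The polynomial kernel is (scale * <x, x'> + 1)^degree with the scale
    fixed at one; the RBF kernel is exp(-sigma * |x - x'|^2).
    """
    if cost <= 0:
        raise ValueError("cost must be positive")
    if kernel == "poly":
        if degree is None or degree < 1:
            raise ValueError("polynomial kernel requires degree >= 1")
        if scale <= 0:
            raise ValueError("non-positive kernel scale")
        model = SVR(kernel="poly", degree=int(degree), gamma=scale, coef0=1.0,
                    C=cost, epsilon=epsilon)
    elif kernel == "rbf":
        if sigma is None or sigma <= 0:
            raise ValueError("rbf kernel requires sigma > 0")
        model = SVR(kernel="rbf", gamma=sigma, C=cost, epsilon=epsilon)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


def fit_model(family: str, X, y, params: dict, seed: int = 0,
              epsilon: float = DEFAULT_SVR_EPSILON):
    if family == "GLM_elastic_net":
        return fit_glm_elastic_net(X, y, alpha=params["alpha"], lam=params["lam"])
    if family == "RF":
        return fit_rf(X, y, n_trees=params.get("n_trees", 1000), mtry=params["mtry"],
                      min_node_size=params["min_node_size"], seed=seed)
    if family == "SVR_poly":
        return fit_svr(X, y, kernel="poly", cost=params["cost"],
                       degree=params["degree"], scale=params.get("scale", 1.0),
                       epsilon=epsilon)
    if family == "SVR_rbf":
        return fit_svr(X, y, kernel="rbf", cost=params["cost"],
                       sigma=params["sigma"], epsilon=epsilon)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# splitting and cross-validation

def stratified_split(target: pd.Series, train_fraction: float = 0.8,
                     seed: int = 0, n_bins: int = 5):
    """Train/test split stratified by target quantile.

    Rounds the train count toward ``floor(train_fraction * n)`` overall
    (95 samples -> 76 train / 19 test), allocating per-bin counts by
    largest fractional remainder.  Falls back to a plain random split with
    a warning when there are fewer samples than bins.
    """
    target = pd.Series(target)
    n = len(target)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    n_train = int(math.floor(train_fraction * n))
    order = np.argsort(target.to_numpy(), kind="stable")
    if n < n_bins:
        warnings.warn("fewer samples than strata; using a random split")
        perm = rng.permutation(n)
        train_pos, test_pos = perm[:n_train], perm[n_train:]
    else:
        bins = np.array_split(order, n_bins)
        quotas = [train_fraction * len(b) for b in bins]
        base = [int(math.floor(q)) for q in quotas]
        short = n_train - sum(base)
        remainders = sorted(
            range(n_bins), key=lambda i: (-(quotas[i] - base[i]), i)
        )
        for i in remainders[:short]:
            base[i] += 1
        train_pos, test_pos = [], []
        for b, k in zip(bins, base):
            b = rng.permutation(b)
            train_pos.extend(b[:k])
            test_pos.extend(b[k:])
        train_pos, test_pos = np.sort(train_pos), np.sort(test_pos)
    idx = target.index
    return list(idx[train_pos]), list(idx[test_pos])


def cv_fold_ids(y, k: int, rng) -> np.ndarray:
    """Fold assignment stratified by target quantile.

    Samples are ordered by target and partitioned into consecutive chunks of
    size ``k``; within each chunk the fold labels are a random permutation,
    so every fold spans the target range.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        chunk = order[start:start + k]
        labels = rng.permutation(k)[: len(chunk)]
        folds[chunk] = labels
    return folds


@dataclass
class GridSearchResult:
    family: str
    best_params: dict
    cv_rmse: float
    cv_table: pd.DataFrame
    model: object
    seed: int


def grid_search_cv(family: str, grid: ModelGrid, X, y, k: int = 10,
                   repeats: int = 10, seed: int = 0,
                   epsilon: float = DEFAULT_SVR_EPSILON) -> GridSearchResult:
    """Repeated stratified k-fold grid search; refits the winner on all data.

    The score of a grid point is the mean RMSE over all k x repeats
    validation folds; ties go to the stronger regularization.  Folds are
    re-randomized on every repeat.
    """
    if grid.family != family:
        raise ValueError("grid/family mismatch")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant target: cross-validation is degenerate")
    rng = np.random.default_rng(seed)
    sq_err = np.zeros(len(grid))
    n_pred = 0
    for rep in range(repeats):
        folds = cv_fold_ids(y, k, rng)
        for fold in range(k):
            val = folds == fold
            if not val.any():
                continue
            Xtr, ytr = X[~val], y[~val]
            Xva, yva = X[val], y[val]
            if np.ptp(ytr) == 0:
                raise ValueError("degenerate fold with constant training target")
            for gi, params in enumerate(grid.points):
                fit_seed = int(rng.integers(0, 2**31 - 1)) if family == "RF" else 0
                model = fit_model(family, Xtr, ytr, params, seed=fit_seed,
                                  epsilon=epsilon)
                resid = model.predict(Xva) - yva
                sq_err[gi] += float(np.sum(resid**2))
            n_pred += int(val.sum())
    mean_rmse = np.sqrt(sq_err / n_pred)
    best_score = mean_rmse.min()
    tied = [i for i in range(len(grid)) if mean_rmse[i] <= best_score + 1e-12]
    best_i = min(tied, key=lambda i: _tie_key(family, grid.points[i]))
    best_params = dict(grid.points[best_i])
    final_seed = int(rng.integers(0, 2**31 - 1))
    model = fit_model(family, X, y, best_params, seed=final_seed, epsilon=epsilon)
    table = pd.DataFrame([dict(p, cv_rmse=r) for p, r in zip(grid.points, mean_rmse)])
    return GridSearchResult(
        family=family, best_params=best_params, cv_rmse=float(best_score),
        cv_table=table, model=model, seed=seed,
    )


# ---------------------------------------------------------------------------
# benchmark over preprocessing combinations

@dataclass
class FitResult:
    """One benchmark cell: a tuned model evaluated on the held-out test set.

    Test metrics are reported on the original C475 scale; NRMSE divides the
    test RMSE by the full-dataset C475 range, in percent.
    """

    spec: PreprocessSpec
    family: str
    best_params: dict
    cv_rmse: float
    test_rmse: float
    test_nrmse: float
    test_r2: float
    test_mae: float
    n_features: int
    model: object
    seed: int
    feature_names: list = field(default_factory=list)


def _evaluate(model, X_test, y_test_orig, scaler, full_target):
    pred = scaler.inverse(model.predict(np.asarray(X_test, dtype=float)))
    y = np.asarray(y_test_orig, dtype=float)
    r = rmse(y, pred)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "test_rmse": r,
        "test_nrmse": nrmse(r, full_target),
        "test_r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "test_mae": float(np.mean(np.abs(y - pred))),
    }


def run_benchmark(long: LongTable, specs, families=FAMILIES, seed: int = 0,
                  grids: dict | None = None, k: int = 10, repeats: int = 10,
                  rf_n_trees: int = 1000, train_fraction: float = 0.8):
    """Fit every (preprocessing spec x model family) cell.

    Returns a results DataFrame (one row per cell, NRMSE in percent) and a
    dict of :class:`FitResult` keyed by (spec.key, family).  Cell failures
    are recorded in the table rather than aborting the grid.  ``grids`` maps
    family name to a :class:`ModelGrid` override; without an override the
    full default grid is used.
    """
    base = {
        "time_aware": build_time_aware(long),
        "time_agnostic": build_time_agnostic(long),
    }
    target = long.c475
    z_all, scaler = zscore_target(target)
    train_ids, test_ids = stratified_split(target, train_fraction, seed=seed)
    rows, fits = [], {}
    cell_rng = np.random.default_rng(seed)
    for spec in specs:
        try:
            table = preprocess_table(base[spec.table_format], spec, doc=long.doc)
        except Exception as exc:  # record, keep going
            for family in families:
                rows.append({"spec": spec.key, "family": family, "error": str(exc)})
            continue
        X_train = table.values.loc[train_ids]
        X_test = table.values.loc[test_ids]
        y_train = z_all.loc[train_ids].to_numpy()
        for family in families:
            cell_seed = int(cell_rng.integers(0, 2**31 - 1))
            try:
                if grids and family in grids:
                    grid = grids[family]
                elif family == "RF":
                    grid = default_grid("RF", n_features=table.n_features,
                                        n_trees=rf_n_trees)
                else:
                    grid = default_grid(family)
                gs = grid_search_cv(family, grid, X_train, y_train, k=k,
                                    repeats=repeats, seed=cell_seed)
                ev = _evaluate(gs.model, X_test, target.loc[test_ids], scaler, target)
                fr = FitResult(
                    spec=spec, family=family, best_params=gs.best_params,
                    cv_rmse=gs.cv_rmse, n_features=table.n_features,
                    model=gs.model, seed=cell_seed,
                    feature_names=list(table.values.columns), **ev,
                )
                fits[(spec.key, family)] = fr
                rows.append({
                    "spec": spec.key, "table_format": spec.table_format,
                    "elimination": spec.elimination,
                    "normalization": spec.normalization, "family": family,
                    "n_features": table.n_features,
                    "nrmse_pct": fr.test_nrmse, "rmse": fr.test_rmse,
                    "r2": fr.test_r2, "mae": fr.test_mae,
                    "cv_rmse": fr.cv_rmse, "error": "",
                })
            except Exception as exc:
                rows.append({"spec": spec.key, "family": family, "error": str(exc)})
    return pd.DataFrame(rows), fits


def heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """NRMSE grid: rows = normalization, columns = family, one block per
    table-format x elimination combination."""
    ok = results[results["error"] == ""]
    return ok.pivot_table(
        index=["table_format", "elimination", "normalization"],
        columns="family", values="nrmse_pct",
    )
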