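"""Feature importance, top-k stability, SHAP compositions, and RFE.

Importance scores carry a sign convention inherited from the z-scored C475
target: a positive beta weight or SHAP value marks a feature whose intensity
pushes the prediction toward the terrestrial end member, a negative one
toward the marine end member.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .formulas import MolecularFormula, parse_formula
from .metrics import nrmse, jaccard  # noqa: F401  (jaccard re-exported here)
from .models import cv_fold_ids, fit_rf
from .shapley import forest_expected_value, forest_shap_values, sampling_shap_values
from .tables import split_feature_key

__all__ = [
    "ImportanceReport",
    "CompositionSummary",
    "beta_importance",
    "permutation_importance_oob",
    "shap_values",
    "shap_report",
    "top_k_union",
    "shap_composition",
    "recursive_feature_elimination",
    "jaccard",
]


@dataclass
class ImportanceReport:
    """Per-feature importance scores from one fitted model.

    ``method`` is one of ``beta``, ``permutation``, ``shap_mean_abs``.  For
    SHAP reports the full per-sample matrix and base values are attached.
    """

    method: str
    scores: pd.Series
    shap_matrix: pd.DataFrame | None = None
    base_value: float | np.ndarray | None = None

    def top_k(self, k: int) -> list:
        """Top-k feature keys by |score|; exact-zero scores are excluded.

        Ties are broken by feature key.  ``k`` larger than the number of
        scored features clamps with a warning.
        """
        nonzero = self.scores[self.scores != 0]
        if len(nonzero) == 0:
            warnings.warn(f"{self.method} report has no nonzero scores")
            return []
        if k > len(nonzero):
            warnings.warn(
                f"k={k} exceeds the {len(nonzero)} scored features; clamping"
            )
            k = len(nonzero)
        ranked = sorted(nonzero.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
        return [key for key, _ in ranked[:k]]


def beta_importance(model, feature_names) -> ImportanceReport:
    """Beta weights of a zero-intercept linear model as importance scores."""
    intercept = getattr(model, "intercept_", None)
    if intercept is None or not np.isclose(float(np.ravel([intercept])[0]), 0.0):
        raise ValueError("beta importance requires a zero-intercept linear model")
    scores = pd.Series(np.asarray(model.coef_, dtype=float), index=list(feature_names))
    if (scores == 0).all():
        warnings.warn("all beta weights are zero; ranking is empty")
    return ImportanceReport(method="beta", scores=scores)


def _oob_indices(forest: RandomForestRegressor, n: int):
    for in_bag in forest.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[in_bag] = False
        yield np.flatnonzero(mask)


def permutation_importance_oob(forest: RandomForestRegressor, X, y,
                               seed: int = 0, feature_names=None) -> ImportanceReport:
    """Out-of-bag permutation importance, averaged over trees.

    For each tree, the feature values are shuffled among that tree's
    out-of-bag samples and the increase in OOB mean squared error is
    recorded; features a tree never splits on contribute exactly zero for
    that tree and are skipped.  Shuffles are seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    total = np.zeros(p)
    for tree, oob in zip(forest.estimators_, _oob_indices(forest, n)):
        if oob.size < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            err = np.mean((tree.predict(Xp) - yo) ** 2)
            total[j] += err - base
    scores = total / len(forest.estimators_)
    names = list(feature_names) if feature_names is not None else list(range(p))
    return ImportanceReport(method="permutation", scores=pd.Series(scores, index=names))


def shap_values(model, X, background=None, n_permutations: int = 64, seed: int = 0):
    """Per-sample, per-feature SHAP matrix plus base value(s).

    Tree ensembles use the exact path-dependent algorithm; any other model
    falls back to the seeded permutation-sampling estimator against
    ``background`` (default: ``X`` itself).
    """
    Xv = np.asarray(X, dtype=float)
    if isinstance(model, RandomForestRegressor) or hasattr(model, "estimators_"):
        phi = forest_shap_values(model, Xv)
        base = forest_expected_value(model)
    elif hasattr(model, "tree_"):
        from .shapley import tree_expected_value, tree_shap_values
        phi = tree_shap_values(model, Xv)
        base = tree_expected_value(model)
    else:
        if background is None:
            background = Xv
        phi, base = sampling_shap_values(
            model.predict, Xv, background, n_permutations=n_permutations, seed=seed
        )
    return phi, base


def shap_report(model, X: pd.DataFrame, **kwargs) -> ImportanceReport:
    """SHAP importance report; global ranking uses mean |SHAP| over samples."""
    phi, base = shap_values(model, X.to_numpy(), **kwargs)
    mat = pd.DataFrame(phi, index=X.index, columns=X.columns)
    scores = mat.abs().mean(axis=0)
    return ImportanceReport(
        method="shap_mean_abs", scores=scores, shap_matrix=mat, base_value=base
    )


def top_k_union(reports, k: int = 100) -> set:
    """Union of each report's top-k feature keys."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one importance report")
    out = set()
    for rep in reports:
        out.update(rep.top_k(k))
    return out


@dataclass
class CompositionSummary:
    """SHAP-weighted mean elemental composition of one sample's terrestrial markers."""

    counts: dict  # element -> fractional mean count
    n_to_c: float
    s_to_c: float
    sample_id: object = None
    weighting: str = "minmax"
    n_features: int = 0


def _formula_of(key: str) -> MolecularFormula:
    label, _ = split_feature_key(key)
    return parse_formula(label)


def shap_composition(shap_row: pd.Series, formulas: dict | None = None,
                     sample_id=None, scaling: str = "minmax") -> CompositionSummary:
    """Weighted mean composition of the positive-SHAP (terrestrial) features.

    Positive SHAP values are min-max scaled to [0, 1] over the positive
    subset (``scaling='max'`` divides by the maximum instead) and used as
    weights on the element counts; negative-SHAP features are read as marine
    and excluded.  If all positive values coincide, weights are uniform.
    """
    pos = shap_row[shap_row > 0]
    if len(pos) == 0:
        raise ValueError("no positive SHAP values: no terrestrial-leaning features")
    v = pos.to_numpy(dtype=float)
    if scaling == "minmax":
        span = v.max() - v.min()
        w = (v - v.min()) / span if span > 0 else np.ones_like(v)
    elif scaling == "max":
        w = v / v.max()
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if w.sum() == 0:  # single feature or all equal after min-max
        w = np.ones_like(w)
    counts = {el: 0.0 for el in ("C", "H", "N", "O", "S")}
    for key, wi in zip(pos.index, w):
        f = formulas[key] if formulas is not None else _formula_of(key)
        for el in counts:
            counts[el] += wi * f.counts[el]
    for el in counts:
        counts[el] /= w.sum()
    return CompositionSummary(
        counts=counts,
        n_to_c=counts["N"] / counts["C"],
        s_to_c=counts["S"] / counts["C"],
        sample_id=sample_id,
        weighting=scaling,
        n_features=len(pos),
    )


def recursive_feature_elimination(X: pd.DataFrame, y, rf_params: dict,
                                  step_fraction: float = 0.1, k: int = 10,
                                  seed: int = 0) -> pd.DataFrame:
    """RFE driven by OOB permutation importance.

    Each iteration fits a forest on the remaining features, records the
    k-fold cross-validated NRMSE (error from the omitted folds, not a
    held-out set), then drops the ``floor(step_fraction * p)`` (at least
    one) least-important features.  Hyperparameters stay fixed except mtry,
    which is re-derived as the same fraction of the shrinking feature count.
    The curve is returned down to a single feature.
    """
    if X.shape[1] < 2:
        raise ValueError("RFE needs at least two features")
    y = np.asarray(y, dtype=float)
    target_span = y.max() - y.min()
    if target_span <= 0:
        raise ValueError("constant target")
    rng = np.random.default_rng(seed)
    n_trees = rf_params.get("n_trees", 1000)
    min_node = rf_params.get("min_node_size", 5)
    mtry0 = rf_params.get("mtry", X.shape[1])
    mtry_fraction = mtry0 / X.shape[1]
    cols = list(X.columns)
    rows = []
    while True:
        p = len(cols)
        Xc = X[cols].to_numpy(dtype=float)
        mtry = max(1, min(p, int(round(mtry_fraction * p))))
        # cross-validated NRMSE at this feature count
        folds = cv_fold_ids(y, k, rng)
        sq = 0.0
        for fold in range(k):
            val = folds == fold
            rf = fit_rf(Xc[~val], y[~val], n_trees=n_trees, mtry=mtry,
                        min_node_size=min_node,
                        seed=int(rng.integers(0, 2**31 - 1)))
            sq += float(np.sum((rf.predict(Xc[val]) - y[val]) ** 2))
        cv_rmse = math.sqrt(sq / len(y))
        rows.append({"n_features": p, "cv_nrmse_pct": nrmse(cv_rmse, y),
                     "mtry": mtry})
        if p == 1:
            break
        rf_full = fit_rf(Xc, y, n_trees=n_trees, mtry=mtry,
                         min_node_size=min_node,
                         seed=int(rng.integers(0, 2**31 - 1)))
        report = permutation_importance_oob(
            rf_full, Xc, y, seed=int(rng.integers(0, 2**31 - 1)),
            feature_names=cols,
        )
        n_drop = max(1, int(math.floor(step_fraction * p)))
        order = report.scores.sort_values(kind="stable")
        dropped = set(order.index[:n_drop])
        cols = [c for c in cols if c not in dropped]
    return pd.DataFrame(rows)
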