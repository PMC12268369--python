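"""Shapley additive feature attributions for the fitted models.

Two estimators are provided:

* :func:`forest_shap_values` — the path-dependent polynomial-time algorithm
  for decision-tree ensembles.  The coalition value of a feature subset is
  the tree's expected prediction when splits on absent features are averaged
  with their training cover; the resulting attributions satisfy additivity
  exactly: per sample they sum to the prediction minus the cover-weighted
  mean leaf value.
* :func:`sampling_shap_values` — a seeded permutation-sampling estimator for
  arbitrary regressors.  Each permutation walks from a background sample to
  the explained sample one feature at a time, so the telescoping sum makes
  additivity exact with respect to the mean background prediction even at a
  small number of draws; the per-feature attribution converges to the
  Shapley value as draws increase.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tree_shap_values",
    "forest_shap_values",
    "tree_expected_value",
    "forest_expected_value",
    "sampling_shap_values",
]


def _tree_arrays(tree):
    """Extract flat arrays from an sklearn ``tree_`` object."""
    t = tree.tree_ if hasattr(tree, "tree_") else tree
    return (
        t.children_left,
        t.children_right,
        t.feature,
        t.threshold,
        t.value[:, 0, 0],
        t.weighted_n_node_samples,
    )


def tree_expected_value(tree) -> float:
    """Cover-weighted mean leaf value (the base value of the attribution)."""
    left, right, _, _, value, cover = _tree_arrays(tree)
    leaves = left < 0
    return float(np.sum(value[leaves] * cover[leaves]) / cover[0])


def forest_expected_value(forest) -> float:
    return float(np.mean([tree_expected_value(e) for e in forest.estimators_]))


def _unwound_sum(zf, of, pw, depth, i):
    one, zero = of[i], zf[i]
    nxt = pw[depth]
    total = 0.0
    for j in range(depth - 1, -1, -1):
        if one != 0:
            tmp = nxt * (depth + 1) / ((j + 1) * one)
            total += tmp
            nxt = pw[j] - tmp * zero * (depth - j) / (depth + 1)
        else:
            total += (pw[j] / zero) / ((depth - j) / (depth + 1))
    return total


def _unwind(fi, zf, of, pw, depth, i):
    one, zero = of[i], zf[i]
    nxt = pw[depth]
    for j in range(depth - 1, -1, -1):
        if one != 0:
            tmp = pw[j]
            pw[j] = nxt * (depth + 1) / ((j + 1) * one)
            nxt = tmp - pw[j] * zero * (depth - j) / (depth + 1)
        else:
            pw[j] = (pw[j] * (depth + 1)) / (zero * (depth - j))
    for j in range(i, depth):
        fi[j] = fi[j + 1]
        zf[j] = zf[j + 1]
        of[j] = of[j + 1]


def _extend(fi, zf, of, pw, depth, pzf, pof, pfi):
    fi[depth] = pfi
    zf[depth] = pzf
    of[depth] = pof
    pw[depth] = 1.0 if depth == 0 else 0.0
    for j in range(depth - 1, -1, -1):
        pw[j + 1] += pof * pw[j] * (j + 1) / (depth + 1)
        pw[j] = pzf * pw[j] * (depth - j) / (depth + 1)


def _recurse(arrays, x, phi, node, depth, p_fi, p_zf, p_of, p_pw, pzf, pof, pfi):
    left, right, feature, threshold, value, cover = arrays
    fi = p_fi[:depth] + [0]
    zf = p_zf[:depth] + [0.0]
    of = p_of[:depth] + [0.0]
    pw = p_pw[:depth] + [0.0]
    _extend(fi, zf, of, pw, depth, pzf, pof, pfi)
    if left[node] < 0:  # leaf
        for i in range(1, depth + 1):
            w = _unwound_sum(zf, of, pw, depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * value[node]
        return
    d = feature[node]
    if x[d] <= threshold[node]:
        hot, cold = left[node], right[node]
    else:
        hot, cold = right[node], left[node]
    hot_zf = cover[hot] / cover[node]
    cold_zf = cover[cold] / cover[node]
    inc_zf, inc_of = 1.0, 1.0
    path_i = 0
    while path_i <= depth:
        if fi[path_i] == d:
            break
        path_i += 1
    if path_i != depth + 1:
        inc_zf, inc_of = zf[path_i], of[path_i]
        _unwind(fi, zf, of, pw, depth, path_i)
        depth -= 1
    _recurse(arrays, x, phi, hot, depth + 1, fi, zf, of, pw,
             hot_zf * inc_zf, inc_of, d)
    _recurse(arrays, x, phi, cold, depth + 1, fi, zf, of, pw,
             cold_zf * inc_zf, 0.0, d)


def tree_shap_values(tree, X) -> np.ndarray:
    """Path-dependent SHAP values for one fitted decision tree.

    Returns an (n_samples, n_features) array; per sample the values sum to
    ``tree.predict(x) - tree_expected_value(tree)``.
    """
    X = np.asarray(X, dtype=float)
    arrays = _tree_arrays(tree)
    n, p = X.shape
    out = np.zeros((n, p))
    for i in range(n):
        phi = out[i]
        _recurse(arrays, X[i], phi, 0, 0, [], [], [], [], 1.0, 1.0, -1)
    return out


def forest_shap_values(forest, X) -> np.ndarray:
    """Mean of the per-tree SHAP values of a random-forest regressor."""
    X = np.asarray(X, dtype=float)
    out = np.zeros((X.shape[0], X.shape[1]))
    for est in forest.estimators_:
        out += tree_shap_values(est, X)
    out /= len(forest.estimators_)
    return out


def sampling_shap_values(predict, X, background, n_permutations: int = 64,
                         seed: int = 0):
    """Permutation-sampling Shapley estimates for an arbitrary regressor.

    Parameters
    ----------
    predict
        Callable mapping an (m, p) array to m predictions.
    X
        Samples to explain, shape (n, p).
    background
        Reference data whose feature values stand in for "absent" features.
    n_permutations
        Seeded Monte-Carlo draws per explained sample.

    Returns
    -------
    (phi, base) where ``phi`` is (n, p) and ``base`` is the per-sample mean
    background prediction; ``phi.sum(axis=1) == predict(X) - base`` exactly.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = np.zeros(n)
    for i in range(n):
        x = X[i]
        # build all intermediate coalition vectors, one block per permutation
        blocks = np.empty((n_permutations, p + 1, p))
        perms = np.empty((n_permutations, p), dtype=int)
        for m in range(n_permutations):
            b = background[rng.integers(len(background))]
            perm = rng.permutation(p)
            perms[m] = perm
            z = b.copy()
            blocks[m, 0] = z
            for step, j in enumerate(perm, start=1):
                z = z.copy()
                z[j] = x[j]
                blocks[m, step] = z
        preds = predict(blocks.reshape(-1, p)).reshape(n_permutations, p + 1)
        base[i] = preds[:, 0].mean()
        deltas = np.diff(preds, axis=1)  # contribution of the step-th added feature
        for m in range(n_permutations):
            phi[i, perms[m]] += deltas[m]
        phi[i] /= n_permutations
    return phi, base
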