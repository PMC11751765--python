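"""Exact SHAP values for scikit-learn tree ensembles.

Implements the polynomial-time, path-dependent tree-SHAP algorithm: for every
sample the recursion keeps track of the proportion of feature-subset
permutations that flow down each tree path, weighting branches by the
training-sample fractions stored in the fitted trees.  The resulting
per-feature contributions are exact Shapley values with respect to the tree's
own conditional-expectation function, and satisfy additivity per row:
``base_value + sum(contributions) == prediction``.

The heavy recursion is compiled with numba; the public entry point is
:func:`forest_shap_values`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_shap_values", "tree_shap_values"]


@njit(cache=True, fastmath=True)
def _extend(path, o, u, pz, po, pi):
    # Append one split (zero/one fractions pz/po for feature pi) to the
    # permutation-weight path rooted at offset o with u existing elements.
    path[o + u, 0] = pi
    path[o + u, 1] = pz
    path[o + u, 2] = po
    path[o + u, 3] = 1.0 if u == 0 else 0.0
    for i in range(u - 1, -1, -1):
        path[o + i + 1, 3] += po * path[o + i, 3] * (i + 1.0) / (u + 1.0)
        path[o + i, 3] = pz * path[o + i, 3] * (u - i) / (u + 1.0)


@njit(cache=True, fastmath=True)
def _unwind(path, o, u, k):
    # Remove element k, inverting _extend, and shift the tail down.
    one = path[o + k, 2]
    zero = path[o + k, 1]
    nxt = path[o + u, 3]
    if one != 0.0:
        for i in range(u - 1, -1, -1):
            tmp = path[o + i, 3]
            path[o + i, 3] = nxt * (u + 1.0) / ((i + 1.0) * one)
            nxt = tmp - path[o + i, 3] * zero * (u - i) / (u + 1.0)
    else:
        for i in range(u - 1, -1, -1):
            path[o + i, 3] = path[o + i, 3] * (u + 1.0) / (zero * (u - i))
    for i in range(k, u):
        path[o + i, 0] = path[o + i + 1, 0]
        path[o + i, 1] = path[o + i + 1, 1]
        path[o + i, 2] = path[o + i + 1, 2]


@njit(cache=True, fastmath=True)
def _unwound_sum(path, o, u, k):
    # Total permutation weight of the path with element k removed,
    # without mutating the path.
    one = path[o + k, 2]
    zero = path[o + k, 1]
    nxt = path[o + u, 3]
    total = 0.0
    if one != 0.0:
        for i in range(u - 1, -1, -1):
            tmp = nxt * (u + 1.0) / ((i + 1.0) * one)
            total += tmp
            nxt = path[o + i, 3] - tmp * zero * (u - i) / (u + 1.0)
    else:
        for i in range(u - 1, -1, -1):
            total += path[o + i, 3] * (u + 1.0) / (zero * (u - i))
    return total


@njit(cache=True, fastmath=True)
def _shap_one(x, cl, cr, feat, thr, w, leafval, phi, path, stack):
    # Iterative depth-first traversal; stack rows hold
    # (node, entry_depth, parent_path_offset, zero_fraction, one_fraction,
    #  parent_feature).
    stack[0, 0] = 0.0
    stack[0, 1] = 0.0
    stack[0, 2] = -1.0
    stack[0, 3] = 1.0
    stack[0, 4] = 1.0
    stack[0, 5] = -1.0
    ns = 1
    while ns > 0:
        ns -= 1
        node = int(stack[ns, 0])
        u = int(stack[ns, 1])
        poff = int(stack[ns, 2])
        pz = stack[ns, 3]
        po = stack[ns, 4]
        pi = int(stack[ns, 5])
        if poff < 0:
            off = 0
        else:
            off = poff + u + 1
            for i in range(u):
                path[off + i, 0] = path[poff + i, 0]
                path[off + i, 1] = path[poff + i, 1]
                path[off + i, 2] = path[poff + i, 2]
                path[off + i, 3] = path[poff + i, 3]
        _extend(path, off, u, pz, po, float(pi))
        if cl[node] < 0:
            for i in range(1, u + 1):
                s = _unwound_sum(path, off, u, i)
                phi[int(path[off + i, 0])] += (
                    s * (path[off + i, 2] - path[off + i, 1]) * leafval[node]
                )
        else:
            f = feat[node]
            if x[f] <= thr[node]:
                hot, cold = cl[node], cr[node]
            else:
                hot, cold = cr[node], cl[node]
            iz = 1.0
            io = 1.0
            uu = u
            for k in range(u + 1):
                if int(path[off + k, 0]) == f:
                    iz = path[off + k, 1]
                    io = path[off + k, 2]
                    _unwind(path, off, u, k)
                    uu = u - 1
                    break
            hzf = w[hot] / w[node]
            czf = w[cold] / w[node]
            stack[ns, 0] = cold
            stack[ns, 1] = uu + 1.0
            stack[ns, 2] = off
            stack[ns, 3] = czf * iz
            stack[ns, 4] = 0.0
            stack[ns, 5] = f
            ns += 1
            stack[ns, 0] = hot
            stack[ns, 1] = uu + 1.0
            stack[ns, 2] = off
            stack[ns, 3] = hzf * iz
            stack[ns, 4] = io
            stack[ns, 5] = f
            ns += 1


@njit(cache=True, fastmath=True)
def _shap_all(X, cl, cr, feat, thr, w, leafval, maxdepth):
    n, p = X.shape
    phi = np.zeros((n, p))
    cap = (maxdepth + 4) * (maxdepth + 5) // 2 + 8
    path = np.zeros((cap, 4))
    stack = np.zeros((2 * maxdepth + 12, 6))
    for i in range(n):
        _shap_one(X[i], cl, cr, feat, thr, w, leafval, phi[i], path, stack)
    return phi


def tree_shap_values(tree, X):
    """SHAP values of a single fitted ``sklearn.tree._tree.Tree``.

    Returns ``(phi, base)`` where ``phi`` has shape ``(n_samples,
    n_features)`` and ``base`` is the training-weighted mean prediction.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = _shap_all(
        X,
        tree.children_left,
        tree.children_right,
        tree.feature,
        tree.threshold,
        tree.weighted_n_node_samples,
        np.ascontiguousarray(tree.value[:, 0, 0]),
        max(int(tree.max_depth), 1),
    )
    return phi, float(tree.value[0, 0, 0])


def forest_shap_values(model, X):
    """Exact SHAP decomposition of a fitted random-forest regressor.

    Parameters
    ----------
    model : fitted ``RandomForestRegressor`` (or any bagged ensemble whose
        members expose ``tree_``).
    X : array-like, shape (n_samples, n_features)

    Returns
    -------
    phi : ndarray, shape (n_samples, n_features)
        Per-row, per-feature contributions in target units.
    base : float
        Expected model output; ``base + phi.sum(1)`` equals the forest
        prediction row by row.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros(X.shape, dtype=np.float64)
    base = 0.0
    for est in model.estimators_:
        p, b = tree_shap_values(est.tree_, X)
        phi += p
        base += b
    m = len(model.estimators_)
    return phi / m, base / m
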