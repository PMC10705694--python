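"""Path-dependent TreeSHAP for sklearn tree ensembles.

Computes exact Shapley attributions for regression forests under the
path-dependent (tree-traversal / cover-weighted) value function: the
conditional expectation E[f(x) | x_S] follows a tree's split when the split
feature is in S and otherwise averages the children weighted by their
training cover. Attributions for one tree are obtained in O(L * D^2) by
maintaining, along a depth-first traversal, the polynomial of subset-size
weights for each unique feature on the current path (the EXTEND / UNWIND
bookkeeping of the original TreeSHAP algorithm), rather than enumerating
the 2^p feature subsets.

Interaction values use the conditional form of the same traversal: for a
feature j, attributions are recomputed with j forced "known" (its splits
follow x) and forced "unknown" (its splits cover-average), and

    interaction[i, j] = (phi_i | j known  -  phi_i | j unknown) / 2,  i != j
    interaction[i, i] = phi_i - sum_{j != i} interaction[i, j]

which yields a symmetric matrix whose rows sum to the SHAP values.

Kernels are numba-compiled; the traversal is iterative (explicit stack) so
no recursion support is needed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ForestArrays", "unpack_forest", "shap_values_arrays", "shap_interactions_arrays"]


# --------------------------------------------------------------------------
# path bookkeeping (one row of the 2-d buffers per traversal level)
# --------------------------------------------------------------------------
@njit(cache=True)
def _extend(pf, pz, po, pw, row, m, pz0, po0, pf0):
    pf[row, m] = pf0
    pz[row, m] = pz0
    po[row, m] = po0
    pw[row, m] = 1.0 if m == 0 else 0.0
    for i in range(m - 1, -1, -1):
        pw[row, i + 1] += po0 * pw[row, i] * (i + 1.0) / (m + 1.0)
        pw[row, i] = pz0 * pw[row, i] * (m - i) / (m + 1.0)


@njit(cache=True)
def _unwind(pf, pz, po, pw, row, ud, k):
    one = po[row, k]
    zero = pz[row, k]
    nxt = pw[row, ud]
    for i in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = pw[row, i]
            pw[row, i] = nxt * (ud + 1.0) / ((i + 1.0) * one)
            nxt = tmp - pw[row, i] * zero * (ud - i) / (ud + 1.0)
        else:
            pw[row, i] = pw[row, i] * (ud + 1.0) / (zero * (ud - i))
    for i in range(k, ud):
        pf[row, i] = pf[row, i + 1]
        pz[row, i] = pz[row, i + 1]
        po[row, i] = po[row, i + 1]


@njit(cache=True)
def _unwound_sum(pf, pz, po, pw, row, ud, k):
    one = po[row, k]
    zero = pz[row, k]
    nxt = pw[row, ud]
    total = 0.0
    for i in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (ud + 1.0) / ((i + 1.0) * one)
            total += tmp
            nxt = pw[row, i] - tmp * zero * (ud - i) / (ud + 1.0)
        else:
            total += pw[row, i] * (ud + 1.0) / (zero * (ud - i))
    return total


# --------------------------------------------------------------------------
# single-tree traversal
# --------------------------------------------------------------------------
@njit(cache=True)
def _tree_shap(cl, cr, feat, thr, val, cover, x, phi, condition, cond_feat, scale, max_levels):
    # per-level path buffers
    pf = np.empty((max_levels, max_levels), dtype=np.int64)
    pz = np.empty((max_levels, max_levels), dtype=np.float64)
    po = np.empty((max_levels, max_levels), dtype=np.float64)
    pw = np.empty((max_levels, max_levels), dtype=np.float64)

    cap = 4 * max_levels + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_level = np.empty(cap, dtype=np.int64)
    st_plen = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pf = np.empty(cap, dtype=np.int64)
    st_cf = np.empty(cap, dtype=np.float64)

    top = 0
    st_node[top] = 0
    st_level[top] = 1
    st_plen[top] = 0
    st_pz[top] = 1.0
    st_po[top] = 1.0
    st_pf[top] = -1
    st_cf[top] = 1.0
    top += 1

    while top > 0:
        top -= 1
        node = st_node[top]
        level = st_level[top]
        plen = st_plen[top]
        pz0 = st_pz[top]
        po0 = st_po[top]
        pf0 = st_pf[top]
        cf = st_cf[top]
        if cf == 0.0:
            continue

        row = level
        for i in range(plen):
            pf[row, i] = pf[row - 1, i]
            pz[row, i] = pz[row - 1, i]
            po[row, i] = po[row - 1, i]
            pw[row, i] = pw[row - 1, i]
        m = plen
        if condition == 0 or pf0 != cond_feat:
            _extend(pf, pz, po, pw, row, m, pz0, po0, pf0)
            m += 1

        if cl[node] < 0:  # leaf
            for i in range(1, m):
                w = _unwound_sum(pf, pz, po, pw, row, m - 1, i)
                phi[pf[row, i]] += w * (po[row, i] - pz[row, i]) * val[node] * cf * scale
            continue

        f = feat[node]
        if x[f] <= thr[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(m):
            if pf[row, i] == f:
                k = i
                break
        if k >= 0:
            iz = pz[row, k]
            io = po[row, k]
            _unwind(pf, pz, po, pw, row, m - 1, k)
            m -= 1
        hz = cover[hot] / cover[node]
        cz = cover[cold] / cover[node]

        if condition != 0 and f == cond_feat:
            if condition > 0:
                st_node[top] = hot
                st_level[top] = level + 1
                st_plen[top] = m
                st_pz[top] = 1.0
                st_po[top] = 1.0
                st_pf[top] = f
                st_cf[top] = cf
                top += 1
            else:
                st_node[top] = hot
                st_level[top] = level + 1
                st_plen[top] = m
                st_pz[top] = 1.0
                st_po[top] = 1.0
                st_pf[top] = f
                st_cf[top] = cf * hz
                top += 1
                st_node[top] = cold
                st_level[top] = level + 1
                st_plen[top] = m
                st_pz[top] = 1.0
                st_po[top] = 1.0
                st_pf[top] = f
                st_cf[top] = cf * cz
                top += 1
        else:
            st_node[top] = hot
            st_level[top] = level + 1
            st_plen[top] = m
            st_pz[top] = iz * hz
            st_po[top] = io
            st_pf[top] = f
            st_cf[top] = cf
            top += 1
            st_node[top] = cold
            st_level[top] = level + 1
            st_plen[top] = m
            st_pz[top] = iz * cz
            st_po[top] = 0.0
            st_pf[top] = f
            st_cf[top] = cf
            top += 1


@njit(cache=True)
def _forest_shap(offsets, cl, cr, feat, thr, val, cover, depths, X, phi, condition, cond_feat):
    n_trees = offsets.shape[0] - 1
    scale = 1.0 / n_trees
    for t in range(n_trees):
        a, b = offsets[t], offsets[t + 1]
        levels = depths[t] + 3
        for i in range(X.shape[0]):
            _tree_shap(
                cl[a:b], cr[a:b], feat[a:b], thr[a:b], val[a:b], cover[a:b],
                X[i], phi[i], condition, cond_feat, scale, levels,
            )


@njit(cache=True)
def _forest_interactions(offsets, cl, cr, feat, thr, val, cover, depths, used, X, inter):
    """Accumulate off-diagonal interaction entries; diagonal fixed by caller."""
    n_trees = offsets.shape[0] - 1
    p = X.shape[1]
    scale = 1.0 / n_trees
    phi_on = np.empty(p, dtype=np.float64)
    phi_off = np.empty(p, dtype=np.float64)
    for t in range(n_trees):
        a, b = offsets[t], offsets[t + 1]
        levels = depths[t] + 3
        for j in range(p):
            if not used[t, j]:
                continue
            for i in range(X.shape[0]):
                phi_on[:] = 0.0
                phi_off[:] = 0.0
                _tree_shap(cl[a:b], cr[a:b], feat[a:b], thr[a:b], val[a:b], cover[a:b],
                           X[i], phi_on, 1, j, scale, levels)
                _tree_shap(cl[a:b], cr[a:b], feat[a:b], thr[a:b], val[a:b], cover[a:b],
                           X[i], phi_off, -1, j, scale, levels)
                for k in range(p):
                    if k != j:
                        inter[i, k, j] += 0.5 * (phi_on[k] - phi_off[k])


# --------------------------------------------------------------------------
# forest packing and public entry points
# --------------------------------------------------------------------------
class ForestArrays:
    """Flat array view of a fitted sklearn forest for the numba kernels."""

    def __init__(self, model):
        if not hasattr(model, "estimators_"):
            raise TypeError(f"{type(model).__name__} is not a fitted tree ensemble")
        trees = [est.tree_ for est in model.estimators_]
        self.offsets = np.cumsum([0] + [t.node_count for t in trees]).astype(np.int64)
        self.cl = np.concatenate([t.children_left for t in trees]).astype(np.int64)
        self.cr = np.concatenate([t.children_right for t in trees]).astype(np.int64)
        self.feat = np.concatenate([t.feature for t in trees]).astype(np.int64)
        self.thr = np.concatenate([t.threshold for t in trees]).astype(np.float64)
        self.val = np.concatenate([t.value.reshape(-1) for t in trees]).astype(np.float64)
        self.cover = np.concatenate(
            [t.weighted_n_node_samples for t in trees]
        ).astype(np.float64)
        self.depths = np.array([int(t.max_depth) for t in trees], dtype=np.int64)
        self.n_features = int(model.n_features_in_)
        # which features each tree actually splits on
        self.used = np.zeros((len(trees), self.n_features), dtype=np.bool_)
        for t_i, t in enumerate(trees):
            f = t.feature[t.feature >= 0]
            self.used[t_i, np.unique(f)] = True

    @property
    def baseline(self) -> float:
        """Cover-weighted expected prediction of the ensemble."""
        n_trees = len(self.depths)
        total = 0.0
        for t in range(n_trees):
            a, b = self.offsets[t], self.offsets[t + 1]
            leaves = self.cl[a:b] < 0
            total += float(
                np.sum(self.val[a:b][leaves] * self.cover[a:b][leaves]) / self.cover[a]
            )
        return total / n_trees


def unpack_forest(model) -> ForestArrays:
    return ForestArrays(model)


def shap_values_arrays(forest: ForestArrays, X: np.ndarray) -> np.ndarray:
    """(n, p) SHAP values; rows sum to prediction minus ``forest.baseline``."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], forest.n_features), dtype=np.float64)
    _forest_shap(
        forest.offsets, forest.cl, forest.cr, forest.feat, forest.thr,
        forest.val, forest.cover, forest.depths, X, phi, 0, -1,
    )
    return phi


def shap_interactions_arrays(
    forest: ForestArrays, X: np.ndarray, phi: np.ndarray | None = None
) -> np.ndarray:
    """(n, p, p) symmetric SHAP interaction matrices (rows sum to phi)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if phi is None:
        phi = shap_values_arrays(forest, X)
    inter = np.zeros((X.shape[0], forest.n_features, forest.n_features), dtype=np.float64)
    _forest_interactions(
        forest.offsets, forest.cl, forest.cr, forest.feat, forest.thr,
        forest.val, forest.cover, forest.depths, forest.used, X, inter,
    )
    for i in range(X.shape[0]):
        np.fill_diagonal(inter[i], 0.0)
        np.fill_diagonal(inter[i], phi[i] - inter[i].sum(axis=1))
    return inter
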