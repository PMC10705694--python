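"""Independent brute-force / closed-form oracles used by the tests.

Everything here is deliberately naive (enumeration, closed forms, direct
formula transcriptions) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Shapley values under the path-dependent (cover-weighted) value function
# ---------------------------------------------------------------------------
def tree_cond_exp(tree, x, S, node=0):
    """E[f(x) | x_S] for one sklearn tree: follow splits in S, cover-average
    the rest."""
    if tree.children_left[node] < 0:
        return tree.value[node, 0, 0]
    f = tree.feature[node]
    left, right = tree.children_left[node], tree.children_right[node]
    if f in S:
        nxt = left if x[f] <= tree.threshold[node] else right
        return tree_cond_exp(tree, x, S, nxt)
    wl = tree.weighted_n_node_samples[left] / tree.weighted_n_node_samples[node]
    wr = tree.weighted_n_node_samples[right] / tree.weighted_n_node_samples[node]
    return wl * tree_cond_exp(tree, x, S, left) + wr * tree_cond_exp(tree, x, S, right)


def forest_value(model, x, S):
    return float(np.mean([tree_cond_exp(est.tree_, x, S) for est in model.estimators_]))


def exact_shap(model, x, p):
    """Shapley values by summation over all 2^(p-1) subsets per feature."""
    phi = np.zeros(p)
    for i in range(p):
        rest = [f for f in range(p) if f != i]
        for k in range(p):
            for S in itertools.combinations(rest, k):
                w = math.factorial(k) * math.factorial(p - k - 1) / math.factorial(p)
                phi[i] += w * (forest_value(model, x, set(S) | {i}) - forest_value(model, x, set(S)))
    return phi


def exact_interactions(model, x, p):
    """Shapley interaction values by subset-pair enumeration; diagonal is the
    residual main effect so rows sum to the Shapley values."""
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            rest = [f for f in range(p) if f not in (i, j)]
            for k in range(p - 1):
                for S in itertools.combinations(rest, k):
                    w = (
                        math.factorial(k)
                        * math.factorial(p - k - 2)
                        / (2 * math.factorial(p - 1))
                    )
                    S = set(S)
                    delta = (
                        forest_value(model, x, S | {i, j})
                        - forest_value(model, x, S | {i})
                        - forest_value(model, x, S | {j})
                        + forest_value(model, x, S)
                    )
                    out[i, j] += w * delta
    phi = exact_shap(model, x, p)
    for i in range(p):
        out[i, i] = phi[i] - (out[i].sum() - out[i, i])
    return out


# ---------------------------------------------------------------------------
# classical statistics, written straight from the formulas
# ---------------------------------------------------------------------------
def welch_t_one_sided(a, b):
    """Welch statistic and one-sided (less) p via the Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, stats.t.cdf(t, df)


def pooled_cohens_d(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    sp = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    return abs(b.mean() - a.mean()) / sp


def bh_stepup(pvals):
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return np.minimum(q, 1.0)


def sum_sq_r2(y, yhat):
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    return 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)


def nzv_brute(table, freq_cut=19.0, exempt=()):
    """Near-zero-variance decision by explicit frequency counting."""
    keep = []
    for col in table.columns:
        if col in exempt:
            keep.append(col)
            continue
        freq: dict = {}
        for v in table[col]:
            key = ("nan",) if v != v else v
            freq[key] = freq.get(key, 0) + 1
        counts = sorted(freq.values(), reverse=True)
        if len(counts) < 2:
            continue
        if counts[0] / counts[1] > freq_cut:
            continue
        keep.append(col)
    return keep


def select_brute(importances, names, fraction=0.70, n_filter=None):
    """Reference re-implementation of the retention rule (treatment handled
    by the caller)."""
    p = len(names)
    cap = math.ceil(fraction * p)
    if n_filter is None:
        k = min(sum(1 for v in importances if v > 0), cap)
        if k == 0:
            k = cap
    else:
        k = min(n_filter, p)
    ranked = sorted(range(p), key=lambda i: (-importances[i], i))
    return [names[i] for i in ranked[:k]]


def greedy_match_brute(logits_small, logits_large, order, max_dist=np.inf):
    """Greedy 1:1 nearest neighbor without replacement, literal transcription."""
    taken = set()
    pairs = []
    for i in order:
        best, best_d = None, max_dist
        for j in range(len(logits_large)):
            if j in taken:
                continue
            d = abs(logits_large[j] - logits_small[i])
            if d <= best_d:
                if d < best_d or best is None:
                    best, best_d = j, d
        if best is not None:
            taken.add(best)
            pairs.append((i, best))
    return pairs
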