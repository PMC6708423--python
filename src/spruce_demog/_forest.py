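"""Numba bagged classification-tree ensemble (CART, Gini splits).

Small hand-rolled random forest used by the origin-assignment procedure:
per-tree bootstrap resampling, exhaustive threshold search over a random
subset of features at each node, majority vote across trees.  Feature
counts here are tiny (five principal components), so exact split search is
cheap.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def build_forest(X, y, n_classes, n_trees, mtry, seed):
    """Fit a bagged forest; returns (feature, thresh, left, right, pred) arrays.

    Each row t describes tree t in parallel arrays; pred >= 0 marks leaves.
    """
    n, f = X.shape
    max_nodes = 2 * n + 1
    feature = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    thresh = np.zeros((n_trees, max_nodes), dtype=np.float64)
    left = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    right = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    pred = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    np.random.seed(seed)
    idx = np.zeros(n, dtype=np.int32)
    tmp = np.zeros(n, dtype=np.int32)
    stack_node = np.zeros(max_nodes, dtype=np.int32)
    stack_lo = np.zeros(max_nodes, dtype=np.int32)
    stack_hi = np.zeros(max_nodes, dtype=np.int32)
    feats = np.zeros(f, dtype=np.int32)
    for t in range(n_trees):
        for i in range(n):
            idx[i] = int(np.random.random() * n)
        n_nodes = 1
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            m = hi - lo
            counts = np.zeros(n_classes, dtype=np.int64)
            for i in range(lo, hi):
                counts[y[idx[i]]] += 1
            best_c = 0
            for c in range(1, n_classes):
                if counts[c] > counts[best_c]:
                    best_c = c
            if counts[best_c] == m or m < 2 or n_nodes + 2 > max_nodes:
                pred[t, node] = best_c
                continue
            # random feature subset (partial Fisher-Yates)
            for j in range(f):
                feats[j] = j
            for j in range(min(mtry, f)):
                r = j + int(np.random.random() * (f - j))
                fj = feats[j]
                feats[j] = feats[r]
                feats[r] = fj
            best_score = -1.0
            best_feat = -1
            best_thr = 0.0
            for jj in range(min(mtry, f)):
                ft = feats[jj]
                vals = np.empty(m, dtype=np.float64)
                for i in range(m):
                    vals[i] = X[idx[lo + i], ft]
                order = np.argsort(vals)
                cl = np.zeros(n_classes, dtype=np.int64)
                cr = counts.copy()
                sl = 0.0
                sr = 0.0
                for c in range(n_classes):
                    sr += cr[c] * cr[c]
                for i in range(m - 1):
                    yy = y[idx[lo + order[i]]]
                    sl += 2.0 * cl[yy] + 1.0
                    cl[yy] += 1
                    sr -= 2.0 * cr[yy] - 1.0
                    cr[yy] -= 1
                    vi = vals[order[i]]
                    vn = vals[order[i + 1]]
                    if vn <= vi:
                        continue
                    nl = i + 1.0
                    nr = m - nl
                    score = sl / nl + sr / nr  # maximizing this minimizes weighted Gini
                    if score > best_score:
                        best_score = score
                        best_feat = ft
                        best_thr = 0.5 * (vi + vn)
            if best_feat < 0:
                pred[t, node] = best_c
                continue
            # stable partition of idx[lo:hi] on the chosen split
            nl = 0
            for i in range(lo, hi):
                if X[idx[i], best_feat] <= best_thr:
                    tmp[nl] = idx[i]
                    nl += 1
            nr = nl
            for i in range(lo, hi):
                if X[idx[i], best_feat] > best_thr:
                    tmp[nr] = idx[i]
                    nr += 1
            for i in range(m):
                idx[lo + i] = tmp[i]
            feature[t, node] = best_feat
            thresh[t, node] = best_thr
            lchild = n_nodes
            rchild = n_nodes + 1
            n_nodes += 2
            left[t, node] = lchild
            right[t, node] = rchild
            stack_node[sp] = lchild
            stack_lo[sp] = lo
            stack_hi[sp] = lo + nl
            sp += 1
            stack_node[sp] = rchild
            stack_lo[sp] = lo + nl
            stack_hi[sp] = hi
            sp += 1
    return feature, thresh, left, right, pred


@njit(cache=False)
def forest_votes(Xq, feature, thresh, left, right, pred, n_classes):
    """Per-query per-class vote counts across trees."""
    nq = Xq.shape[0]
    n_trees = feature.shape[0]
    votes = np.zeros((nq, n_classes), dtype=np.int64)
    for q in range(nq):
        for t in range(n_trees):
            node = 0
            while pred[t, node] < 0:
                if Xq[q, feature[t, node]] <= thresh[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            votes[q, pred[t, node]] += 1
    return votes
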