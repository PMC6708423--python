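"""Admixture screening and geographic-origin assignment.

Two families of tools:

* population-level admixture evidence — the f3 statistic
  E[(c−a)(c−b)] with a block jackknife over consecutive SNP blocks
  (significantly negative ⇒ the target is admixed), and a drift-covariance
  tree (NJ on allele-frequency drift distances, branch lengths refit by
  least squares, residual variance explained);
* individual-level origin assignment — smartpca-convention PCA scores feed
  a bagged classification-tree ensemble; repeated bootstrap retraining
  yields a per-individual assignment confidence, and stratified k-fold
  cross-validation estimates the misassignment rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import _forest
from .genotypes import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# Population allele frequencies
# ---------------------------------------------------------------------------

def pop_allele_freqs(G: GenotypeMatrix, groups: dict) -> pd.DataFrame:
    """Per-population allele frequency table.

    ``groups`` maps label → sample indices.  Returns a DataFrame indexed by
    site with columns ``(pop, field)`` for fields p (alt frequency), n
    (called allele copies) and h (finite-sample heterozygosity
    p(1−p)·n/(n−1)).  Sites where a population has no calls get NaN there.
    """
    if not groups:
        raise ValueError("no populations given")
    cols = {}
    for label, samples in groups.items():
        samples = np.asarray(samples, dtype=np.intp)
        if samples.size == 0:
            raise ValueError(f"population {label!r} is empty")
        sub = G.calls[samples]
        called = sub != MISSING
        n = 2.0 * called.sum(axis=0)
        k = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, k / n, np.nan)
            h = np.where(n > 1, p * (1 - p) * n / (n - 1), np.nan)
        cols[(label, "p")] = p
        cols[(label, "n")] = n
        cols[(label, "h")] = h
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# f3 admixture test
# ---------------------------------------------------------------------------

@dataclass
class F3Result:
    target: str
    source1: str
    source2: str
    f3: float
    se: float
    z: float
    n_blocks: int
    block_size: int
    n_sites: int
    significant_negative: bool
    degenerate: bool = False  # target coincides with a source; sign uninformative

    def __repr__(self):
        return (f"F3Result(f3({self.target}; {self.source1}, {self.source2}) = "
                f"{self.f3:.5g}, Z = {self.z:.2f})")


def f3_test(
    freqs: pd.DataFrame,
    target: str,
    source1: str,
    source2: str,
    block_size: int = 100,
    z_threshold: float = 3.0,
) -> F3Result:
    """f3(target; source1, source2) with delete-one-block jackknife SE.

    Per site: (c−a)(c−b) − h_c/n_c, the target's finite-sample
    heterozygosity correction; averaged over usable sites.  Blocks are
    ``block_size`` consecutive usable SNPs.  A significantly negative value
    (Z < −z_threshold) indicates the target is admixed between the sources.
    """
    c = freqs[(target, "p")].to_numpy()
    a = freqs[(source1, "p")].to_numpy()
    b = freqs[(source2, "p")].to_numpy()
    hc = freqs[(target, "h")].to_numpy()
    nc = freqs[(target, "n")].to_numpy()
    use = ~(np.isnan(c) | np.isnan(a) | np.isnan(b) | np.isnan(hc)) & (nc >= 2)
    stat = (c[use] - a[use]) * (c[use] - b[use]) - hc[use] / nc[use]
    n_sites = stat.size
    n_blocks = n_sites // block_size
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks of usable sites")
    trimmed = stat[: n_blocks * block_size].reshape(n_blocks, block_size)
    total = trimmed.sum()
    m = n_blocks * block_size
    loo = (total - trimmed.sum(axis=1)) / (m - block_size)  # leave-one-block-out means
    f3 = float(trimmed.mean())
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    z = f3 / se if se > 0 else math.inf * np.sign(f3)
    # a target identical to one source drives (c-a)(c-b) to 0 and leaves only
    # the (negative) sampling correction: flag rather than report as admixture
    degenerate = (target in (source1, source2)
                  or np.allclose(c[use], a[use]) or np.allclose(c[use], b[use]))
    return F3Result(
        target, source1, source2, f3, se, float(z),
        n_blocks, block_size, n_sites, bool(z < -z_threshold) and not degenerate,
        degenerate,
    )


# ---------------------------------------------------------------------------
# Drift-covariance tree
# ---------------------------------------------------------------------------

def covariance_tree(freqs: pd.DataFrame, pops: list, outgroup: str):
    """NJ drift tree plus least-squares branch refit and residuals.

    Drift distances d_ij = E[(p_i−p_j)²]/(p̄(1−p̄)) (p̄ the across-pop mean
    frequency per site) feed neighbor joining; the tree is rooted at the
    outgroup's attachment node.  Branch lengths are then refit by
    non-negative least squares to the outgroup-referenced covariance
    W_ij = E[(p_i−p_out)(p_j−p_out)]/(p̄(1−p̄)) over non-outgroup
    populations, whose tree expectation is the shared branch length on the
    root paths of i and j (plus the outgroup stem).  Returns
    (newick string, residual DataFrame, variance_explained).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(pops) < 3:
        raise ValueError("need at least 3 populations")
    if outgroup not in pops:
        raise ValueError("outgroup must be among pops")
    P = [freqs[(p, "p")].to_numpy() for p in pops]
    use = ~np.any([np.isnan(x) for x in P], axis=0)
    P = np.array([x[use] for x in P])  # pops × sites
    pbar = P.mean(axis=0)
    poly = (pbar > 0) & (pbar < 1)
    P = P[:, poly]
    denom = pbar[poly] * (1 - pbar[poly])
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = float(np.mean((P[i] - P[j]) ** 2 / denom))
    tree = nj(DistanceMatrix(d, ids=list(pops)))
    tree = tree.root_at(tree.find(outgroup).parent)

    # path-to-root edge sets (edges named by their child node id)
    edges = {}
    paths = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node.parent is not None:
            eid = id(node)
            edges.setdefault(eid, max(node.length or 0.0, 0.0))
            path.append(eid)
            node = node.parent
        paths[tip.name] = set(path)
    others = [p for p in pops if p != outgroup]
    out_path = paths[outgroup]
    edge_ids = list(edges)
    col = {e: i for i, e in enumerate(edge_ids)}
    iout = pops.index(outgroup)

    # observed outgroup-referenced covariance
    W = np.zeros((len(others), len(others)))
    for i, pi in enumerate(others):
        for j, pj in enumerate(others):
            ii, jj = pops.index(pi), pops.index(pj)
            W[i, j] = float(np.mean((P[ii] - P[iout]) * (P[jj] - P[iout]) / denom))
    # design: W_ij = sum of edges shared by paths(i), paths(j) relative to the
    # root, plus every edge of the outgroup's own root path
    rows = []
    for i, pi in enumerate(others):
        for j, pj in enumerate(others):
            shared = (paths[pi] & paths[pj]) | out_path
            r = np.zeros(len(edge_ids))
            for e in shared:
                r[col[e]] = 1.0
            rows.append(r)
    A = np.array(rows)
    w_flat = W.ravel()
    lengths, _ = nnls(A, w_flat)
    W_hat = (A @ lengths).reshape(W.shape)
    resid = W - W_hat
    centered = W - W.mean()
    denom_var = float((centered**2).sum())
    var_explained = 1.0 - float((resid**2).sum()) / denom_var if denom_var > 0 else 1.0
    # write refit lengths back into the tree for the newick output
    for node in tree.traverse(include_self=False):
        if id(node) in col:
            node.length = float(lengths[col[id(node)]])
    newick = str(tree).strip()
    resid_df = pd.DataFrame(resid, index=others, columns=others)
    return newick, resid_df, float(var_explained)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(G: GenotypeMatrix, n_components: int = 5, samples=None):
    """Sample scores on the leading principal components (smartpca scaling).

    Dosages are centered by 2p̂ and scaled by √(p̂(1−p̂)); missing dosages
    are mean-imputed (zero after centering).  Deterministic sign: each
    component's largest-|score| coordinate is positive.

    Returns (scores (n_samples, n_components), explained variance fractions).
    """
    samples = np.arange(G.n_samples) if samples is None else np.asarray(samples, dtype=np.intp)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    X = G.calls[samples].astype(np.float64)
    miss = X == MISSING
    X[miss] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic")
    X = X[:, poly]
    p = p[poly]
    X = (X - 2 * p) / np.sqrt(p * (1 - p))
    X[np.isnan(X)] = 0.0  # mean imputation
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(s))
    scores = U[:, :n_components] * s[:n_components]
    for c in range(n_components):
        if scores[np.argmax(np.abs(scores[:, c])), c] < 0:
            scores[:, c] = -scores[:, c]
    explained = (s**2) / (s**2).sum()
    return scores, explained[:n_components]


# ---------------------------------------------------------------------------
# Bagged-tree classifier, assignment, cross-validation
# ---------------------------------------------------------------------------

class BaggedTreeClassifier:
    """Bagged CART ensemble with per-node feature subsampling (⌈√f⌉)."""

    def __init__(self, n_trees: int = 200, seed: int = 0):
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self._arrays = None
        self.classes_: list = []

    def fit(self, X: np.ndarray, y) -> "BaggedTreeClassifier":
        X = np.ascontiguousarray(X, dtype=np.float64)
        self.classes_ = sorted(set(y))
        codes = np.array([self.classes_.index(v) for v in y], dtype=np.int32)
        mtry = int(math.ceil(math.sqrt(X.shape[1])))
        self._arrays = _forest.build_forest(
            X, codes, len(self.classes_), self.n_trees, mtry, self.seed % 2147483647
        )
        return self

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = _forest.forest_votes(X, *self._arrays, len(self.classes_))
        return votes / votes.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        frac = self.vote_fractions(X)
        return np.array([self.classes_[i] for i in frac.argmax(axis=1)])


@dataclass
class AssignmentResult:
    sample: str
    assigned: str
    confidence: float          # modal fraction over repetitions
    votes: dict                # cluster -> fraction of repetitions


def train_and_assign(
    scores_ref: np.ndarray,
    labels_ref,
    scores_unknown: np.ndarray,
    unknown_ids=None,
    R: int = 1000,
    B_trees: int = 200,
    seed: int = 0,
) -> list:
    """Assign unknowns to reference clusters with repetition-frequency confidence.

    Each repetition bootstraps the reference individuals, trains a bagged
    tree ensemble on their PC scores, and classifies the unknowns by
    majority vote; the final call is the modal class over ``R`` repetitions
    and the confidence its modal fraction.
    """
    labels_ref = list(labels_ref)
    classes = sorted(set(labels_ref))
    if len(classes) < 2:
        raise ValueError("need at least 2 reference classes")
    for cl in classes:
        if labels_ref.count(cl) < 2:
            raise ValueError(f"class {cl!r} has fewer than 2 reference samples")
    if unknown_ids is None:
        unknown_ids = [f"unknown_{i}" for i in range(len(scores_unknown))]
    rng = np.random.default_rng(seed)
    n_ref = len(labels_ref)
    labels_arr = np.array(labels_ref)
    tallies = np.zeros((len(scores_unknown), len(classes)), dtype=np.int64)
    for r in range(R):
        boot = rng.integers(0, n_ref, size=n_ref)
        clf = BaggedTreeClassifier(n_trees=B_trees, seed=int(rng.integers(1 << 31)))
        clf.fit(scores_ref[boot], labels_arr[boot])
        pred = clf.predict(scores_unknown)
        for i, cl in enumerate(pred):
            tallies[i, classes.index(cl)] += 1
    out = []
    for i, sid in enumerate(unknown_ids):
        frac = tallies[i] / tallies[i].sum()
        j = int(frac.argmax())
        out.append(
            AssignmentResult(
                sample=sid,
                assigned=classes[j],
                confidence=float(frac[j]),
                votes={c: float(v) for c, v in zip(classes, frac)},
            )
        )
    return out


def cross_validate(
    scores_ref: np.ndarray,
    labels_ref,
    k: int = 5,
    seed: int = 0,
    B_trees: int = 200,
) -> float:
    """Stratified k-fold cross-validated misassignment rate."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels_ref = np.array(list(labels_ref))
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(labels_ref), dtype=int)
    for cl in np.unique(labels_ref):
        idx = np.flatnonzero(labels_ref == cl)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    wrong = 0
    for fold in range(k):
        test = folds == fold
        clf = BaggedTreeClassifier(n_trees=B_trees, seed=seed + fold)
        clf.fit(scores_ref[~test], labels_ref[~test])
        pred = clf.predict(scores_ref[test])
        wrong += int((pred != labels_ref[test]).sum())
    return wrong / len(labels_ref)
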