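"""Joint site-frequency spectra: polarization, projection, construction,
folding, and dadi-style text I/O.

A :class:`JointSFS` holds a 1- to 3-dimensional array of (possibly
fractional, via hypergeometric projection) site counts indexed by
derived- or minor-allele copy numbers per population, with the two
invariant corners (all-ancestral, all-derived) masked out of likelihood
sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from scipy.stats import hypergeom

from .genotypes import MISSING, GenotypeMatrix

REASON_OK = 0
REASON_OUTGROUP_UNCALLED = 1
REASON_SHARED_POLY = 2
REASON_OUTGROUP_POLY = 3


class JointSFS:
    """Joint SFS over ≤3 populations.

    Parameters
    ----------
    pops
        Ordered population labels, one per axis.
    data
        Array of shape ``(n_1+1, ..., n_d+1)`` where ``n_k`` is the haploid
        sample size on axis ``k``.
    polarity
        ``"derived"`` (outgroup-polarized) or ``"minor"`` (folded).
    mask
        Boolean array, ``True`` = excluded from likelihood sums.  Defaults
        to the two corners; for minor polarity every non-representative
        entry (total minor count > total/2, and the larger of tied pairs)
        is masked as well.
    """

    def __init__(self, pops, data, polarity="derived", mask=None):
        self.pops = tuple(pops)
        self.data = np.asarray(data, dtype=np.float64)
        if self.data.ndim != len(self.pops) or self.data.ndim > 3:
            raise ValueError("data must have one axis per population (<= 3)")
        if (self.data < 0).any():
            raise ValueError("SFS entries must be >= 0")
        if polarity not in ("derived", "minor"):
            raise ValueError("polarity must be 'derived' or 'minor'")
        self.polarity = polarity
        self.n = tuple(s - 1 for s in self.data.shape)
        if mask is None:
            mask = corner_mask(self.data.shape)
            if polarity == "minor":
                mask |= ~_minor_representative(self.data.shape)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape mismatch")

    # -- basics ------------------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.data.ndim

    def total(self) -> float:
        """Sum over unmasked entries."""
        return float(self.data[~self.mask].sum())

    def normalized(self) -> np.ndarray:
        """Probabilities over unmasked entries (masked cells set to 0)."""
        p = np.where(self.mask, 0.0, self.data)
        t = p.sum()
        if t <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return p / t

    def marginalize(self, axes_to_keep) -> "JointSFS":
        """Sum out all axes not listed (raw data summed, corners re-masked)."""
        axes_to_keep = tuple(axes_to_keep)
        drop = tuple(a for a in range(self.ndim) if a not in axes_to_keep)
        data = self.data.sum(axis=drop)
        if sorted(axes_to_keep) != list(axes_to_keep):
            data = np.transpose(data, np.argsort(np.argsort(axes_to_keep)))
        return JointSFS([self.pops[a] for a in axes_to_keep], data, self.polarity)

    def __eq__(self, other):
        return (
            isinstance(other, JointSFS)
            and self.pops == other.pops
            and self.polarity == other.polarity
            and np.allclose(self.data, other.data)
            and np.array_equal(self.mask, other.mask)
        )

    def __repr__(self):
        return f"JointSFS(pops={self.pops}, n={self.n}, polarity={self.polarity})"


def corner_mask(shape) -> np.ndarray:
    """Mask of the all-ancestral and all-derived corners."""
    m = np.zeros(shape, dtype=bool)
    m[(0,) * len(shape)] = True
    m[tuple(s - 1 for s in shape)] = True
    return m


def _minor_representative(shape) -> np.ndarray:
    """True where an entry is the canonical representative of its fold pair."""
    n = tuple(s - 1 for s in shape)
    half = sum(n) / 2.0
    rep = np.zeros(shape, dtype=bool)
    for e in np.ndindex(*shape):
        c = tuple(ni - ei for ni, ei in zip(n, e))
        tot = sum(e)
        if tot < half or (tot == half and e <= c):
            rep[e] = True
    return rep


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

@dataclass
class Polarization:
    """Per-site ancestral/derived assignment from a fixed outgroup."""

    derived_is_alt: np.ndarray  # bool per site (valid only where usable)
    usable: np.ndarray          # bool per site
    reason: np.ndarray          # int8 reason codes (REASON_*)
    fixed_difference: np.ndarray  # target fixed for the derived allele

    def tallies(self) -> dict:
        return {
            "usable": int(self.usable.sum()),
            "outgroup_uncalled": int((self.reason == REASON_OUTGROUP_UNCALLED).sum()),
            "shared_poly": int((self.reason == REASON_SHARED_POLY).sum()),
            "outgroup_poly": int((self.reason == REASON_OUTGROUP_POLY).sum()),
            "fixed_difference": int(self.fixed_difference.sum()),
        }


def _allele_counts(G: GenotypeMatrix, samples) -> tuple[np.ndarray, np.ndarray]:
    sub = G.calls[np.asarray(samples, dtype=np.intp)]
    called = sub != MISSING
    n = 2 * called.sum(axis=0)
    k = np.where(called, sub, 0).sum(axis=0)
    return n, k


def polarize_by_outgroup(G_target: GenotypeMatrix, G_outgroup: GenotypeMatrix) -> Polarization:
    """Assign ancestral/derived alleles using a (nearly) fixed outgroup.

    The ancestral allele is the allele fixed in the outgroup.  Sites where
    the outgroup is entirely uncalled are excluded, as are sites polymorphic
    in the outgroup (shared target/outgroup polymorphism gets its own reason
    code, mirroring the stringency filter of the study).  Sites where target
    and outgroup are fixed for different alleles are usable fixed derived
    differences.
    """
    if [(s.chrom, s.pos) for s in G_target.sites] != [(s.chrom, s.pos) for s in G_outgroup.sites]:
        raise ValueError("target and outgroup matrices must cover identical sites")
    n_o, k_o = _allele_counts(G_outgroup, np.arange(G_outgroup.n_samples))
    n_t, k_t = _allele_counts(G_target, np.arange(G_target.n_samples))
    reason = np.zeros(G_target.n_sites, dtype=np.int8)
    reason[n_o == 0] = REASON_OUTGROUP_UNCALLED
    out_poly = (n_o > 0) & (k_o > 0) & (k_o < n_o)
    tgt_poly = (n_t > 0) & (k_t > 0) & (k_t < n_t)
    reason[out_poly & tgt_poly] = REASON_SHARED_POLY
    reason[out_poly & ~tgt_poly] = REASON_OUTGROUP_POLY
    usable = reason == REASON_OK
    derived_is_alt = k_o == 0  # outgroup fixed ref -> derived is alt
    k_derived = np.where(derived_is_alt, k_t, n_t - k_t)
    fixed_diff = usable & (n_t > 0) & (k_derived == n_t)
    return Polarization(derived_is_alt, usable, reason, fixed_diff)


def split_polarize(G: GenotypeMatrix, target_samples, outgroup_samples) -> Polarization:
    """Polarize using sample subsets of a single matrix."""
    tgt = G.take_samples([G.samples[i] for i in np.asarray(target_samples, dtype=np.intp)])
    out = G.take_samples([G.samples[i] for i in np.asarray(outgroup_samples, dtype=np.intp)])
    return polarize_by_outgroup(tgt, out)


# ---------------------------------------------------------------------------
# Projection and construction
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def _proj_cached(k: int, n_from: int, n_to: int):
    j = np.arange(n_to + 1)
    return hypergeom.pmf(j, n_from, k, n_to)


def project_counts(k: int, n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric down-projection of ``k`` derived copies among ``n_from``
    to a subsample of ``n_to`` copies; weights over 0..n_to summing to 1."""
    if n_to > n_from:
        raise ValueError("cannot project to a larger sample size")
    if not 0 <= k <= n_from:
        raise ValueError("k must be in [0, n_from]")
    return _proj_cached(int(k), int(n_from), int(n_to))


def joint_sfs(
    G: GenotypeMatrix,
    pops: dict,
    n_project: dict | None = None,
    polarity: str = "minor",
    polarization: Polarization | None = None,
):
    """Build a joint SFS over ≤3 populations with hypergeometric projection.

    ``pops`` maps label → sample indices; ``n_project`` maps label → target
    haploid size (default: the 10th percentile of called copies per
    population, so ~90% of sites project without loss).  Each usable site
    contributes total weight 1, distributed by the projection.
    ``polarity='derived'`` requires a :class:`Polarization`; ``'minor'``
    counts alt alleles and folds after accumulation.

    Returns
    -------
    (JointSFS, report dict) with tallies of skipped sites.
    """
    labels = list(pops)
    if not 1 <= len(labels) <= 3:
        raise ValueError("1 to 3 populations required")
    if polarity == "derived" and polarization is None:
        raise ValueError("derived polarity requires a polarization")
    if n_project is None:
        n_project = {}
        for l in labels:
            n, _ = _allele_counts(G, pops[l])
            n_project[l] = max(2, int(np.percentile(n[n > 0], 10)))
    n_to = [int(n_project[l]) for l in labels]
    shape = tuple(nt + 1 for nt in n_to)
    counts = []
    for l in labels:
        n, k = _allele_counts(G, pops[l])
        counts.append((n, k))
    data = np.zeros(shape)
    report = {"used": 0, "insufficient_coverage": 0, "not_polarizable": 0}
    for s in range(G.n_sites):
        if polarization is not None and not polarization.usable[s]:
            report["not_polarizable"] += 1
            continue
        ws = []
        ok = True
        for (n, k), nt in zip(counts, n_to):
            if n[s] < nt:
                ok = False
                break
            kk = int(k[s])
            if polarization is not None and not polarization.derived_is_alt[s]:
                kk = int(n[s]) - kk
            ws.append(project_counts(kk, int(n[s]), nt))
        if not ok:
            report["insufficient_coverage"] += 1
            continue
        w = ws[0]
        for extra in ws[1:]:
            w = np.multiply.outer(w, extra)
        data += w
        report["used"] += 1
    S = JointSFS(labels, data, polarity="derived")
    if polarity == "minor":
        S = fold_sfs(S)
    return S, report


def fold_sfs(S: JointSFS) -> JointSFS:
    """Fold a derived spectrum to minor-allele polarity.

    Each entry and its vectorwise complement are summed into the
    representative with the smaller total count (lexicographic tie-break);
    self-complementary entries are counted once.
    """
    if S.polarity != "derived":
        raise ValueError("spectrum is already folded")
    shape = S.data.shape
    n = S.n
    folded = np.zeros(shape)
    rep = _minor_representative(shape)
    for e in np.ndindex(*shape):
        if not rep[e]:
            continue
        c = tuple(ni - ei for ni, ei in zip(n, e))
        folded[e] = S.data[e] + (S.data[c] if c != e else 0.0)
    mask = corner_mask(shape) | ~rep
    return JointSFS(S.pops, folded, polarity="minor", mask=mask)


# ---------------------------------------------------------------------------
# I/O (dadi-compatible text dialect)
# ---------------------------------------------------------------------------

def write_sfs(S: JointSFS, path) -> None:
    with open(path, "w") as fh:
        shape = " ".join(str(s) for s in S.data.shape)
        fold = "folded" if S.polarity == "minor" else "unfolded"
        labels = " ".join(f'"{p}"' for p in S.pops)
        fh.write(f"{shape} {fold} {labels}\n")
        fh.write(" ".join(repr(float(x)) for x in S.data.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in S.mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    if len(lines) < 3:
        raise ValueError("truncated SFS file")
    head = lines[0].split()
    shape = []
    i = 0
    while i < len(head) and head[i].isdigit():
        shape.append(int(head[i]))
        i += 1
    if i >= len(head) or head[i] not in ("folded", "unfolded"):
        raise ValueError("malformed SFS header")
    polarity = "minor" if head[i] == "folded" else "derived"
    pops = [t.strip('"') for t in head[i + 1:]] or [f"pop{j}" for j in range(len(shape))]
    size = int(np.prod(shape))
    data = np.array(lines[1].split(), dtype=float)
    mask_flat = np.array(lines[2].split(), dtype=int)
    if data.size != size or mask_flat.size != size:
        raise ValueError("SFS shape/count mismatch")
    return JointSFS(pops, data.reshape(shape), polarity, mask_flat.reshape(shape).astype(bool))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def pi_from_sfs(S: JointSFS) -> float:
    """Total pairwise diversity Σ_i ξ_i · 2i(n−i)/(n(n−1)) from a 1D spectrum."""
    if S.ndim != 1:
        raise ValueError("pi_from_sfs needs a 1D spectrum")
    n = S.n[0]
    i = np.arange(n + 1)
    w = 2.0 * i * (n - i) / (n * (n - 1.0))
    data = np.where(S.mask, 0.0, S.data)
    return float((data * w).sum())
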