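"""Within- and between-population summary statistics.

Per-site pairwise diversity (π) overall and by degeneracy class, Tajima's D,
Hudson's F_ST (ratio-of-averages form), composite-LD r² from genotype
dosages, and the LD-pruning rule used before PCA/clustering (drop the later
site of any pair with r² ≥ 0.2 and BH-adjusted p ≤ 0.05).

Notes on conventions
--------------------
π is reported per *variant* site over the supplied SNP panel; absolute
per-bp diversity would need monomorphic-site counts which the genotype
matrix does not carry.  Tajima's D handles missing data by fixing the
constants at the median called allele count across used sites.  F_ST sums
per-site numerator and denominator before dividing (negative per-site
components retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .genotypes import MISSING, GenotypeMatrix, SiteAnnotation


def _counts(G: GenotypeMatrix, sites, samples):
    """Per-site called allele copies n and alt copies k over ``samples``."""
    sub = G.calls[np.asarray(samples, dtype=np.intp)][:, np.asarray(sites, dtype=np.intp)]
    called = sub != MISSING
    n = 2 * called.sum(axis=0)
    k = np.where(called, sub, 0).sum(axis=0)
    return n.astype(np.int64), k.astype(np.int64)


def site_pi(G: GenotypeMatrix, sites=None, samples=None):
    """Per-site heterozygosity π = 2k(n−k)/(n(n−1)) and its mean.

    Sites with fewer than 2 called allele copies are excluded and counted.

    Returns
    -------
    (per_site_pi, mean_pi, n_used, n_excluded)
    """
    sites = np.arange(G.n_sites) if sites is None else np.asarray(sites)
    samples = np.arange(G.n_samples) if samples is None else np.asarray(samples)
    n, k = _counts(G, sites, samples)
    usable = n >= 2
    if not usable.any():
        raise ValueError("no site with >=2 called allele copies")
    n_u, k_u = n[usable], k[usable]
    pi = 2.0 * k_u * (n_u - k_u) / (n_u * (n_u - 1.0))
    return pi, float(pi.mean()), int(usable.sum()), int((~usable).sum())


def pi_by_degeneracy(G: GenotypeMatrix, annot: SiteAnnotation, samples=None,
                     class_sizes: dict | None = None):
    """π at 0-fold and 4-fold sites and their ratio π₀/π₄.

    Without ``class_sizes`` π is the mean over the class's *variant* sites,
    so the ratio compares per-SNP diversity.  When ``class_sizes`` supplies
    the total number of class sites surveyed (the per-bp denominators, e.g.
    the pre-thinning class counts of a simulated panel), π becomes the
    class total divided by that size — the per-site rate the π₀/π₄
    statistic classically uses.  Ratio is ``nan`` (and flagged) when either
    class is unusable or π₄ = 0.
    """
    if len(annot) != G.n_sites:
        raise ValueError("annotation does not cover all sites")
    out = {}
    for key, cls in (("pi0", "zero_fold"), ("pi4", "four_fold")):
        idx = annot.class_indices(cls)
        if idx.size == 0:
            out[key], out["n" + key[-1]] = np.nan, 0
            continue
        try:
            per_site, mean, n_used, _ = site_pi(G, idx, samples)
        except ValueError:
            mean, n_used = np.nan, 0
            per_site = np.array([])
        if class_sizes is not None and key in ("pi0", "pi4"):
            denom = class_sizes.get(cls, None)
            if denom:
                mean = float(per_site.sum()) / denom if per_site.size else np.nan
        out[key], out["n" + key[-1]] = mean, n_used
    if out["n4"] == 0 or out["n0"] == 0 or not out["pi4"] or np.isnan(out["pi4"]) or np.isnan(out["pi0"]):
        out["ratio"] = np.nan
        out["ratio_defined"] = False
    else:
        out["ratio"] = out["pi0"] / out["pi4"]
        out["ratio_defined"] = True
    return out


def _tajima_constants(n: int):
    """Tajima (1989) normalization constants for n haploid sequences."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(G: GenotypeMatrix, sites=None, samples=None) -> float:
    """Tajima's D over the supplied sites.

    Effective sample size for the constants is the *median* called allele
    count across used segregating sites; π is summed from per-site
    complete-case heterozygosity.  Raises ``ValueError`` when there is no
    segregating site (undefined, never silently 0).
    """
    sites = np.arange(G.n_sites) if sites is None else np.asarray(sites)
    samples = np.arange(G.n_samples) if samples is None else np.asarray(samples)
    n, k = _counts(G, sites, samples)
    seg = (n >= 3) & (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        raise ValueError("Tajima's D undefined: no segregating site")
    n_s, k_s = n[seg], k[seg]
    pi_total = float(np.sum(2.0 * k_s * (n_s - k_s) / (n_s * (n_s - 1.0))))
    n_eff = int(np.median(n_s))
    if n_eff < 3:
        raise ValueError("Tajima's D undefined: fewer than 3 called copies")
    a1, e1, e2 = _tajima_constants(n_eff)
    var = e1 * S + e2 * S * (S - 1.0)
    return (pi_total - S / a1) / np.sqrt(var)


def hudson_fst(G: GenotypeMatrix, popA, popB, sites=None) -> float:
    """Hudson's F_ST (Bhatia et al. ratio-of-averages).

    Per site, with sample allele frequencies p̂ and sizes n (allele copies):
    N = (p_A − p_B)² − h_A/n_A − h_B/n_B,  D = p_A(1−p_B) + p_B(1−p_A),
    where h = p̂(1−p̂)·n/(n−1); F_ST = ΣN / ΣD over usable sites.
    """
    sites = np.arange(G.n_sites) if sites is None else np.asarray(sites)
    nA, kA = _counts(G, sites, np.asarray(popA))
    nB, kB = _counts(G, sites, np.asarray(popB))
    use = (nA >= 2) & (nB >= 2)
    nA, kA, nB, kB = nA[use], kA[use], nB[use], kB[use]
    pA, pB = kA / nA, kB / nB
    hA = pA * (1 - pA) * nA / (nA - 1.0)
    hB = pB * (1 - pB) * nB / (nB - 1.0)
    num = (pA - pB) ** 2 - hA / nA - hB / nB
    den = pA * (1 - pB) + pB * (1 - pA)
    usable = den > 0
    if not usable.any():
        raise ValueError("no usable site for F_ST")
    return float(num[usable].sum() / den[usable].sum())


def fst_matrix(G: GenotypeMatrix, groups: dict[str, np.ndarray], sites=None):
    """Symmetric matrix of pairwise Hudson F_ST between sample groups."""
    labels = list(groups)
    F = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            F[i, j] = F[j, i] = hudson_fst(G, groups[labels[i]], groups[labels[j]], sites)
    return labels, F


def ld_r2(G: GenotypeMatrix, site_i: int, site_j: int, samples=None) -> float:
    """Squared Pearson correlation of genotype dosages (composite LD).

    Complete-case samples only; ``nan`` if either site is monomorphic after
    the complete-case restriction.
    """
    samples = np.arange(G.n_samples) if samples is None else np.asarray(samples)
    x = G.calls[samples, site_i].astype(float)
    y = G.calls[samples, site_j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    G: GenotypeMatrix,
    r2_threshold: float = 0.2,
    fdr: float = 0.05,
    window: int = 10_000,
    samples=None,
) -> np.ndarray:
    """Greedy left-to-right LD pruning within a physical window.

    A later site is dropped when, against any retained earlier site within
    ``window`` bp on the same chromosome, r² ≥ ``r2_threshold`` AND its
    Benjamini–Hochberg-adjusted p-value (χ²₁ approximation, n·r²) is ≤
    ``fdr``.  Deterministic given input order.  Returns retained indices.
    """
    if not (0 < r2_threshold <= 1 and 0 < fdr <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    samples = np.arange(G.n_samples) if samples is None else np.asarray(samples)
    n_sites = G.n_sites
    pair_i, pair_j, pair_r2, pair_p = [], [], [], []
    # first pass: collect candidate pairs and raw p-values for BH
    for j in range(n_sites):
        sj = G.sites[j]
        for i in range(j - 1, -1, -1):
            si = G.sites[i]
            if si.chrom != sj.chrom or sj.pos - si.pos > window:
                break
            r2 = ld_r2(G, i, j, samples)
            if np.isnan(r2):
                continue
            ok = (G.calls[samples, i] != MISSING) & (G.calls[samples, j] != MISSING)
            n_cc = int(ok.sum())
            p = float(_stats.chi2.sf(n_cc * r2, df=1))
            pair_i.append(i), pair_j.append(j), pair_r2.append(r2), pair_p.append(p)
    if pair_p:
        q = _bh_adjust(np.array(pair_p))
    else:
        q = np.array([])
    significant = {}
    for i, j, r2, qv in zip(pair_i, pair_j, pair_r2, q):
        if r2 >= r2_threshold and qv <= fdr:
            significant.setdefault(j, []).append(i)
    retained: list[int] = []
    kept = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        partners = significant.get(j, ())
        if any(kept[i] for i in partners):
            continue
        kept[j] = True
        retained.append(j)
    return np.array(retained, dtype=np.intp)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1.0)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class DiversityReport:
    """Table-1-style per-group summary."""

    group: str
    pi_all: float
    pi0: float
    pi4: float
    ratio: float
    tajimas_d_noncoding: float
    tajimas_d_coding: float
    n_sites: dict = field(default_factory=dict)


def diversity_report(
    G: GenotypeMatrix, annot: SiteAnnotation, samples, group: str
) -> DiversityReport:
    """Assemble π (overall / 0-fold / 4-fold), π₀/π₄ and Tajima's D for one group."""
    _, pi_all, n_all, _ = site_pi(G, None, samples)
    by = pi_by_degeneracy(G, annot, samples)
    coding = np.flatnonzero(annot.region == "coding")
    noncoding = np.flatnonzero(annot.region != "coding")

    def _d(idx):
        if idx.size == 0:
            return float("nan")
        try:
            return tajimas_d(G, idx, samples)
        except ValueError:
            return float("nan")

    return DiversityReport(
        group=group,
        pi_all=pi_all,
        pi0=by["pi0"],
        pi4=by["pi4"],
        ratio=by["ratio"],
        tajimas_d_noncoding=_d(noncoding),
        tajimas_d_coding=_d(coding),
        n_sites={"all": n_all, "zero_fold": by["n0"], "four_fold": by["n4"]},
    )
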