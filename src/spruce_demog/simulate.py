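"""Synthetic-data engine: expected/sampled SFS, genotype-level cohorts, and
degeneracy annotation with a purifying-selection thinning proxy.

Sites are unlinked (one independent genealogy per site), matching the fast
within-gene LD decay of the exome panel this emulates.  A single integer
seed governs a whole simulation; per-locus child streams are derived
deterministically from it, so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .demography import DemographicModel
from .genotypes import GenotypeMatrix, PopulationMap, Site, SiteAnnotation
from .sfs import JointSFS


def _compile_for(model: DemographicModel, sample_pops):
    comp = model.compile()
    P = len(model.populations)
    axis_of_pop = np.full(P, -1, dtype=np.int32)
    for ax, pop in enumerate(sample_pops):
        axis_of_pop[model.index(pop)] = ax
    return comp, axis_of_pop


def simulate_sfs(
    model: DemographicModel,
    sample_config: dict,
    n_loci: int,
    mode: str = "branch",
    seed: int = 0,
) -> JointSFS:
    """Simulate a derived-polarity joint SFS under ``model``.

    ``sample_config`` maps population → number of diploids (≤3 populations).
    ``mode='branch'`` accumulates expected branch lengths per entry over
    ``n_loci`` genealogies (normalize for entry probabilities);
    ``mode='mutation'`` drops one infinite-sites mutation per genealogy,
    giving an observed spectrum with exactly ``n_loci`` segregating sites.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    pops = list(sample_config)
    if not 1 <= len(pops) <= 3:
        raise ValueError("1 to 3 sampled populations supported")
    for p in pops:
        if p not in model.names:
            raise ValueError(f"population {p!r} not in model")
    comp, axis_of_pop = _compile_for(model, pops)
    ns = [2 * int(sample_config[p]) for p in pops]
    shape = tuple(n + 1 for n in ns)
    strides = np.array(
        [int(np.prod(shape[a + 1:])) for a in range(len(shape))], dtype=np.int64
    )
    init_pop = np.concatenate(
        [np.full(n, model.index(p), dtype=np.int32) for p, n in zip(pops, ns)]
    )
    kern = _kernel.branch_sfs if mode == "branch" else _kernel.mutation_sfs
    if mode not in ("branch", "mutation"):
        raise ValueError("mode must be 'branch' or 'mutation'")
    flat = kern(
        int(n_loci), int(seed) % 2147483647,
        init_pop, comp["sizes0"], comp["mig"],
        comp["ev_time"], comp["ev_type"], comp["ev_a"], comp["ev_b"], comp["ev_x"],
        axis_of_pop, strides, int(np.prod(shape)),
    )
    return JointSFS(pops, flat.reshape(shape), polarity="derived")


def simulate_genotypes(
    model: DemographicModel,
    sample_config: dict,
    n_sites: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    anc_weights: np.ndarray | None = None,
    sample_names: list | None = None,
    pos_spacing: int = 100_000,
) -> GenotypeMatrix:
    """Simulate diploid genotypes at ``n_sites`` unlinked segregating sites.

    Diploids pair consecutive simulated gene copies; each copy draws its
    source population per site from ``anc_weights`` (defaults to one-hot
    rows from ``sample_config``).  Missingness is i.i.d. per genotype.
    Positions are spaced ``pos_spacing`` bp apart on one contig so that
    physically windowed operations treat them as unlinked.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    comp = model.compile()
    P = len(model.populations)
    if anc_weights is None:
        rows = []
        names = []
        for p, nd in sample_config.items():
            w = np.zeros(P)
            w[model.index(p)] = 1.0
            for i in range(int(nd)):
                names.append(f"{p}_{i}")
                rows.append(w)
                rows.append(w)
        anc_weights = np.array(rows)
        if sample_names is None:
            sample_names = names
    anc_weights = np.asarray(anc_weights, dtype=np.float64)
    if anc_weights.shape[0] % 2 != 0:
        raise ValueError("anc_weights must have two rows (gene copies) per individual")
    if not np.allclose(anc_weights.sum(axis=1), 1.0):
        raise ValueError("ancestry weights must sum to 1 per gene copy")
    geno = _kernel.genotype_sim(
        int(n_sites), int(seed) % 2147483647,
        anc_weights,
        comp["sizes0"], comp["mig"],
        comp["ev_time"], comp["ev_type"], comp["ev_a"], comp["ev_b"], comp["ev_x"],
        float(missing_rate),
    )
    n_ind = geno.shape[0]
    if sample_names is None:
        sample_names = [f"ind_{i}" for i in range(n_ind)]
    sites = [Site("1", 1 + pos_spacing * j, "A", "T") for j in range(n_sites)]
    return GenotypeMatrix(sample_names, sites, geno)


def annotate_degeneracy(
    n_sites: int,
    fractions: dict | None = None,
    retention: float = 0.4,
    seed: int = 0,
):
    """I.i.d. degeneracy labels plus a thinning mask for 0-fold sites.

    Default class fractions follow the composition of the exome-capture SNP
    panel this emulates (≈23% 0-fold, ≈13.5% 4-fold, remainder noncoding).
    Segregating 0-fold sites are dropped with probability ``1 − retention``
    — a crude purifying-selection proxy that drives π₀/π₄ toward
    ``retention`` since thinning is linear in π.

    Returns (SiteAnnotation, keep_mask).
    """
    if fractions is None:
        fractions = {"zero_fold": 0.227, "four_fold": 0.135, "other": 0.638}
    if not np.isclose(sum(fractions.values()), 1.0):
        raise ValueError("fractions must sum to 1")
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must be in (0, 1]")
    rng = np.random.default_rng(seed)
    classes = np.array(["zero_fold", "four_fold", "other"], dtype=object)
    probs = [fractions.get(str(c), 0.0) for c in classes]
    deg = rng.choice(classes, size=n_sites, p=probs)
    region = np.where(
        deg == "other",
        np.where(rng.random(n_sites) < 0.7, "intron", "intergenic"),
        "coding",
    ).astype(object)
    keep = np.ones(n_sites, dtype=bool)
    zf = deg == "zero_fold"
    keep[zf] = rng.random(int(zf.sum())) < retention
    return SiteAnnotation(deg, region), keep


#: Cluster composition used by the seven-cluster study cohort: the three
#: core P. abies domains plus four derived clusters, each a two-way mixture.
DEFAULT_ADMIXED_SPEC = {
    "RUS_BALTIC": {"CAR": 0.50, "FEN": 0.50},
    "N_POLAND": {"CAR": 0.75, "FEN": 0.25},
    "CENTRAL_EUROPE": {"ALP": 0.50, "CAR": 0.50},
    "CS_SWEDEN": {"ALP": 0.50, "FEN": 0.50},
}

CORE_CLUSTERS = ("ALP", "CAR", "FEN")


@dataclass
class SimulatedCohort:
    """Genotypes + truth labels for a synthetic study cohort."""

    matrix: GenotypeMatrix
    popmap: PopulationMap          # truth: cluster column is always the true cluster
    annotation: SiteAnnotation
    admixture: pd.DataFrame        # per-individual true ancestry weights
    # class counts before 0-fold thinning: the per-bp-style denominators for
    # pi0/pi4 rates (diversity.pi_by_degeneracy class_sizes argument)
    pre_thinning_class_sizes: dict = None

    def blinded_popmap(self) -> PopulationMap:
        """Popmap with the cluster of unknown-flagged samples hidden."""
        t = self.popmap.table.copy()
        t.loc[~t["known_origin"], ["population", "cluster"]] = "UNKNOWN"
        return PopulationMap(t, clusters=tuple(self.popmap.clusters) + ("UNKNOWN",))


def synthetic_cohort(
    model: DemographicModel,
    cluster_sizes: dict | None = None,
    unknown_fraction: float = 0.0,
    admixed_spec: dict | None = None,
    missing_rate: float = 0.05,
    n_sites: int = 20_000,
    weight_jitter_sd: float = 0.05,
    retention: float = 0.4,
    seed: int = 0,
) -> SimulatedCohort:
    """Emulate the seven-cluster study cohort under ``model``.

    Core clusters (ALP/CAR/FEN) are unadmixed draws from the matching model
    populations; derived clusters draw each gene copy from a source domain
    with per-individual ancestry weights (cluster means from
    ``admixed_spec``, jittered by a truncated normal of sd
    ``weight_jitter_sd``).  ``unknown_fraction`` of individuals is flagged
    as having no origin record; truth labels are retained.  0-fold sites
    are thinned with ``retention`` to emulate purifying selection.
    """
    if cluster_sizes is None:
        cluster_sizes = {c: 40 for c in CORE_CLUSTERS + tuple(DEFAULT_ADMIXED_SPEC)}
    if admixed_spec is None:
        admixed_spec = DEFAULT_ADMIXED_SPEC
    if any(v < 1 for v in cluster_sizes.values()):
        raise ValueError("cluster sizes must be >= 1")
    rng = np.random.default_rng(seed)
    P = len(model.populations)
    rows, names, clusters, weights_rec = [], [], [], []
    for cl, size in cluster_sizes.items():
        if cl in model.names:
            mean_w = {cl: 1.0}
        elif cl in admixed_spec:
            mean_w = admixed_spec[cl]
        else:
            raise ValueError(f"cluster {cl!r} is neither a model population nor in admixed_spec")
        if not np.isclose(sum(mean_w.values()), 1.0):
            raise ValueError(f"ancestry weights for {cl!r} must sum to 1")
        srcs = list(mean_w)
        for i in range(int(size)):
            w = np.array([mean_w[s] for s in srcs])
            if len(srcs) > 1 and weight_jitter_sd > 0:
                w = w + rng.normal(0.0, weight_jitter_sd, size=len(srcs))
                w = np.clip(w, 0.01, None)
                w = w / w.sum()
            row = np.zeros(P)
            for s, ws in zip(srcs, w):
                row[model.index(s)] = ws
            names.append(f"{cl}_{i}")
            clusters.append(cl)
            rows.append(row)
            rows.append(row)
            weights_rec.append(dict(zip(srcs, map(float, w))))
    anc = np.array(rows)
    G = simulate_genotypes(
        model, {}, n_sites, missing_rate, seed=seed,
        anc_weights=anc, sample_names=names,
    )
    annot, keep = annotate_degeneracy(n_sites, retention=retention, seed=seed + 1)
    class_sizes = {
        c: int((annot.degeneracy == c).sum()) for c in ("zero_fold", "four_fold", "other")
    }
    idx = np.flatnonzero(keep)
    G = G.take_sites(idx)
    annot = SiteAnnotation(annot.degeneracy[idx], annot.region[idx])
    known = np.ones(len(names), dtype=bool)
    if unknown_fraction > 0:
        n_unknown = int(round(unknown_fraction * len(names)))
        known[rng.choice(len(names), size=n_unknown, replace=False)] = False
    popmap = PopulationMap(
        pd.DataFrame(
            {
                "sample": names,
                "population": clusters,
                "cluster": clusters,
                "known_origin": known,
            }
        )
    )
    admix = pd.DataFrame({"sample": names, "cluster": clusters, "weights": weights_rec})
    return SimulatedCohort(G, popmap, annot, admix, class_sizes)
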