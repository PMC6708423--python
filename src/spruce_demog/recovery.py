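"""Recovery protocols on the fitted three-spruce demographic model.

Each protocol simulates an observed joint SFS under the published point
estimates, frees exactly one parameter (all others held at truth) and
re-estimates it by composite likelihood — the standard simulation check
that the inference machinery can recover the printed values.  The module
also bundles the seven-cluster origin-assignment benchmark and the
migration model-choice replication (m = 1e-6 vs m = 0 by Akaike weight).

Published point estimates and 95% CIs are those of the fitted model the
preset encodes; they are reference values for the checks, not inputs to
the estimation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import spruce_model
from .inference import akaike_weights, composite_log_likelihood, fit_model
from .simulate import simulate_sfs, synthetic_cohort


@dataclass(frozen=True)
class RecoveryProtocol:
    param: str                 # free parameter of the spruce preset
    bounds: tuple              # log-scale search bounds
    sample_config: dict        # population -> diploids for the observed SFS
    truth: float               # published point estimate (simulation truth)
    ci: tuple                  # published 95% CI
    kind: str                  # "size" | "time" | "proportion"


#: One protocol per recovered parameter of the fitted model.
RECOVERY_PROTOCOLS = {
    "n_omo": RecoveryProtocol("n_omo", (10.0, 1e4), {"OMO": 10, "FEN": 10},
                              78.0, (42.0, 566.0), "size"),
    "n_obo": RecoveryProtocol("n_obo", (1e3, 1e6), {"OBO": 10, "FEN": 10},
                              35_498.0, (14_500.0, 57_200.0), "size"),
    "n_fen": RecoveryProtocol("n_fen", (1e3, 1e6), {"OBO": 10, "FEN": 10},
                              7_540.0, (6_400.0, 9_500.0), "size"),
    # no CI was published for the pulse proportion; the band is the ±0.05
    # absolute tolerance of the recovery check
    "alpha_adm": RecoveryProtocol("alpha_adm", (0.01, 0.99), {"OBO": 10, "FEN": 10},
                                  0.17, (0.12, 0.22), "proportion"),
    "t_adm": RecoveryProtocol("t_adm", (1e3, 1e6), {"OBO": 10, "FEN": 10},
                              103_150.0, (1_300.0, 242_000.0), "time"),
    "t_obo_abies": RecoveryProtocol("t_obo_abies", (1e7, 1e8), {"OBO": 10, "FEN": 10},
                                    17_600_050.0, (17_040_000.0, 21_493_000.0), "time"),
    "t_omo_split": RecoveryProtocol("t_omo_split", (1e7, 1e8), {"OMO": 10, "FEN": 10},
                                    22_875_400.0, (22_770_000.0, 52_700_000.0), "time"),
    "t_bot_abies": RecoveryProtocol("t_bot_abies", (1e3, 1e6), {"ALP": 8, "CAR": 8, "FEN": 8},
                                    12_850.0, (6_400.0, 32_700.0), "time"),
    "t_hyb": RecoveryProtocol("t_hyb", (1e2, 1e5), {"OBO": 10, "HYB": 10, "FEN": 10},
                              1_600.0, (420.0, 77_000.0), "time"),
}


def derive_seed(base: int, idx: int, salt: int = 0) -> int:
    """Deterministic child seed below 2^31."""
    return (base * 7_919 + idx * 104_729 + salt * 1_299_709 + 13) % 2_147_483_647


def recover_parameter(
    name: str,
    seed: int = 1,
    n_sites: int = 50_000,
    n_genealogies: int = 100_000,
):
    """Run one single-parameter recovery; returns (estimate, protocol, fit).

    The observed SFS is a mutation-mode draw of ``n_sites`` segregating
    sites under the full preset; the focal parameter is then re-estimated
    with every other parameter fixed at its published value.
    """
    proto = RECOVERY_PROTOCOLS[name]
    idx = list(RECOVERY_PROTOCOLS).index(name)
    obs = simulate_sfs(
        spruce_model(), proto.sample_config, n_sites,
        mode="mutation", seed=derive_seed(seed, idx, 1),
    )
    fit = fit_model(
        obs, spruce_model, {proto.param: proto.bounds}, proto.sample_config,
        n_genealogies=n_genealogies, seed=derive_seed(seed, idx, 2),
        template="spruce_preset",
    )
    return fit.estimates[proto.param], proto, fit


def assignment_error(
    seed: int = 1,
    n_per_cluster: int = 40,
    n_sites: int = 23_000,
    n_components: int = 5,
    k: int = 5,
    missing_rate: float = 0.05,
) -> float:
    """Cross-validated misassignment rate on the seven-cluster cohort.

    Generates the synthetic study cohort (three core domains + four admixed
    derived clusters, ~2e4 SNPs after 0-fold thinning and LD pruning),
    computes the leading principal components and runs stratified k-fold
    cross-validation of the bagged-tree classifier.
    """
    from .assignment import cross_validate, pca_scores
    from .diversity import ld_prune

    coh = synthetic_cohort(
        spruce_model(),
        cluster_sizes={c: n_per_cluster for c in
                       ("ALP", "CAR", "FEN", "RUS_BALTIC", "N_POLAND",
                        "CENTRAL_EUROPE", "CS_SWEDEN")},
        missing_rate=missing_rate,
        n_sites=n_sites,
        seed=derive_seed(seed, 20, 1),
    )
    G = coh.matrix.take_sites(ld_prune(coh.matrix))
    scores, _ = pca_scores(G, n_components)
    labels = coh.popmap.table["cluster"].tolist()
    return cross_validate(scores, labels, k=k, seed=derive_seed(seed, 20, 2))


def migration_model_choice(
    seed: int = 1,
    n_replicates: int = 20,
    n_sites: int = 20_000,
    n_genealogies: int = 50_000,
) -> float:
    """Fraction of replicates whose Akaike weight favors m = 1e-6 over m = 0.

    Data are simulated under the preset (which carries m = 1e-6 among the
    three *P. abies* domains); both candidate models have all parameters
    fixed, so the comparison reduces to the composite likelihoods of the
    two expected spectra on each replicate's 3D ALP/CAR/FEN SFS.
    """
    config = {"ALP": 8, "CAR": 8, "FEN": 8}
    exp_mig = simulate_sfs(spruce_model(), config, n_genealogies,
                           mode="branch", seed=derive_seed(seed, 30, 1))
    exp_nomig = simulate_sfs(spruce_model(m_abies=0.0), config, n_genealogies,
                             mode="branch", seed=derive_seed(seed, 30, 1))

    class _Fixed:
        def __init__(self, cl):
            self.cl_e = cl
            self.free_names = []

    favored = 0
    for r in range(n_replicates):
        obs = simulate_sfs(spruce_model(), config, n_sites, mode="mutation",
                           seed=derive_seed(seed, 31, r + 1))
        cl_mig = composite_log_likelihood(obs, exp_mig)
        cl_nomig = composite_log_likelihood(obs, exp_nomig)
        w = akaike_weights([_Fixed(cl_mig), _Fixed(cl_nomig)])
        if w[0] > 0.5:
            favored += 1
    return favored / n_replicates
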