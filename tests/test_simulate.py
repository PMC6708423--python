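"""Coalescent simulator: closed forms, an independent-simulator oracle
(msprime), genotype-level contracts, and the study-cohort generator."""

import numpy as np
import pytest

from spruce_demog import (
    DemographicModel,
    Join,
    Population,
    Pulse,
    SiteAnnotation,
    annotate_degeneracy,
    simulate_genotypes,
    simulate_sfs,
    spruce_model,
    synthetic_cohort,
)
from spruce_demog.demography import SPRUCE_PARAMS, SizeChange


class TestClosedForms:
    def test_pairwise_coalescence_time(self, constant_model):
        # E[T2] = 2N generations; singleton-class branch length per locus = 2*T2
        chunks = []
        for s in range(10):
            S = simulate_sfs(constant_model, {"A": 1}, 2000, seed=s)
            chunks.append(S.data[1] / 2000 / 2)
        m, se = np.mean(chunks), np.std(chunks, ddof=1) / np.sqrt(10)
        assert abs(m - 2000) < 3 * se

    def test_sfs_proportional_to_one_over_i(self, constant_model):
        # E[xi_i] = theta/i: branch expectation 4N/i for i = 1..n-1
        chunks = np.array(
            [simulate_sfs(constant_model, {"A": 3}, 3000, seed=100 + s).data[1:6] / 3000
             for s in range(8)]
        )
        m = chunks.mean(axis=0)
        se = chunks.std(axis=0, ddof=1) / np.sqrt(8)
        expect = 4 * 1000.0 / np.arange(1, 6)
        assert np.all(np.abs(m - expect) < 3 * se + 0.02 * expect)

    def test_branch_and_mutation_modes_agree(self, constant_model):
        Sb = simulate_sfs(constant_model, {"A": 3}, 30000, mode="branch", seed=5)
        Sm = simulate_sfs(constant_model, {"A": 3}, 30000, mode="mutation", seed=6)
        pb = Sb.normalized()[1:6]
        pm = Sm.normalized()[1:6]
        # multinomial SE plus an allowance for the branch-mode MC error
        se = np.sqrt(pb * (1 - pb) / 30000)
        assert np.all(np.abs(pb - pm) < 4 * se + 0.01)


def _my_mean_sfs(model, config, n_loci, seed, chunks=8):
    per = [simulate_sfs(model, config, n_loci // chunks, seed=seed + i).normalized()
           for i in range(chunks)]
    per = np.array(per)
    return per.mean(axis=0), per.std(axis=0, ddof=1) / np.sqrt(chunks)


def _msprime_mean_sfs(demography, samples, n_rep, seed, chunks=8):
    import msprime

    per = []
    reps = msprime.sim_ancestry(
        samples=samples, demography=demography, num_replicates=n_rep,
        random_seed=seed, ploidy=2,
    )
    afs = []
    for ts in reps:
        sample_sets = [ts.samples(population=p) for p in range(ts.num_populations)
                       if len(ts.samples(population=p))]
        afs.append(ts.allele_frequency_spectrum(
            sample_sets=sample_sets, mode="branch", polarised=True, span_normalise=False))
    afs = np.array(afs)
    chunked = afs.reshape(chunks, n_rep // chunks, *afs.shape[1:]).mean(axis=1)
    chunked = chunked / chunked.sum(axis=tuple(range(1, afs.ndim)), keepdims=True)
    return chunked.mean(axis=0), chunked.std(axis=0, ddof=1) / np.sqrt(chunks)


def _assert_close_spectra(p1, se1, p2, se2, min_mass=0.005):
    big = (p1 > min_mass) | (p2 > min_mass)
    tol = 3 * np.sqrt(se1**2 + se2**2) + 0.003
    assert np.all(np.abs(p1 - p2)[big] < tol[big]), (
        np.abs(p1 - p2)[big] / tol[big]
    )


class TestMsprimeOracle:
    def test_constant_size(self, constant_model):
        import msprime

        p1, se1 = _my_mean_sfs(constant_model, {"A": 4}, 8000, seed=11)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=1000)
        p2, se2 = _msprime_mean_sfs(dem, {"A": 4}, 4000, seed=7)
        _assert_close_spectra(p1, se1, p2, se2)

    def test_two_pop_split(self):
        import msprime

        model = DemographicModel(
            [Population("A", 800.0), Population("B", 2000.0)],
            events=[SizeChange(25 * 3000, "A", 1500.0), Join(25 * 3000, "B", "A")],
        )
        p1, se1 = _my_mean_sfs(model, {"A": 3, "B": 3}, 8000, seed=21)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=800)
        dem.add_population(name="B", initial_size=2000)
        dem.add_population(name="anc", initial_size=1500)
        dem.add_population_split(time=3000, derived=["A", "B"], ancestral="anc")
        p2, se2 = _msprime_mean_sfs(dem, {"A": 3, "B": 3}, 4000, seed=9)
        _assert_close_spectra(p1.ravel(), se1.ravel(), p2.ravel(), se2.ravel())

    def test_pulse_admixture(self):
        import msprime

        model = DemographicModel(
            [Population("A", 1000.0), Population("B", 1000.0)],
            events=[
                Pulse(25 * 500, "A", "B", 0.3),
                Join(25 * 6000, "B", "A"),
            ],
        )
        p1, se1 = _my_mean_sfs(model, {"A": 3, "B": 3}, 8000, seed=31)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=1000)
        dem.add_population(name="B", initial_size=1000)
        dem.add_population(name="anc", initial_size=1000)
        dem.add_mass_migration(time=500, source="A", dest="B", proportion=0.3)
        dem.add_population_split(time=6000, derived=["A", "B"], ancestral="anc")
        p2, se2 = _msprime_mean_sfs(dem, {"A": 3, "B": 3}, 4000, seed=13)
        _assert_close_spectra(p1.ravel(), se1.ravel(), p2.ravel(), se2.ravel())

    def test_fst_increases_with_split_time(self):
        from spruce_demog.diversity import hudson_fst

        fsts = []
        for T_gen in (500, 3000, 15000):
            model = DemographicModel(
                [Population("A", 1000.0), Population("B", 1000.0)],
                events=[Join(25 * T_gen, "B", "A")],
            )
            G = simulate_genotypes(model, {"A": 10, "B": 10}, 3000, seed=T_gen)
            fsts.append(hudson_fst(G, np.arange(10), np.arange(10, 20)))
        assert fsts == sorted(fsts)


class TestSpruceModelPreset:
    def test_printed_point_values(self):
        m = spruce_model()
        assert m.populations[m.index("OBO")].size == 35_498
        pulse = [e for e in m.events if isinstance(e, Pulse) and e.recipient == "FEN"][0]
        assert pulse.proportion == 0.17
        assert pulse.donor == "OBO"
        assert m.mu_per_year * m.generation_time == pytest.approx(2.75e-8)

    def test_generation_time_rescaling(self):
        m25, m50 = spruce_model(25), spruce_model(50)
        for p25, p50 in zip(m25.populations, m50.populations):
            assert p50.size == pytest.approx(p25.size / 2)
        for e25, e50 in zip(m25.events, m50.events):
            assert e25.time_years == e50.time_years  # years unchanged
        # generations halve for fixed years
        assert m50.generations(1e6) == pytest.approx(m25.generations(1e6) / 2)

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            spruce_model(n_bogus=3)

    def test_sampling_missing_population_rejected(self, constant_model):
        with pytest.raises(ValueError):
            simulate_sfs(constant_model, {"Z": 2}, 10)


class TestModelSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        m = spruce_model()
        p = tmp_path / "model.yaml"
        m.to_yaml(p)
        m2 = DemographicModel.from_yaml(p)
        assert m2.names == m.names
        assert [p.size for p in m2.populations] == [p.size for p in m.populations]
        assert m2.events == m.events
        assert m2.migration == {tuple(k): v for k, v in m.migration.items()}
        assert (m2.mu_per_year, m2.generation_time) == (m.mu_per_year, m.generation_time)

    def test_default_projection_sizes(self, rng):
        from spruce_demog import joint_sfs

        from conftest import make_matrix

        calls = rng.choice([-1, 0, 1, 2], size=(10, 60), p=[0.2, 0.3, 0.3, 0.2])
        G = make_matrix(calls)
        S, report = joint_sfs(G, {"A": np.arange(10)})
        assert S.polarity == "minor"
        # default projects to the 10th percentile of called copies
        assert 2 <= S.n[0] <= 20
        assert report["used"] > 0


class TestGenotypeSimulation:
    def test_no_missing_when_rate_zero(self, constant_model):
        G = simulate_genotypes(constant_model, {"A": 5}, 200, missing_rate=0.0, seed=1)
        assert (G.calls >= 0).all()

    def test_site_count_contract(self, constant_model):
        G = simulate_genotypes(constant_model, {"A": 5}, 137, seed=2)
        assert G.n_sites == 137
        # every simulated site segregates in the full sample
        k = G.calls.sum(axis=0)
        assert ((k > 0) & (k < 20)).all()

    def test_pi_matches_branch_expectation(self, constant_model):
        from spruce_demog.diversity import site_pi
        from spruce_demog.sfs import pi_from_sfs

        G = simulate_genotypes(constant_model, {"A": 5}, 20000, seed=3)
        _, mean_pi, _, _ = site_pi(G)
        Sb = simulate_sfs(constant_model, {"A": 5}, 20000, mode="branch", seed=4)
        expect = pi_from_sfs(
            type(Sb)(Sb.pops, Sb.normalized(), Sb.polarity, Sb.mask)
        )
        assert mean_pi == pytest.approx(expect, rel=0.05)


@pytest.fixture(scope="module")
def cohort():
    return synthetic_cohort(
        spruce_model(), cluster_sizes=None, unknown_fraction=0.25,
        missing_rate=0.05, n_sites=3000, seed=42,
    )


class TestSyntheticCohort:

    def test_all_labels_visible_when_unknown_zero(self):
        coh = synthetic_cohort(spruce_model(), {"ALP": 3, "CAR": 3, "FEN": 3},
                               unknown_fraction=0.0, n_sites=50, seed=1)
        assert coh.popmap.table["known_origin"].all()

    def test_unknown_fraction_flagged_with_truth_retained(self, cohort):
        t = cohort.popmap.table
        assert (~t["known_origin"]).sum() == round(0.25 * len(t))
        assert set(t["cluster"]) == {"ALP", "CAR", "FEN"} | {
            "RUS_BALTIC", "N_POLAND", "CENTRAL_EUROPE", "CS_SWEDEN"}
        blinded = cohort.blinded_popmap()
        assert (blinded.table.loc[~t["known_origin"], "cluster"] == "UNKNOWN").all()

    def test_core_domains_form_separated_triangle(self, cohort):
        from sklearn.metrics import silhouette_score

        from spruce_demog.assignment import pca_scores

        scores, _ = pca_scores(cohort.matrix, 2)
        t = cohort.popmap.table
        core = t["cluster"].isin(["ALP", "CAR", "FEN"]).to_numpy()
        sil = silhouette_score(scores[core], t.loc[core, "cluster"])
        assert sil > 0

    def test_pure_weight_individual_matches_core(self):
        coh = synthetic_cohort(
            spruce_model(), {"FEN": 6, "PSEUDO": 6, "ALP": 4},
            admixed_spec={"PSEUDO": {"FEN": 1.0}},
            weight_jitter_sd=0.0, n_sites=2000, missing_rate=0.0, seed=8,
        )
        from spruce_demog.diversity import hudson_fst

        G = coh.matrix
        fen = G.sample_indices(coh.popmap.samples_of("FEN", "cluster"))
        pse = G.sample_indices(coh.popmap.samples_of("PSEUDO", "cluster"))
        assert abs(hudson_fst(G, fen, pse)) < 0.01

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synthetic_cohort(spruce_model(), {"X": 2, "ALP": 2, "CAR": 2},
                             admixed_spec={"X": {"ALP": 0.5, "CAR": 0.3}},
                             n_sites=10, seed=1)


class TestDegeneracyAnnotation:
    def test_full_retention_keeps_everything(self):
        annot, keep = annotate_degeneracy(5000, retention=1.0, seed=1)
        assert keep.all()

    def test_class_fractions(self):
        annot, _ = annotate_degeneracy(50000, seed=2)
        frac0 = (annot.degeneracy == "zero_fold").mean()
        assert frac0 == pytest.approx(0.227, abs=0.01)

    def test_no_zero_fold_when_fraction_zero(self):
        annot, _ = annotate_degeneracy(
            1000, fractions={"zero_fold": 0.0, "four_fold": 1.0, "other": 0.0}, seed=3)
        assert (annot.degeneracy == "four_fold").all()

    def test_pi_ratio_tracks_retention(self, constant_model):
        from spruce_demog.diversity import pi_by_degeneracy
        from spruce_demog.genotypes import SiteAnnotation

        n_sites = 30000
        G = simulate_genotypes(constant_model, {"A": 8}, n_sites, seed=5)
        annot, keep = annotate_degeneracy(n_sites, retention=0.4, seed=6)
        sizes = {c: int((annot.degeneracy == c).sum())
                 for c in ("zero_fold", "four_fold", "other")}
        idx = np.flatnonzero(keep)
        G2 = G.take_sites(idx)
        annot2 = SiteAnnotation(annot.degeneracy[idx], annot.region[idx])
        out = pi_by_degeneracy(G2, annot2, class_sizes=sizes)
        assert out["ratio"] == pytest.approx(0.4, abs=0.05)
        # per-variant-site ratio stays ~1: thinning removes sites, not diversity
        out_snp = pi_by_degeneracy(G2, annot2)
        assert out_snp["ratio"] == pytest.approx(1.0, abs=0.1)
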