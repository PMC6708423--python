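"""Polarization, projection, joint-SFS construction, folding and I/O."""

import itertools

import numpy as np
import pytest

from spruce_demog import JointSFS, fold_sfs, joint_sfs, project_counts, read_sfs, write_sfs
from spruce_demog.sfs import (
    REASON_OUTGROUP_POLY,
    REASON_OUTGROUP_UNCALLED,
    REASON_SHARED_POLY,
    pi_from_sfs,
    polarize_by_outgroup,
)

from conftest import make_matrix


class TestPolarization:
    def _pair(self, target_calls, outgroup_calls):
        return make_matrix(target_calls), make_matrix(outgroup_calls)

    def test_outgroup_fixed_ref_derived_is_alt(self):
        tgt, out = self._pair([[1], [0]], [[0], [0]])
        pol = polarize_by_outgroup(tgt, out)
        assert pol.usable[0] and pol.derived_is_alt[0]

    def test_shared_polymorphism_excluded(self):
        tgt, out = self._pair([[1], [0]], [[1], [0]])
        pol = polarize_by_outgroup(tgt, out)
        assert not pol.usable[0]
        assert pol.reason[0] == REASON_SHARED_POLY

    def test_uncalled_outgroup_excluded(self):
        tgt, out = self._pair([[1], [0]], [[-1], [-1]])
        pol = polarize_by_outgroup(tgt, out)
        assert pol.reason[0] == REASON_OUTGROUP_UNCALLED

    def test_fixation_truth_table(self):
        """All 9 combinations of {fixed ref, segregating, fixed alt}."""
        states = {"ref": [0, 0], "seg": [1, 0], "alt": [2, 2]}
        for out_state, tgt_state in itertools.product(states, states):
            tgt = make_matrix([[states[tgt_state][0]], [states[tgt_state][1]]])
            out = make_matrix([[states[out_state][0]], [states[out_state][1]]])
            pol = polarize_by_outgroup(tgt, out)
            if out_state == "seg":
                assert not pol.usable[0]
                expect = REASON_SHARED_POLY if tgt_state == "seg" else REASON_OUTGROUP_POLY
                assert pol.reason[0] == expect
            else:
                assert pol.usable[0]
                assert pol.derived_is_alt[0] == (out_state == "ref")
                # fixed derived difference iff target fixed for the non-outgroup allele
                expect_fixed = (out_state == "ref" and tgt_state == "alt") or (
                    out_state == "alt" and tgt_state == "ref"
                )
                assert bool(pol.fixed_difference[0]) == expect_fixed

    def test_site_lists_must_match(self):
        tgt = make_matrix([[0]])
        out = make_matrix([[0]], chrom="2")
        with pytest.raises(ValueError):
            polarize_by_outgroup(tgt, out)


class TestProjection:
    def test_identity_when_sizes_equal(self):
        w = project_counts(3, 6, 6)
        assert w[3] == pytest.approx(1.0)

    def test_zero_count_projects_to_zero(self):
        w = project_counts(0, 8, 4)
        assert w[0] == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        # k=2 of n_from=4 down to n_to=2: enumerate all C(4,2) subsamples
        copies = [1, 1, 0, 0]
        tallies = np.zeros(3)
        for pair in itertools.combinations(range(4), 2):
            tallies[sum(copies[i] for i in pair)] += 1
        expect = tallies / tallies.sum()
        assert project_counts(2, 4, 2) == pytest.approx(list(expect))
        assert expect == pytest.approx([1 / 6, 2 / 3, 1 / 6])

    def test_projecting_up_rejected(self):
        with pytest.raises(ValueError):
            project_counts(1, 4, 6)

    def test_weights_sum_to_one(self):
        for k, n_from, n_to in [(5, 12, 7), (1, 9, 3), (7, 7, 7)]:
            assert project_counts(k, n_from, n_to).sum() == pytest.approx(1.0)


class TestJointSfs:
    def test_single_pop_histogram(self):
        calls = [[1, 0, 2, 1], [0, 1, 2, 1]]
        G = make_matrix(calls)
        S, report = joint_sfs(G, {"A": [0, 1]}, {"A": 4}, polarity="derived",
                              polarization=_all_alt_polarization(G))
        counts = np.bincount(np.array(calls).sum(axis=0), minlength=5)
        assert S.data == pytest.approx(counts.astype(float))

    def test_conservation_of_segregating_sites(self, rng):
        calls = rng.choice([0, 1, 2], size=(8, 100))
        G = make_matrix(calls)
        S, report = joint_sfs(G, {"A": np.arange(4), "B": np.arange(4, 8)},
                              {"A": 8, "B": 8}, polarity="derived",
                              polarization=_all_alt_polarization(G))
        k = calls.sum(axis=0)
        n_seg = int(((k > 0) & (k < 16)).sum())
        assert S.total() == pytest.approx(n_seg)
        assert report["used"] == 100

    def test_two_pop_toy_matrix_brute_force(self):
        # 6 sites, 2+2 diploids; no missing data, no projection
        calls = [
            [1, 0, 2, 1, 0, 2],
            [0, 1, 2, 0, 0, 2],
            [2, 0, 0, 1, 1, 0],
            [1, 1, 0, 0, 1, 0],
        ]
        G = make_matrix(calls)
        S, _ = joint_sfs(G, {"A": [0, 1], "B": [2, 3]}, {"A": 4, "B": 4},
                         polarity="derived", polarization=_all_alt_polarization(G))
        expect = np.zeros((5, 5))
        arr = np.array(calls)
        for s in range(6):
            expect[arr[:2, s].sum(), arr[2:, s].sum()] += 1
        assert S.data == pytest.approx(expect)

    def test_insufficient_coverage_skipped(self):
        calls = [[1, 1], [-1, 0], [0, 1], [1, 0]]
        G = make_matrix(calls)
        S, report = joint_sfs(G, {"A": np.arange(4)}, {"A": 8}, polarity="derived",
                              polarization=_all_alt_polarization(G))
        assert report["insufficient_coverage"] == 1
        assert report["used"] == 1

    def test_projection_spreads_unit_mass(self):
        calls = [[1, 1], [-1, 1], [0, 0], [1, 2]]
        G = make_matrix(calls)
        S, report = joint_sfs(G, {"A": np.arange(4)}, {"A": 6}, polarity="derived",
                              polarization=_all_alt_polarization(G))
        assert S.data.sum() == pytest.approx(report["used"])


class TestFold:
    def test_double_fold_rejected(self):
        S = JointSFS(["A"], np.arange(5, dtype=float), polarity="derived")
        with pytest.raises(ValueError):
            fold_sfs(fold_sfs(S))

    def test_total_count_conserved(self, rng):
        data = rng.random((5, 5)) * 10
        S = JointSFS(["A", "B"], data)
        assert fold_sfs(S).data.sum() == pytest.approx(data.sum())

    def test_brute_force_fold_oracle(self, rng):
        data = rng.random((5, 5)) * 10
        S = JointSFS(["A", "B"], data)
        F = fold_sfs(S)
        n = (4, 4)
        # oracle: accumulate every entry into its canonical fold representative
        expect = np.zeros((5, 5))
        for e in np.ndindex(5, 5):
            c = (n[0] - e[0], n[1] - e[1])
            tot, ctot = sum(e), sum(c)
            if tot < ctot or (tot == ctot and e <= c):
                rep = e
            else:
                rep = c
            expect[rep] += data[e]
        assert F.data == pytest.approx(expect)
        # minor polarity: no unmasked mass above half-total
        heavy = [e for e in np.ndindex(5, 5) if sum(e) > 4 and not F.mask[e]]
        assert heavy == []

    def test_minor_entries_above_half_are_zero(self, rng):
        F = fold_sfs(JointSFS(["A"], rng.random(7)))
        i = np.arange(7)
        assert F.data[i > 3] == pytest.approx(0.0)


class TestSfsIo:
    def test_roundtrip(self, tmp_path, rng):
        S = JointSFS(["X", "Y"], rng.random((4, 6)), polarity="derived")
        p = tmp_path / "s.sfs"
        write_sfs(S, p)
        assert read_sfs(p) == S

    def test_truncated_file_rejected(self, tmp_path):
        p = tmp_path / "bad.sfs"
        p.write_text('3 3 unfolded "A" "B"\n1 2 3 4\n')
        with pytest.raises(ValueError):
            read_sfs(p)

    def test_hand_written_3x3(self, tmp_path):
        p = tmp_path / "hand.sfs"
        p.write_text('3 3 unfolded "A" "B"\n0 1 2 3 4 5 6 7 8\n1 0 0 0 0 0 0 0 1\n')
        S = read_sfs(p)
        assert S.data == pytest.approx(np.arange(9.0).reshape(3, 3))
        assert S.mask[0, 0] and S.mask[2, 2] and S.mask.sum() == 2


class TestCrossModuleIdentities:
    def test_marginalizing_3d_matches_direct_2d(self, rng):
        calls = rng.choice([0, 1, 2], size=(12, 150))
        G = make_matrix(calls)
        pops3 = {"A": np.arange(4), "B": np.arange(4, 8), "C": np.arange(8, 12)}
        pol = _all_alt_polarization(G)
        S3, _ = joint_sfs(G, pops3, {"A": 8, "B": 8, "C": 8}, "derived", pol)
        S2, _ = joint_sfs(G, {"A": pops3["A"], "B": pops3["B"]},
                          {"A": 8, "B": 8}, "derived", pol)
        marg = S3.marginalize((0, 1))
        assert marg.data == pytest.approx(S2.data)

    def test_pi_two_routes_agree(self, rng):
        from spruce_demog.diversity import site_pi

        calls = rng.choice([0, 1, 2], size=(6, 80))
        G = make_matrix(calls)
        S, _ = joint_sfs(G, {"A": np.arange(6)}, {"A": 12}, "derived",
                         _all_alt_polarization(G))
        per_site, _, n_used, _ = site_pi(G)
        assert pi_from_sfs(S) == pytest.approx(per_site.sum() - _corner_pi(calls))


class TestPropertyInvariants:
    """Hypothesis property checks (derandomised)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10_000))
    def test_fold_conserves_mass_and_halves_support(self, n1, n2, key):
        rng = np.random.default_rng(key)
        data = rng.random((n1 + 1, n2 + 1)) * 5
        S = JointSFS(["A", "B"], data)
        F = fold_sfs(S)
        assert F.data.sum() == pytest.approx(data.sum())
        half = (n1 + n2) / 2
        for e in np.ndindex(*F.data.shape):
            if sum(e) > half:
                assert F.data[e] == 0.0 and F.mask[e]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_projection_is_a_distribution_with_correct_mean(self, data):
        n_from = data.draw(self.st.integers(1, 30), label="n_from")
        n_to = data.draw(self.st.integers(1, n_from), label="n_to")
        k = data.draw(self.st.integers(0, n_from), label="k")
        w = project_counts(k, n_from, n_to)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        # hypergeometric mean: k * n_to / n_from
        assert (w * np.arange(n_to + 1)).sum() == pytest.approx(k * n_to / n_from)


def _corner_pi(calls):
    """π contribution of sites monomorphic in the sample (always 0)."""
    return 0.0


def _all_alt_polarization(G):
    """Trivial polarization: ref ancestral everywhere (simulator convention)."""
    from spruce_demog.sfs import Polarization

    n = G.n_sites
    return Polarization(
        derived_is_alt=np.ones(n, dtype=bool),
        usable=np.ones(n, dtype=bool),
        reason=np.zeros(n, dtype=np.int8),
        fixed_difference=np.zeros(n, dtype=bool),
    )
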