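import math

import numpy as np
import pytest

from mtphylogeo.diversity import brute_force_k_bar
from mtphylogeo.neutrality import (coalescent_simulate, ewens_log_pmf, fus_fs,
                                   log_stirling_first_kind, neutrality_test,
                                   tajima_constants, tajimas_d)
from mtphylogeo.seqio import Alignment


class TestStirling:
    # unsigned Stirling numbers of the first kind, rows n = 2..6
    KNOWN = {
        2: [0, 1, 1],
        3: [0, 2, 3, 1],
        4: [0, 6, 11, 6, 1],
        5: [0, 24, 50, 35, 10, 1],
        6: [0, 120, 274, 225, 85, 15, 1],
    }

    @pytest.mark.parametrize("n", sorted(KNOWN))
    def test_rows_match_known_values(self, n):
        np.testing.assert_allclose(np.exp(log_stirling_first_kind(n)), self.KNOWN[n],
                                   rtol=1e-12)

    def test_recursion_property(self):
        # |s(n,k)| = |s(n-1,k-1)| + (n-1)|s(n-1,k)|
        for n in range(3, 7):
            cur = np.exp(log_stirling_first_kind(n))
            prev = np.exp(log_stirling_first_kind(n - 1))
            for k in range(1, n):
                assert cur[k] == pytest.approx(prev[k - 1] + (n - 1) * prev[k])


class TestEwens:
    @pytest.mark.parametrize("n", [2, 5, 10, 30])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 7.3])
    def test_pmf_sums_to_one(self, n, theta):
        assert np.exp(ewens_log_pmf(n, theta)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_large_n_stays_normalized(self):
        assert np.exp(ewens_log_pmf(239, 8.9)).sum() == pytest.approx(1.0, abs=1e-8)


class TestFusFs:
    def test_toy_enumeration(self):
        # n=3, theta=1: |s(3,.)| = (2,3,1), (theta)_3 = 6 -> Pr(K=3) = 1/6
        assert fus_fs(3, 1.0, 3) == pytest.approx(math.log(0.2))

    def test_single_haplotype_is_plus_infinity(self):
        assert fus_fs(10, 2.0, 1) == math.inf

    def test_more_haplotypes_than_expected_pushes_fs_negative(self):
        assert fus_fs(50, 2.0, 30) < fus_fs(50, 2.0, 5)


class TestTajimasD:
    def test_zero_when_kbar_equals_watterson(self):
        c = tajima_constants(10)
        S = 7
        assert tajimas_d(10, S, S / c["a1"]) == pytest.approx(0.0, abs=1e-12)

    def test_four_sequence_example_independent_evaluation(self):
        # patterns (A,A,A,T) and (A,A,T,T): S=2, k_bar=7/6; constants by hand
        n = 4
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        S, k_bar = 2, 7 / 6
        expected = (k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(4, 2, 7 / 6) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.59, abs=0.005)

    def test_no_segregating_sites_flagged_nan(self):
        assert math.isnan(tajimas_d(10, 0, 0.0))

    def test_agrees_with_brute_force_k_bar(self, rng):
        seqs = tuple("".join(rng.choice(list("ACGT"), 25)) for _ in range(12))
        aln = Alignment(tuple(f"s{i}" for i in range(12)), seqs)
        res = neutrality_test(aln, reps=0)
        assert res.k_bar == pytest.approx(brute_force_k_bar(seqs))
        assert res.D == pytest.approx(tajimas_d(12, res.S, brute_force_k_bar(seqs)))


class TestCoalescentSimulation:
    def test_pairwise_expectation_n2(self):
        sims = coalescent_simulate(2, 3.0, 4000, seed=5, compute_fs=False)
        se = sims["k_bar"].std() / math.sqrt(len(sims["k_bar"]))
        assert sims["k_bar"].mean() == pytest.approx(3.0, abs=3 * se)

    def test_watterson_expectation(self):
        n, theta, reps = 10, 5.0, 10_000
        sims = coalescent_simulate(n, theta, reps, seed=6, compute_fs=False)
        expected = theta * tajima_constants(n)["a1"]
        se = sims["S"].std() / math.sqrt(reps)
        assert sims["S"].mean() == pytest.approx(expected, abs=3 * se)

    def test_tajimas_d_near_zero_under_neutrality(self):
        sims = coalescent_simulate(20, 5.0, 2000, seed=7, compute_fs=False)
        assert abs(np.nanmean(sims["D"])) < 0.15

    def test_neutrality_test_returns_seeded_p_values(self):
        aln = Alignment(("a", "b", "c", "d", "e"),
                        ("AAAAA", "AAAAT", "AATAT", "TATAT", "AAAAA"))
        r1 = neutrality_test(aln, reps=200, seed=9)
        r2 = neutrality_test(aln, reps=200, seed=9)
        assert r1.p_D == r2.p_D and r1.p_Fs == r2.p_Fs
        assert 0 < r1.p_D <= 1 and 0 < r1.p_Fs <= 1


def test_msprime_oracle_agrees_on_segregating_sites():
    """Independent coalescent oracle: our engine and msprime agree on E[S]."""
    import msprime

    n, theta, reps = 10, 5.0, 2000
    ours = coalescent_simulate(n, theta, reps, seed=13, compute_fs=False)["S"]
    s_msp = []
    for rep, ts in enumerate(msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, ploidy=1)], ploidy=1,
            population_size=1.0, sequence_length=1, discrete_genome=False,
            num_replicates=reps, random_seed=99)):
        mts = msprime.sim_mutations(ts, rate=theta / 2, random_seed=rep + 1,
                                    discrete_genome=False)
        s_msp.append(mts.num_sites)
    s_msp = np.asarray(s_msp)
    se = math.sqrt(ours.var() / reps + s_msp.var() / reps)
    assert ours.mean() == pytest.approx(s_msp.mean(), abs=3 * se)
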