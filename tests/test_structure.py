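import itertools
import math

import numpy as np
import pytest

from mtphylogeo.distances import DistanceMatrix, distance_matrix
from mtphylogeo.seqio import Alignment, Dataset, PopulationMap
from mtphylogeo.structure import (amova, amova_from_distances,
                                  geographic_distance_matrix, grouping_search,
                                  mantel_r, mantel_test, pairwise_phist,
                                  pairwise_phist_matrix, upgma)
from conftest import two_pop_fixed_dataset


def random_dataset(rng, pops=(6, 5, 7), L=30):
    ids, seqs, mapping = [], [], {}
    for p, n in enumerate(pops):
        for i in range(n):
            sid = f"p{p}i{i}"
            ids.append(sid)
            seqs.append("".join(rng.choice(list("ACGT"), L)))
            mapping[sid] = f"P{p}"
    return Dataset(Alignment(tuple(ids), tuple(seqs)), PopulationMap(mapping))


class TestAmova:
    def test_fixed_haplotypes_give_phi_one_with_hand_ssd(self):
        # 2 pops x 2 inds, within d=0, between d=1: SSD_T=1, SSD_WP=0 by hand
        d2 = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float)
        res = amova_from_distances(d2, ["P1", "P1", "P2", "P2"])
        assert res.ssd["total"] == pytest.approx(1.0)
        assert res.ssd["WP"] == pytest.approx(0.0)
        assert res.ssd["AP"] == pytest.approx(1.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_identical_sequences_flagged(self):
        aln = Alignment(tuple(f"s{i}" for i in range(4)), ("AAAA",) * 4)
        ds = Dataset(aln, PopulationMap({f"s{i}": f"P{i % 2}" for i in range(4)}))
        res = amova(ds, n_perm=0)
        assert all(v == 0 for v in res.sigma2.values())
        assert math.isnan(res.phi_st)

    def test_single_population_rejected(self):
        d2 = np.zeros((3, 3))
        with pytest.raises(ValueError):
            amova_from_distances(d2, ["P1", "P1", "P1"])

    def test_percentages_sum_to_100_on_random_data(self, rng):
        for _ in range(5):
            ds = random_dataset(rng)
            res = amova(ds, n_perm=0)
            assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.01)
            grouping = {"G1": ("P0", "P1"), "G2": ("P2",)}
            res2 = amova(ds, grouping, n_perm=0)
            assert sum(res2.percent.values()) == pytest.approx(100.0, abs=0.01)

    def test_hierarchical_phi_consistent_with_components(self, rng):
        ds = random_dataset(rng, pops=(5, 5, 5, 5))
        res = amova(ds, {"G1": ("P0", "P1"), "G2": ("P2", "P3")}, n_perm=0)
        sa, sb, sc = res.sigma2["AG"], res.sigma2["AP/WG"], res.sigma2["WP"]
        st = sa + sb + sc
        assert res.phi["phi_ct"] == pytest.approx(sa / st)
        assert res.phi["phi_sc"] == pytest.approx(sb / (sb + sc))
        assert res.phi["phi_st"] == pytest.approx((sa + sb) / st)

    def test_permutation_p_uses_add_one_estimator(self, rng):
        # p lives on the (count+1)/(n_perm+1) grid and can never be 0
        ds = random_dataset(rng, pops=(5, 6))
        res = amova(ds, n_perm=99, seed=0)
        p = res.p_values["phi_st"]
        assert p >= 1 / 100
        assert (p * 100) == pytest.approx(round(p * 100))
        # with 3+3 fixed haplotypes, 2 * 3!3!/6! of permutations tie the observed
        tied = amova(two_pop_fixed_dataset(), n_perm=999, seed=1)
        assert tied.p_values["phi_st"] == pytest.approx(0.1, abs=0.03)


class TestPairwisePhist:
    def test_identical_pools_near_zero(self, rng):
        # both populations drawn at random from one haplotype pool
        pool = ["ACGTACGT", "ACGTACGA", "ACGTACTT", "ACGAACGT"]
        n = 60
        ids = tuple(f"s{i}" for i in range(n))
        seqs = tuple(pool[i] for i in rng.integers(0, 4, size=n))
        ds = Dataset(Alignment(ids, seqs),
                     PopulationMap({sid: ("P1" if i < n // 2 else "P2")
                                    for i, sid in enumerate(ids)}))
        phi, p = pairwise_phist(ds, "P1", "P2", n_perm=99, seed=1)
        assert abs(phi) < 0.1
        assert p > 0.05

    def test_fixed_difference_gives_one(self):
        phi, _ = pairwise_phist(two_pop_fixed_dataset(), "PA", "PB", n_perm=49, seed=0)
        assert phi == pytest.approx(1.0)

    def test_matches_two_population_amova_exactly(self, rng):
        ds = random_dataset(rng, pops=(5, 6))
        phi, _ = pairwise_phist(ds, "P0", "P1", n_perm=0)
        res = amova(ds, n_perm=0)
        assert phi == pytest.approx(res.phi_st, abs=1e-12)

    def test_matrix_symmetric_with_unit_diagonal_zero(self, rng):
        ds = random_dataset(rng)
        m = pairwise_phist_matrix(ds, n_perm=19, seed=2)
        np.testing.assert_allclose(m.phi, m.phi.T)
        assert np.all(np.diag(m.phi) == 0)
        assert np.all((m.p_values[np.triu_indices(3, 1)] > 0)
                      & (m.p_values[np.triu_indices(3, 1)] <= 1))


class TestGroupingSearch:
    def test_single_candidate_returns_itself(self, rng):
        ds = random_dataset(rng)
        out = grouping_search(ds, {"only": {"G1": ("P0",), "G2": ("P1", "P2")}}, n_perm=0)
        assert len(out) == 1 and out[0][0] == "only"

    def test_true_two_cluster_grouping_wins(self):
        # two divergent clusters of populations; true split must maximize Phi_CT
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ids, seqs, mapping = [], [], {}
            for p in range(4):
                base = ("A" * 20) if p < 2 else ("T" * 10 + "A" * 10)
                for i in range(5):
                    sid = f"p{p}i{i}"
                    s = list(base)
                    for j in rng.integers(0, 20, size=2):
                        s[j] = rng.choice(list("ACGT"))
                    ids.append(sid)
                    seqs.append("".join(s))
                    mapping[sid] = f"P{p}"
            ds = Dataset(Alignment(tuple(ids), tuple(seqs)), PopulationMap(mapping))
            candidates = {
                "true": {"G1": ("P0", "P1"), "G2": ("P2", "P3")},
                "wrong1": {"G1": ("P0", "P2"), "G2": ("P1", "P3")},
                "wrong2": {"G1": ("P0", "P3"), "G2": ("P1", "P2")},
            }
            ranked = grouping_search(ds, candidates, n_perm=0)
            if ranked[0][0] == "true":
                wins += 1
        assert wins == 10


class TestUpgma:
    def test_two_taxa_height_half_distance(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]]), "raw")
        assert upgma(dm) == "(A:1.5,B:1.5);"

    def test_three_taxa_hand_agglomeration(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        newick = upgma(DistanceMatrix(("A", "B", "C"), d, "raw"))
        # (A,B) at height 1, then C joins at height 2
        assert newick == "(C:2,(A:1,B:1):1);"

    def test_negative_distances_clamped(self, caplog):
        d = np.array([[0, -0.1, 1], [-0.1, 0, 1], [1, 1, 0]], float)
        with caplog.at_level("WARNING"):
            newick = upgma(DistanceMatrix(("A", "B", "C"), d, "phi_st"))
        assert "clamping" in caplog.text
        assert newick.startswith("(C:")


class TestMantel:
    def test_identity_correlation_one(self, rng):
        m = np.abs(rng.normal(size=(6, 6)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        r, _ = mantel_test(m, m, n_perm=49, seed=0)
        assert r == pytest.approx(1.0)

    def test_permutation_estimate_matches_exhaustive_n4(self, rng):
        a = np.abs(rng.normal(size=(4, 4)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = np.abs(rng.normal(size=(4, 4)))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        _, p_exact = mantel_test(a, b, exact=True)
        _, p_perm = mantel_test(a, b, n_perm=4999, seed=3)
        assert p_perm == pytest.approx(p_exact, abs=0.05)

    def test_exhaustive_oracle_by_direct_enumeration(self, rng):
        a = np.abs(rng.normal(size=(4, 4)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a[::-1, ::-1].copy()
        r_obs, p_exact = mantel_test(a, b, exact=True)
        perms = list(itertools.permutations(range(4)))
        count = sum(mantel_r(a, b[np.ix_(p, p)]) >= r_obs for p in perms)
        assert p_exact == pytest.approx(count / len(perms))

    def test_type_i_error_near_nominal(self):
        rejections = 0
        n_sims = 300
        rng = np.random.default_rng(8)
        for _ in range(n_sims):
            a = np.abs(rng.normal(size=(10, 10)))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = np.abs(rng.normal(size=(10, 10)))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            _, p = mantel_test(a, b, n_perm=99, seed=rng)
            if p < 0.05:
                rejections += 1
        rate = rejections / n_sims
        se = math.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = np.abs(rng.normal(size=(8, 8)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + np.abs(rng.normal(scale=0.2, size=(8, 8)))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r_ours, p_ours = mantel_test(a, b, n_perm=999, seed=1)
        result = skbio_mantel(SkbioDM(a), SkbioDM(b), permutations=999, alternative="greater")
        r_skbio, p_skbio = float(result[0]), float(result[1])
        assert r_ours == pytest.approx(r_skbio, abs=1e-9)
        assert p_ours == pytest.approx(p_skbio, abs=0.05)


class TestGeography:
    def test_great_circle_matrix(self):
        pm = PopulationMap({"s1": "TPE", "s2": "SEL"},
                           {"TPE": {"lat": 25.03, "lon": 121.56},
                            "SEL": {"lat": 37.57, "lon": 126.98}})
        dm = geographic_distance_matrix(pm)
        # Taipei-Seoul is roughly 1,470 km
        assert dm.matrix[0, 1] == pytest.approx(1470, abs=60)
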