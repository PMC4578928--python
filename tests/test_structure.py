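"""AMOVA, pairwise Phi_ST and Mantel against explicit-loop oracles."""

import itertools

import numpy as np
import pytest

from mtpopgen.structure import (
    UndefinedStatisticError,
    amova,
    great_circle_matrix,
    mantel_test,
    pairwise_fst,
)
from mtpopgen.seqio import GroupingScheme
from conftest import make_dataset, random_alignment


def brute_force_amova(seqs, pops, group_of_pop):
    """Independent sums-of-squares AMOVA: explicit double loops over
    individuals, textbook unequal-size coefficients."""
    N = len(seqs)
    d2 = [[sum(a != b for a, b in zip(x, y)) for y in seqs] for x in seqs]
    pop_names = list(dict.fromkeys(pops))
    groups = list(dict.fromkeys(group_of_pop[p] for p in pop_names))
    idx_pop = {p: [i for i, q in enumerate(pops) if q == p] for p in pop_names}
    idx_grp = {
        g: [i for i, q in enumerate(pops) if group_of_pop[q] == g] for g in groups
    }

    def ssd(idx):
        return sum(d2[i][j] for i in idx for j in idx) / (2.0 * len(idx))

    ssd_t = ssd(range(N))
    ssd_g = sum(ssd(idx_grp[g]) for g in groups)
    ssd_p = sum(ssd(idx_pop[p]) for p in pop_names)
    G, P = len(groups), len(pop_names)
    df_a, df_b, df_c = G - 1, P - G, N - P
    n_p = {p: len(idx_pop[p]) for p in pop_names}
    n_g = {g: len(idx_grp[g]) for g in groups}
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pop_names if group_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    sigma_c = ssd_p / df_c
    n_coef = (N - sum_np2_over_ng) / df_b
    sigma_b = ((ssd_g - ssd_p) / df_b - sigma_c) / n_coef
    nprime = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / N) / df_a
    nprime2 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
    sigma_a = ((ssd_t - ssd_g) / df_a - sigma_c - nprime * sigma_b) / nprime2
    return sigma_a, sigma_b, sigma_c


@pytest.fixture
def toy_structured(rng):
    # 12 individuals, 3 populations (5/4/3), 2 groups, hand-sized alignment
    seqs = random_alignment(rng, 12, 30)
    pops = ["P1"] * 5 + ["P2"] * 4 + ["P3"] * 3
    gs = GroupingScheme({"P1": "G1", "P2": "G1", "P3": "G2"})
    _, _, hd = make_dataset(seqs, pops=pops)
    return seqs, pops, gs, hd


class TestAmova:
    def test_all_variance_among_groups(self):
        seqs = ["AAAAAAAAAA"] * 4 + ["TTTTTAAAAA"] * 4
        pops = ["P1"] * 4 + ["P2"] * 4
        _, _, hd = make_dataset(seqs, pops=pops)
        gs = GroupingScheme({"P1": "G1", "P2": "G2"})
        with pytest.warns(UserWarning, match="single population"):
            res = amova(hd, gs, R=0)
        assert res.F_CT == pytest.approx(1.0)
        assert res.F_ST == pytest.approx(1.0)
        assert res.sigma_b == 0.0 and res.sigma_c == 0.0

    def test_identical_sequences_undefined(self):
        _, _, hd = make_dataset(["ACGT"] * 6, pops=["P1"] * 3 + ["P2"] * 3)
        gs = GroupingScheme({"P1": "G1", "P2": "G2"})
        with pytest.raises(UndefinedStatisticError):
            amova(hd, gs, R=0)

    def test_components_match_brute_force(self, toy_structured):
        seqs, pops, gs, hd = toy_structured
        res = amova(hd, gs, R=0)
        sa, sb, sc = brute_force_amova(seqs, pops, gs.mapping)
        assert res.sigma_a == pytest.approx(sa, abs=1e-12)
        assert res.sigma_b == pytest.approx(sb, abs=1e-12)
        assert res.sigma_c == pytest.approx(sc, abs=1e-12)
        total = sa + sb + sc
        assert res.F_CT == pytest.approx(sa / total, abs=1e-9)
        assert res.F_SC == pytest.approx(sb / (sb + sc), abs=1e-9)
        assert res.F_ST == pytest.approx((sa + sb) / total, abs=1e-9)
        assert res.pct_a + res.pct_b + res.pct_c == pytest.approx(100.0, abs=0.01)

    def test_label_order_invariance(self, toy_structured):
        seqs, pops, gs, hd = toy_structured
        res1 = amova(hd, gs, R=0)
        relab = {"P1": "Z9", "P2": "A0", "P3": "M5"}
        _, _, hd2 = make_dataset(seqs, pops=[relab[p] for p in pops])
        gs2 = GroupingScheme({relab[p]: g for p, g in gs.mapping.items()})
        res2 = amova(hd2, gs2, R=0)
        assert res2.sigma_a == pytest.approx(res1.sigma_a, abs=1e-12)
        assert res2.F_CT == pytest.approx(res1.F_CT, abs=1e-12)

    def test_permutation_pvalues_reproducible(self, toy_structured):
        _, _, gs, hd = toy_structured
        r1 = amova(hd, gs, R=50, seed=11)
        r2 = amova(hd, gs, R=50, seed=11)
        assert (r1.p_CT, r1.p_SC, r1.p_ST) == (r2.p_CT, r2.p_SC, r2.p_ST)
        for p in (r1.p_CT, r1.p_SC, r1.p_ST):
            assert 0 < p <= 1


class TestPairwiseFst:
    def test_identical_monomorphic_populations(self):
        _, _, hd = make_dataset(["ACGT"] * 8, pops=["P1"] * 4 + ["P2"] * 4)
        res = pairwise_fst(hd, R=0)
        assert res.phi_st.loc["P1", "P2"] == 0.0

    def test_duplicate_polymorphic_populations_nonpositive(self, rng):
        # exact compositional duplicates: the among-population component is
        # estimated slightly negative and is reported untruncated
        seqs = random_alignment(rng, 4, 20)
        _, _, hd = make_dataset(seqs + seqs, pops=["P1"] * 4 + ["P2"] * 4)
        res = pairwise_fst(hd, R=0)
        assert res.phi_st.loc["P1", "P2"] <= 0.0

    def test_fixed_difference(self):
        _, _, hd = make_dataset(
            ["AAAA"] * 3 + ["TTAA"] * 3, pops=["P1"] * 3 + ["P2"] * 3
        )
        res = pairwise_fst(hd, R=0)
        assert res.phi_st.loc["P1", "P2"] == pytest.approx(1.0)

    def test_equals_two_level_amova(self, rng):
        seqs = random_alignment(rng, 9, 25)
        pops = ["P1"] * 5 + ["P2"] * 4
        _, _, hd = make_dataset(seqs, pops=pops)
        res = pairwise_fst(hd, R=0)
        # direct two-level oracle with explicit loops
        N = 9
        d2 = [[sum(a != b for a, b in zip(x, y)) for y in seqs] for x in seqs]

        def ssd(idx):
            return sum(d2[i][j] for i in idx for j in idx) / (2.0 * len(idx))

        ssd_t = ssd(range(N))
        ssd_w = ssd(range(5)) + ssd(range(5, 9))
        sigma_c = ssd_w / (N - 2)
        n_coef = (N - (25 + 16) / N) / 1
        sigma_a = ((ssd_t - ssd_w) - sigma_c) / n_coef
        assert res.phi_st.loc["P1", "P2"] == pytest.approx(
            sigma_a / (sigma_a + sigma_c), abs=1e-12
        )


class TestMantel:
    def test_perfect_correlation(self):
        m = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
        res = mantel_test(m, m, method="exact")
        assert res.r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], float)
        res = mantel_test(m, 10 - m - 10 * np.eye(4), method="exact")
        assert res.r == pytest.approx(-1.0)

    def test_constant_matrix_undefined(self):
        m = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(UndefinedStatisticError):
            mantel_test(m, m)

    def test_exact_p_equals_enumeration(self, rng):
        g = rng.random((4, 4))
        g = g + g.T
        np.fill_diagonal(g, 0)
        e = rng.random((4, 4))
        e = e + e.T
        np.fill_diagonal(e, 0)
        res = mantel_test(g, e, method="exact")
        tril = np.tril_indices(4, k=-1)
        x = g[tril]
        rs = []
        for perm in itertools.permutations(range(4)):
            ep = e[np.ix_(perm, perm)]
            rs.append(np.corrcoef(x, ep[tril])[0, 1])
        rs = np.array(rs)
        r_obs = np.corrcoef(x, e[tril])[0, 1]
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p_greater == pytest.approx((rs >= r_obs - 1e-12).mean())
        assert res.p_less == pytest.approx((rs <= r_obs + 1e-12).mean())

    def test_r_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        g = rng.random((6, 6))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        e = rng.random((6, 6))
        e = (e + e.T) / 2
        np.fill_diagonal(e, 0)
        r_sk, _, _ = sk_mantel(DistanceMatrix(g), DistanceMatrix(e),
                               permutations=0, alternative="greater")
        res = mantel_test(g, e, R=10, seed=1, method="permutation")
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)


def test_great_circle_known_distance():
    import pandas as pd
    from mtpopgen.seqio import PopulationMap

    pm = PopulationMap(pd.DataFrame({
        "sequence_id": ["a", "b"],
        "count": [1, 1],
        "population": ["P1", "P2"],
        "latitude": [0.0, 0.0],
        "longitude": [0.0, 1.0],
    }))
    d = great_circle_matrix(pm)
    # one degree of longitude at the equator ~ 111.19 km
    assert d.loc["P1", "P2"] == pytest.approx(111.19, abs=0.1)
    assert d.loc["P1", "P1"] == 0.0
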