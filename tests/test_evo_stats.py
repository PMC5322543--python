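import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirdiverge import (
    align_codons,
    align_proteins,
    chi_square_2x2,
    compare_correlation_groups,
    kaks_for_pair,
    ng86_ka_ks,
    pearson_r,
)
from mirdiverge.evo_stats import codon_sites, translate_cds

from oracles import oracle_ng86

SENSE_CODONS = [
    a + b + c
    for a, b, c in itertools.product("ACGT", repeat=3)
    if (a + b + c) not in {"TAA", "TAG", "TGA"}
]


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,r",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),
        ],
    )
    def test_known_values(self, x, y, r):
        assert pearson_r(x, y) == pytest.approx(r)

    def test_pairwise_deletion_of_missing(self):
        x = [1, 2, np.nan, 3, 4]
        y = [2, 4, 5, 6, 8]
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson_r([1, 2], [3, 4])

    @given(
        st.floats(min_value=0.1, max_value=5),
        st.floats(min_value=-10, max_value=10),
    )
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_positive_affine_transform(self, a, b):
        x = [1.0, 2.0, 4.0, 8.0, 3.0]
        y = [2.0, 1.0, 5.0, 7.0, 4.0]
        assert pearson_r([a * v + b for v in x], y) == pytest.approx(pearson_r(x, y))


class TestGroupComparison:
    def test_separated_groups_direction_and_exact_p(self):
        res = compare_correlation_groups([0.9, 0.8, 0.85], [0.1, 0.2, 0.15])
        assert res.median_a > res.median_b
        assert res.method == "exact"
        # full separation of 3 vs 3: two-sided exact p = 2 * 1/C(6,3)
        assert res.p_value == pytest.approx(2 / 20)

    def test_exact_p_matches_enumeration(self):
        a, b = [0.9, 0.5, 0.7], [0.6, 0.1, 0.3]
        res = compare_correlation_groups(a, b)
        # enumerate all assignments of the pooled ranks to group a
        pooled = sorted(a + b)
        u_obs = sum(1 for x in a for y in b if x > y)
        n = 0
        extreme = 0
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in ga for y in gb if x > y)
            n += 1
            if abs(u - 4.5) >= abs(u_obs - 4.5):
                extreme += 1
        assert res.p_value == pytest.approx(extreme / n)

    def test_identical_groups_p_is_one(self):
        res = compare_correlation_groups([0.1, 0.3, 0.5], [0.2, 0.4, 0.6])
        assert res.p_value == pytest.approx(1.0, abs=0.35)
        same = compare_correlation_groups([0.5, 0.7], [0.5, 0.7])
        assert same.p_value == pytest.approx(1.0)

    def test_large_groups_use_asymptotic(self, rng):
        a = rng.normal(0.8, 0.05, 50)
        b = rng.normal(0.2, 0.05, 50)
        res = compare_correlation_groups(a, b)
        assert res.method == "asymptotic"
        assert res.p_value < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_correlation_groups([], [0.5])


class TestChiSquare:
    def test_independence_gives_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_duplicate_enrichment_table_significant(self):
        _, p = chi_square_2x2([[144, 21910], [1, 3519]])
        assert p < 1e-4

    def test_species_divergence_contrast_significant(self):
        _, p = chi_square_2x2([[507, 51], [52, 18]])
        assert p < 0.05

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            chi_square_2x2([[0, 0], [5, 5]])

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=100)
    def test_matches_closed_form(self, cells):
        a, b, c, d = cells
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed, rel=1e-12)

    def test_matches_scipy_contingency(self):
        table = [[144, 21910], [1, 3519]]
        stat, p = chi_square_2x2(table)
        ref = sps.chi2_contingency(np.asarray(table), correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        stat_y, _ = chi_square_2x2(table, yates=True)
        ref_y = sps.chi2_contingency(np.asarray(table), correction=True)
        assert stat_y == pytest.approx(ref_y.statistic)


def random_cds(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def mutate_cds(rng, cds, n_sub):
    s = list(cds)
    for _ in range(n_sub):
        while True:
            i = int(rng.integers(len(s)))
            b = "ACGT"[rng.integers(4)]
            if b == s[i]:
                continue
            old = s[i]
            s[i] = b
            codon = "".join(s[3 * (i // 3) : 3 * (i // 3) + 3])
            if codon in {"TAA", "TAG", "TGA"}:
                s[i] = old
                continue
            break
    return "".join(s)


class TestCodonAlignment:
    def test_identical_pair_gap_free(self, rng):
        cds = random_cds(rng, 30)
        prot = align_proteins(translate_cds(cds), translate_cds(cds))
        a, b = align_codons(prot, cds, cds)
        assert a == b == cds

    def test_gap_expansion(self):
        cds_a = "ATGGCTGCTAAA"  # M A A K
        cds_b = "ATGGCTAAA"  # M A K
        prot = align_proteins("MAAK", "MAK")
        a, b = align_codons(prot, cds_a, cds_b)
        assert len(a) == len(b) == 12
        assert b.count("-") == 3 and a.count("-") == 0

    def test_round_trip_reproduces_cds(self, rng):
        for _ in range(5):
            cds_a = random_cds(rng, 40)
            cds_b = mutate_cds(rng, cds_a, 10)
            prot = align_proteins(translate_cds(cds_a), translate_cds(cds_b))
            a, b = align_codons(prot, cds_a, cds_b)
            assert a.replace("-", "") == cds_a
            assert b.replace("-", "") == cds_b

    def test_translation_mismatch_names_codon(self):
        prot = ("MK", "MK")
        with pytest.raises(ValueError, match="codon 2"):
            align_codons(prot, "ATGAAA", "ATGCCC")  # second row is M P, not M K


class TestNG86:
    def test_identical_sequences_zero(self, rng):
        cds = random_cds(rng, 50)
        res = ng86_ka_ks((cds, cds))
        assert res.ka == 0.0 and res.ks == 0.0

    def test_ttt_vs_ttc_saturates_synonymous(self):
        # TTT has 1 synonymous neighbour of 9 -> 1/3 synonymous sites;
        # the single difference is synonymous, so ps = 1/(1/3) = 3 >= 3/4
        s, n = codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        res = ng86_ka_ks(("TTT", "TTC"))
        assert "ks_saturated" in res.flags
        assert res.ks is None

    def test_swapping_sequences_symmetric(self, rng):
        a = random_cds(rng, 60)
        b = mutate_cds(rng, a, 15)
        r1, r2 = ng86_ka_ks((a, b)), ng86_ka_ks((b, a))
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)

    def test_self_concatenation_invariant(self, rng):
        a = random_cds(rng, 40)
        b = mutate_cds(rng, a, 8)
        r1 = ng86_ka_ks((a, b))
        r2 = ng86_ka_ks((a + a, b + b))
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)

    def test_gapped_columns_dropped(self, rng):
        a = random_cds(rng, 20)
        b = mutate_cds(rng, a, 4)
        r1 = ng86_ka_ks((a, b))
        r2 = ng86_ka_ks((a + "---", b + "AAA"))
        assert r1.n_codons == r2.n_codons
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_ka_ks(("TAAAAA", "AAAAAA"))

    def test_matches_bruteforce_oracle(self, rng):
        """Random 100-codon pairs agree with the independent NG86
        implementation to 1e-9."""
        for _ in range(10):
            a = random_cds(rng, 100)
            b = mutate_cds(rng, a, int(rng.integers(5, 60)))
            res = ng86_ka_ks((a, b))
            ka_o, ks_o = oracle_ng86(a, b)
            if math.isnan(ks_o):
                assert res.ks is None
            else:
                assert res.ks == pytest.approx(ks_o, abs=1e-9)
            if math.isnan(ka_o):
                assert res.ka is None
            else:
                assert res.ka == pytest.approx(ka_o, abs=1e-9)

    def test_full_pair_wrapper(self, rng):
        a = random_cds(rng, 40)
        b = mutate_cds(rng, a, 6)
        res = kaks_for_pair(a, b, pair_id="p1")
        assert res.pair_id == "p1"
        assert res.ks is not None and res.ks >= 0
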