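import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrpopgen.diversity import (
    aggregate_population_stats,
    classify_pic,
    hwe_exact_test,
    locus_stats,
    nei_distance,
    pic,
)
from ssrpopgen.genotypes import AlleleFrequencyTable, GenotypeMatrix, allele_freqs
from ssrpopgen.reference import locus_diversity_table
from ssrpopgen._util import round_half_up

from ._oracles import hwe_exact_enum_biallelic, pic_double_loop


def _freq_vectors():
    return st.lists(
        st.floats(0.01, 1.0), min_size=1, max_size=15
    ).map(lambda xs: [x / sum(xs) for x in xs])


class TestLocusStats:
    def test_symmetric_biallelic_closed_form(self):
        freqs = {86: 0.5, 90: 0.5}
        col = np.array([[86, 90]] * 50)
        st_ = locus_stats("L", freqs, 50, genotype_column=col)
        assert st_.na == 2
        assert st_.ne == pytest.approx(2.0)
        assert st_.ho == 1.0
        assert st_.he == pytest.approx((100 / 99) * 0.5)

    def test_published_row_internal_consistency(self):
        """He = (2n/(2n-1)) (1 - 1/Ne) reproduces the printed He for the most
        polymorphic published locus (pooled n = 268)."""
        he = (536 / 535) * (1 - 1 / 10.914)
        assert round_half_up(he, 3) == 0.910

    @given(_freq_vectors())
    def test_ne_he_match_direct_summation(self, p):
        n = 40
        freqs = {i + 1: x for i, x in enumerate(p)}
        st_ = locus_stats("L", freqs, n)
        s2 = sum(x * x for x in p)
        assert st_.ne == pytest.approx(1.0 / s2, abs=1e-12)
        assert st_.he == pytest.approx((2 * n / (2 * n - 1)) * (1 - s2), abs=1e-12)
        # identity linking the two
        assert st_.he == pytest.approx((2 * n / (2 * n - 1)) * (1 - 1 / st_.ne), abs=1e-9)

    @given(_freq_vectors())
    def test_allele_relabelling_invariance(self, p):
        a = locus_stats("L", {i + 1: x for i, x in enumerate(p)}, 30)
        b = locus_stats("L", {1000 - i: x for i, x in enumerate(p)}, 30)
        assert a.ne == pytest.approx(b.ne) and a.pic == pytest.approx(b.pic)

    @given(_freq_vectors())
    def test_bounds_and_pic_le_biased_he(self, p):
        st_ = locus_stats("L", {i + 1: x for i, x in enumerate(p)}, 30,
                          unbiased_he=False)
        assert 0 <= st_.he <= 1
        assert 0 <= st_.pic < 1
        assert st_.pic <= st_.he + 1e-12

    def test_singleton_allele_increases_na_and_homozygosity_sum(self):
        p = np.array([0.5, 0.5])
        p2 = np.array([0.45, 0.45, 0.10])
        a = locus_stats("L", {1: 0.5, 2: 0.5}, 20)
        b = locus_stats("L", {1: 0.45, 2: 0.45, 3: 0.10}, 20)
        assert b.na == a.na + 1
        assert np.sum(p2**2) < np.sum(p**2)
        assert 1 / b.ne < 1 / a.ne

    def test_monomorphic_locus(self):
        st_ = locus_stats("L", {100: 1.0}, 25, unbiased_he=False)
        assert (st_.na, st_.ne, st_.he, st_.pic) == (1, 1.0, 0.0, 0.0)


class TestPIC:
    def test_monomorphic_is_zero(self):
        assert pic([1.0]) == 0.0

    def test_symmetric_biallelic(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375)

    @pytest.mark.parametrize("k", range(2, 21))
    def test_equifrequent_closed_form_vs_double_loop(self, k):
        p = [1.0 / k] * k
        closed = 1 - 1 / k - (k - 1) / k**3
        assert pic(p) == pytest.approx(closed, abs=1e-12)
        assert pic(p) == pytest.approx(pic_double_loop(p), abs=1e-12)

    @given(_freq_vectors())
    def test_matches_double_loop_oracle(self, p):
        assert pic(p) == pytest.approx(pic_double_loop(p), abs=1e-12)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            pic([1.2, -0.2])

    @pytest.mark.parametrize(
        "value,band",
        [(0.901, "high"), (0.5, "high"), (0.25, "moderate"),
         (0.4999, "moderate"), (0.2499, "low"), (0.0, "low")],
    )
    def test_classification_bands(self, value, band):
        assert classify_pic(value) == band


class TestHWE:
    def test_exact_hwe_proportions_modal_table(self):
        p = hwe_exact_test({(1, 1): 25, (1, 2): 50, (2, 2): 25}, n_mc=2000, seed=0)
        assert p >= 0.9

    def test_complete_heterozygote_deficit(self):
        p = hwe_exact_test({(1, 1): 50, (2, 2): 50}, n_mc=10_000, seed=0)
        assert p < 0.001

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test({(7, 7): 30}, n_mc=1000, seed=0) == 1.0

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test({(1, 2): 5}, n_mc=50)

    @pytest.mark.parametrize(
        "n11,n12,n22",
        [(5, 0, 5), (2, 6, 2), (0, 10, 0), (4, 2, 4), (1, 3, 6), (3, 4, 3)],
    )
    def test_matches_full_enumeration_for_small_biallelic(self, n11, n12, n22):
        exact = hwe_exact_enum_biallelic(n11, n12, n22)
        mc = hwe_exact_test({(1, 1): n11, (1, 2): n12, (2, 2): n22},
                            n_mc=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_seed_reproducibility(self):
        counts = {(1, 1): 12, (1, 2): 5, (2, 2): 13}
        assert hwe_exact_test(counts, 1000, seed=5) == hwe_exact_test(counts, 1000, seed=5)


class TestNeiDistance:
    @staticmethod
    def _table(pop, freqs_per_locus):
        return AlleleFrequencyTable(
            population=pop,
            freqs={f"L{i}": f for i, f in enumerate(freqs_per_locus)},
            n={f"L{i}": 30 for i in range(len(freqs_per_locus))},
        )

    def test_identical_populations_distance_zero(self):
        t = self._table("X", [{1: 0.3, 2: 0.7}, {1: 1.0}])
        assert nei_distance(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_infinite(self):
        a = self._table("X", [{1: 1.0}, {3: 1.0}])
        b = self._table("Y", [{2: 1.0}, {4: 1.0}])
        assert math.isinf(nei_distance(a, b))

    def test_two_locus_toy_matches_hand_computation(self):
        a = self._table("X", [{1: 0.8, 2: 0.2}, {1: 0.5, 2: 0.5}])
        b = self._table("Y", [{1: 0.4, 2: 0.6}, {1: 0.9, 2: 0.1}])
        jxy = ((0.8 * 0.4 + 0.2 * 0.6) + (0.5 * 0.9 + 0.5 * 0.1)) / 2
        jx = ((0.64 + 0.04) + (0.25 + 0.25)) / 2
        jy = ((0.16 + 0.36) + (0.81 + 0.01)) / 2
        expected = -math.log(jxy / math.sqrt(jx * jy))
        assert nei_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, default_island):
        g, _ = default_island
        pops = g.population_labels
        ta, tb = allele_freqs(g, pops[0]), allele_freqs(g, pops[1])
        assert nei_distance(ta, tb) == pytest.approx(nei_distance(tb, ta), abs=1e-12)


class TestAggregation:
    def test_published_table_aggregates(self):
        from ssrpopgen.diversity import LocusStats

        tbl = locus_diversity_table()
        stats = [
            LocusStats(locus=r.locus, na=int(r.Na), ne=r.Ne, ho=r.Ho, he=r.He,
                       pic=r.PIC, n=268)
            for r in tbl.itertuples()
        ]
        agg = aggregate_population_stats(stats)
        assert agg.total_alleles == 364
        assert round_half_up(agg.mean_na, 3) == 12.552
        assert round_half_up(agg.mean_ne, 3) == 4.809
        assert round_half_up(agg.mean_ho, 3) == 0.648
        assert round_half_up(agg.mean_pic, 3) == 0.680
        assert agg.n_high_pic == 23

    def test_single_locus_mean_equals_value(self):
        from ssrpopgen.diversity import LocusStats

        st_ = LocusStats("L", 5, 3.2, 0.6, 0.7, 0.65, 40, p_hwe=0.2)
        agg = aggregate_population_stats([st_])
        assert agg.mean_ne == 3.2 and agg.mean_pic == 0.65
        assert agg.n_hwe_departures == 0
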