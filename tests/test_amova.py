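import numpy as np
import pytest

from ssrpopgen._util import MISSING, round_half_up
from ssrpopgen.amova import Amova, classify_fst, pairwise_fst, pct_from_components
from ssrpopgen.genotypes import GenotypeMatrix
from ssrpopgen.simulate import IslandModelSpec, simulate_genotypes

from ._oracles import amova_from_distances


def _matrix(pop_sizes, calls):
    individuals, populations = [], []
    for p, n in pop_sizes.items():
        individuals += [f"{p}{i}" for i in range(n)]
        populations += [p] * n
    loci = [f"L{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(individuals, populations, loci, calls)


class TestPctFromComponents:
    def test_published_component_pair(self):
        pct_among, pct_within, fst = pct_from_components(0.784, 9.752)
        assert round_half_up(pct_among, 2) == 7.44
        assert round_half_up(pct_within, 2) == 92.56
        assert round_half_up(fst, 3) == 0.074

    def test_zero_among(self):
        pct_among, pct_within, fst = pct_from_components(0.0, 3.0)
        assert (pct_among, pct_within, fst) == (0.0, 100.0, 0.0)

    def test_equal_components(self):
        pct_among, pct_within, fst = pct_from_components(2.5, 2.5)
        assert (pct_among, pct_within, fst) == (50.0, 50.0, 0.5)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            pct_from_components(0.0, 0.0)


class TestClassifyFst:
    @pytest.mark.parametrize(
        "value,band",
        [(0.074, "moderate"), (0.158, "high"), (0.0, "low"), (0.05, "moderate"),
         (0.15, "high"), (0.25, "very high"), (0.0499, "low")],
    )
    def test_wright_bands(self, value, band):
        assert classify_fst(value) == band


class TestAmova:
    def test_complete_differentiation(self):
        calls = np.zeros((10, 5, 2), dtype=np.int64)
        calls[:5] = 1
        calls[5:] = 2
        g = _matrix({"A": 5, "B": 5}, calls)
        res = Amova(g).fit(n_permutations=0)
        assert res.fst == pytest.approx(1.0, abs=1e-9)
        assert res.pct_among == pytest.approx(100.0, abs=1e-6)
        assert res.ss_within == pytest.approx(0.0, abs=1e-12)

    def test_df_follow_gene_copy_counts(self, default_island):
        g, _ = default_island
        res = Amova(g).fit(n_permutations=0)
        assert res.df_among == 3
        assert res.df_within == 2 * 268 - 4 == 532
        assert res.df_total == 535

    def test_ss_decomposition_and_distance_oracle(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(1, 5, size=(14, 6, 2)).astype(np.int64)
        calls[rng.random((14, 6)) < 0.1] = MISSING
        g = _matrix({"A": 5, "B": 4, "C": 5}, calls)
        res = Amova(g).fit(n_permutations=0)
        pops = np.array([{"A": 0, "B": 1, "C": 2}[p] for p in g.populations])
        ss_a, ss_w, var_a, var_w, fst = amova_from_distances(g.calls, pops)
        assert res.ss_among == pytest.approx(ss_a, abs=1e-6)
        assert res.ss_within == pytest.approx(ss_w, abs=1e-6)
        assert res.var_among == pytest.approx(var_a, abs=1e-9)
        assert res.fst == pytest.approx(fst, abs=1e-9)
        assert res.ss_total == pytest.approx(res.ss_among + res.ss_within, abs=1e-6)

    def test_equal_size_biallelic_closed_form(self):
        # two pops of 4, one biallelic locus: hand-derived copy-level theta
        calls = np.array(
            [[[1, 1]], [[1, 1]], [[1, 2]], [[1, 2]],
             [[2, 2]], [[2, 2]], [[2, 2]], [[1, 2]]], dtype=np.int64
        )
        g = _matrix({"A": 4, "B": 4}, calls)
        res = Amova(g).fit(n_permutations=0)
        # copy counts: pop A has 6 of allele 1, 2 of allele 2; pop B 1 and 7
        m = 16.0
        ssw = (8 - (6**2 + 2**2) / 8) / 2 + (8 - (1**2 + 7**2) / 8) / 2
        sst = (16 - (7**2 + 9**2) / 16) / 2
        ssa = sst - ssw
        var_w = ssw / 14
        n_prime = (16 - (64 + 64) / 16) / 1
        var_a = (ssa / 1 - var_w) / n_prime
        expected = var_a / (var_a + var_w)
        assert res.fst == pytest.approx(expected, abs=1e-6)

    @pytest.mark.filterwarnings("ignore:negative among-population")
    def test_null_populations_give_near_zero_fst(self):
        hits = 0
        for rep in range(40):
            spec = IslandModelSpec(
                pop_sizes={"A": 40, "B": 40}, n_loci=20, f_by_pop=0.0,
                missing_rate=0.0, seed=100 + rep,
            )
            g, _ = simulate_genotypes(spec)
            res = Amova(g).fit(n_permutations=49, seed=rep)
            if abs(res.fst) <= 0.02 and res.p_value > 0.05:
                hits += 1
        assert hits >= 36  # >= 90% of replicates

    def test_negative_variance_component_reported_with_warning(self):
        rng = np.random.default_rng(9)
        # tiny homogeneous data frequently yields a negative among component
        for seed in range(30):
            calls = np.random.default_rng(seed).integers(1, 3, (8, 3, 2)).astype(np.int64)
            g = _matrix({"A": 4, "B": 4}, calls)
            model = Amova(g)
            comp = model._components(model._pop_of_ind)
            if comp[2] < 0:
                with pytest.warns(UserWarning, match="negative"):
                    res = model.fit(n_permutations=0)
                assert res.var_among < 0
                return
        pytest.fail("no negative-component example found")

    def test_seed_determinism(self, default_island):
        g, _ = default_island
        r1 = Amova(g).fit(n_permutations=50, seed=7)
        r2 = Amova(g).fit(n_permutations=50, seed=7)
        assert r1.p_value == r2.p_value and r1.fst == r2.fst


@pytest.mark.filterwarnings("ignore:negative among-population")
class TestPairwiseFst:
    def test_duplicated_population_not_differentiated(self):
        rng = np.random.default_rng(2)
        half = rng.integers(1, 6, size=(30, 10, 2)).astype(np.int64)
        calls = np.concatenate([half, half], axis=0)
        g = _matrix({"A": 30, "B": 30}, calls)
        m = pairwise_fst(g, n_permutations=99, seed=3)
        assert abs(m.fst[0, 1]) < 0.02
        assert m.p_values[0, 1] > 0.05
        assert not m.significant()[0, 1]

    def test_island_model_recovery_and_ordering(self):
        spec = IslandModelSpec(
            pop_sizes={"A": 50, "B": 50, "C": 50},
            n_loci=25, n_alleles=10,
            f_by_pop={"A": 0.02, "B": 0.10, "C": 0.25},
            missing_rate=0.0, seed=21,
        )
        g, _ = simulate_genotypes(spec)
        m = pairwise_fst(g, n_permutations=0, seed=0)
        ab = m.fst[0, 1]
        ac = m.fst[0, 2]
        bc = m.fst[1, 2]
        # pair differentiation tracks the summed divergence of its members
        assert ab < ac and ab < bc
        assert np.allclose(m.fst, m.fst.T)
        assert np.all(np.diag(m.fst) == 0)

    def test_tiny_population_flagged_unreliable(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(1, 4, size=(6, 4, 2)).astype(np.int64)
        g = _matrix({"A": 5, "B": 1}, calls)
        m = pairwise_fst(g, n_permutations=19, seed=1)
        assert ("A", "B") in m.unreliable
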