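"""Unit and property tests for the admixture simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paintscan import scenarios
from paintscan.simulate import (
    DemographicModel,
    RecombinationMap,
    SelectedSite,
    SelectionModel,
    SizeEvent,
    ancestry_proportion_profile,
    check_tiling,
    diploid_fitness,
    draw_crossovers,
    init_founders,
    meiosis,
    next_generation,
    run_simulation,
    sample_haplotypes,
)

from conftest import make_haplotype


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            RecombinationMap(length=-1, rate=1e-8)
        with pytest.raises(ValueError):
            RecombinationMap(length=1e6)  # neither rate nor table
        with pytest.raises(ValueError):
            RecombinationMap(length=1e6, table=[[0, 0], [5e5, 1], [4e5, 2]])
        with pytest.raises(ValueError):
            DemographicModel(m=1.5, N0=10, generations=1,
                             chromosomes=(RecombinationMap(1e6, 1e-8),))
        with pytest.raises(ValueError):
            SelectedSite(0, 1e5, s=-0.1)

    def test_size_trajectory_bottleneck(self):
        model = scenarios.baseline_model(
            N0=10_000,
            size_events=(SizeEvent(25, "bottleneck_start", 5_000),
                         SizeEvent(35, "bottleneck_end")),
        )
        traj = model.size_trajectory()
        assert traj[0] == 10_000 and traj[24] == 10_000
        assert np.all(traj[25:35] == 5_000)
        assert np.all(traj[35:] == 10_000)


class TestFounders:
    def test_m_one_gives_all_source1(self, rng):
        model = scenarios.baseline_model(m=1.0, N0=50, generations=0)
        pop = init_founders(model, SelectionModel(()), rng)
        for chrom in pop.chromosomes:
            assert np.all(chrom.anc == 1)
            assert np.all(np.diff(chrom.offsets) == 1)  # single full-length tract

    def test_allele_equals_ancestry_when_sources_fixed(self, rng):
        # source 1 fixed for the allele, source 2 without it
        model = scenarios.baseline_model(N0=500, generations=0)
        sel = SelectionModel((SelectedSite(0, 25e6, 0.3, 0.5, 1.0, 0.0),))
        pop = init_founders(model, sel, rng)
        assert np.array_equal(pop.alleles[:, 0], pop.site_ancestry[:, 0])

    def test_founder_ancestry_binomial_mean(self, rng):
        # |mean - m| < 4 binomial SDs at 2N = 20,000 haplotypes
        model = scenarios.baseline_model(N0=10_000, generations=0)
        pop = init_founders(model, SelectionModel(()), rng)
        p_hat = pop.chromosomes[0].anc.mean()
        assert abs(p_hat - 0.5) < 4 * np.sqrt(0.25 / 20_000)


class TestCrossovers:
    def test_zero_rate_always_empty(self, rng):
        rmap = RecombinationMap(length=1e7, rate=0.0)
        for _ in range(20):
            assert len(draw_crossovers(rmap, rng)) == 0

    def test_mean_count_matches_map_length(self, rng, uniform_map):
        # rL = 1.3e-8 * 5e7 = 0.65 expected crossovers per meiosis
        counts = [len(draw_crossovers(uniform_map, rng)) for _ in range(10_000)]
        se = np.sqrt(0.65 / 10_000)
        assert abs(np.mean(counts) - 0.65) < 4 * se

    def test_table_mode_morgan_interpretation(self, rng):
        # 50 cM total map length -> 0.5 expected crossovers
        rmap = RecombinationMap(length=1e7, table=[[0, 0.0], [1e7, 50.0]])
        counts = [len(draw_crossovers(rmap, rng)) for _ in range(10_000)]
        assert abs(np.mean(counts) - 0.5) < 4 * np.sqrt(0.5 / 10_000)

    def test_positions_sorted_unique_in_range(self, rng, uniform_map):
        for _ in range(200):
            pos = draw_crossovers(uniform_map, rng)
            assert np.all(np.diff(pos) > 0)
            assert np.all((pos >= 0) & (pos < uniform_map.length))

    def test_poisson_goodness_of_fit(self, rng, uniform_map):
        from scipy import stats

        counts = np.array([len(draw_crossovers(uniform_map, rng)) for _ in range(10_000)])
        kmax = 4
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 0.65)
        expected = np.append(pmf, 1 - pmf.sum()) * len(counts)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.001


class TestMeiosis:
    L = 1e6
    rmap = RecombinationMap(length=1e6, rate=0.0)

    def test_no_breakpoints_returns_one_parent(self, rng):
        a = make_haplotype([4e5, self.L], [0, 1], self.L)
        b = make_haplotype([self.L], [1], self.L)
        g0 = meiosis((a, b), self.rmap, rng, breakpoints=[], start=0)
        g1 = meiosis((a, b), self.rmap, rng, breakpoints=[], start=1)
        assert np.array_equal(g0.tracts[0][0], a.tracts[0][0])
        assert np.array_equal(g0.tracts[0][1], a.tracts[0][1])
        assert np.array_equal(g1.tracts[0][1], b.tracts[0][1])

    def test_start_haplotype_is_fair_coin(self, rng):
        a = make_haplotype([self.L], [0], self.L)
        b = make_haplotype([self.L], [1], self.L)
        picks = [
            int(meiosis((a, b), self.rmap, rng, breakpoints=[]).tracts[0][1][0])
            for _ in range(2000)
        ]
        assert abs(np.mean(picks) - 0.5) < 4 * np.sqrt(0.25 / 2000)

    def test_closure_same_ancestry_parents(self, rng):
        a = make_haplotype([self.L], [1], self.L)
        b = make_haplotype([self.L], [1], self.L)
        g = meiosis((a, b), self.rmap, rng, breakpoints=[3e5, 7e5], start=0)
        ends, anc = g.tracts[0]
        assert np.array_equal(ends, [self.L])
        assert np.array_equal(anc, [1])

    def test_hand_traced_allele_copy(self, rng):
        # one breakpoint left of the selected site, starting on the all-0
        # parent: the all-1 parent donates the segment containing the site
        site = 6e5
        a = make_haplotype([self.L], [0], self.L, alleles=[0])
        b = make_haplotype([self.L], [1], self.L, alleles=[1])
        g = meiosis((a, b), self.rmap, rng, breakpoints=[5e5], start=0,
                    site_positions=[site])
        assert g.alleles[0] == 1
        assert g.ancestry_at(0, [site])[0] == 1
        # mirrored: site left of the breakpoint stays with the starting parent
        g2 = meiosis((a, b), self.rmap, rng, breakpoints=[7e5], start=0,
                     site_positions=[site])
        assert g2.alleles[0] == 0

    def test_junction_bookkeeping(self, rng):
        a = make_haplotype([4e5, self.L], [0, 1], self.L)
        b = make_haplotype([2e5, self.L], [1, 0], self.L)
        g = meiosis((a, b), self.rmap, rng, breakpoints=[5e5], start=0)
        ends, anc = g.tracts[0]
        # A over [0, 5e5): tracts (4e5, 0), (5e5, 1); B over [5e5, L): (L, 0)
        assert np.array_equal(ends, [4e5, 5e5, self.L])
        assert np.array_equal(anc, [0, 1, 0])

    def test_malformed_parent_rejected(self, rng):
        bad = make_haplotype([4e5], [0])  # does not reach chromosome end
        ok = make_haplotype([self.L], [1], self.L)
        with pytest.raises(ValueError):
            meiosis((bad, ok), self.rmap, rng)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_breaks=st.integers(0, 6))
    def test_gamete_always_tiles(self, seed, n_breaks):
        r = np.random.default_rng(seed)
        def random_hap():
            k = int(r.integers(1, 5))
            ends = np.sort(r.uniform(0, self.L, k - 1)) if k > 1 else np.empty(0)
            ends = np.append(ends, self.L)
            anc = np.empty(k, dtype=np.int8)
            anc[0] = r.integers(0, 2)
            for i in range(1, k):
                anc[i] = 1 - anc[i - 1]
            return make_haplotype(ends, anc, self.L)

        a, b = random_hap(), random_hap()
        breaks = np.sort(r.uniform(0, self.L, n_breaks))
        g = meiosis((a, b), self.rmap, r, breakpoints=breaks, start=int(r.integers(0, 2)))
        g.validate([self.L])


class TestFitness:
    sel = SelectionModel((SelectedSite(0, 1e5, 0.5, 0.5),))

    def test_heterozygote(self):
        assert diploid_fitness([1], [0], self.sel) == pytest.approx(1.25)

    def test_homozygote_carrier(self):
        assert diploid_fitness([1], [1], self.sel) == pytest.approx(1.5)

    def test_non_carrier_and_neutral(self):
        assert diploid_fitness([0], [0], self.sel) == 1.0
        assert diploid_fitness([0], [0], SelectionModel(())) == 1.0

    def test_two_site_product(self):
        sel2 = SelectionModel(
            (SelectedSite(0, 1e5, 0.05), SelectedSite(0, 2e5, 0.05))
        )
        # both heterozygous: 1.025 ** 2
        assert diploid_fitness([1, 1], [0, 0], sel2) == pytest.approx(1.050625)


class TestNextGeneration:
    def test_selection_recursion_one_generation(self):
        # p' = p[p(1+s) + q(1+hs)] / wbar = 0.6875 / 1.25 = 0.55 for
        # p0 = 0.5, s = 0.5, h = 0.5; N = 100,000 keeps drift tiny
        model = scenarios.baseline_model(N0=100_000, generations=1)
        sel = SelectionModel((SelectedSite(0, 25e6, 0.5, 0.5, 1.0, 0.0),))
        res = run_simulation(model, sel, seed=5)
        se = np.sqrt(0.55 * 0.45 / 200_000)
        assert abs(res.allele_frequency[1, 0] - 0.55) < 4 * se

    def test_bottleneck_size_honored(self, rng):
        model = scenarios.baseline_model(
            N0=200, generations=2, length=1e6,
            size_events=(SizeEvent(1, "set_size", 50),),
        )
        pop = init_founders(model, SelectionModel(()), rng)
        nxt = next_generation(pop, model, SelectionModel(()), rng)
        assert nxt.n_diploid == 50

    def test_neutral_ancestry_is_martingale(self, rng):
        # over replicate single generations, mean offspring ancestry stays
        # at the parental proportion
        model = scenarios.baseline_model(N0=300, generations=1, length=1e6)
        pop = init_founders(model, SelectionModel(()), rng)
        parental = pop.chromosomes[0].anc.mean()
        means = []
        for _ in range(200):
            nxt = next_generation(pop, model, SelectionModel(()), rng)
            anc = nxt.chromosomes[0]
            # haplotype-level ancestry proportion, length-weighted
            starts = np.concatenate(([0.0], anc.ends[:-1]))
            starts[anc.offsets[:-1]] = 0.0
            weights = anc.ends - starts
            means.append(np.sum(weights * (anc.anc == 1)) / weights.sum())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - parental) < 4 * se


class TestRunSimulation:
    def test_zero_generations_returns_founders(self):
        model = scenarios.baseline_model(N0=100, generations=0, length=1e6)
        res = run_simulation(model, SelectionModel(()), seed=3)
        assert res.population.generation == 0
        assert res.population.n_diploid == 100

    def test_deterministic_given_seed(self):
        model = scenarios.baseline_model(N0=100, generations=5, length=1e6)
        sel = SelectionModel((SelectedSite(0, 5e5, 0.2),))
        r1 = run_simulation(model, sel, seed=11)
        r2 = run_simulation(model, sel, seed=11)
        assert np.array_equal(r1.allele_frequency, r2.allele_frequency)
        assert np.array_equal(r1.population.chromosomes[0].ends,
                              r2.population.chromosomes[0].ends)

    def test_tract_tiling_after_full_run(self, small_model):
        sel = SelectionModel((SelectedSite(0, 2.5e6, 0.3),))
        res = run_simulation(small_model, sel, seed=21)
        check_tiling(res.population, small_model)

    def test_selection_raises_ancestry_above_m(self):
        # strong selection should push ancestry at the site above m in
        # essentially every replicate
        model = scenarios.baseline_model(N0=1_000, generations=50)
        wins = 0
        for i in range(20):
            sel = SelectionModel((SelectedSite(0, 25e6, 0.4, 0.5, 1.0, 0.0),))
            res = run_simulation(model, sel, seed=100 + i)
            wins += res.ancestry_proportion[-1, 0] > model.m
        assert wins >= 19

    def test_fst0_allele_rises_but_ancestry_does_not(self):
        # equal founder frequencies decouple allele and ancestry dynamics
        from scipy import stats

        model = scenarios.baseline_model(N0=1_000, generations=50)
        anc_sel, anc_neutral, freq_final = [], [], []
        for i in range(25):
            sel = SelectionModel((SelectedSite(0, 25e6, 0.4, 0.5, 0.5, 0.5),))
            res = run_simulation(model, sel, seed=300 + i)
            anc_sel.append(res.ancestry_proportion[-1, 0])
            freq_final.append(res.allele_frequency[-1, 0])
            neutral = SelectionModel((SelectedSite(0, 25e6, 0.0, 0.5, 0.5, 0.5),))
            resn = run_simulation(model, neutral, seed=600 + i)
            anc_neutral.append(resn.ancestry_proportion[-1, 0])
        assert np.mean(freq_final) > 0.8  # allele frequency rises strongly
        p = stats.ttest_ind(anc_sel, anc_neutral).pvalue
        assert p > 0.001  # ancestry indistinguishable from neutral


class TestSampling:
    def test_sample_is_permutation_when_exhaustive(self, small_model, rng):
        res = run_simulation(small_model, SelectionModel(()), seed=8)
        samples = sample_haplotypes(res, 2 * res.population.n_diploid, rng)
        assert np.array_equal(samples.individuals, np.arange(res.population.n_diploid))

    def test_same_seed_same_sample(self, small_model):
        res = run_simulation(small_model, SelectionModel(()), seed=8)
        s1 = sample_haplotypes(res, 20, np.random.default_rng(4))
        s2 = sample_haplotypes(res, 20, np.random.default_rng(4))
        assert np.array_equal(s1.individuals, s2.individuals)
        for h1, h2 in zip(s1.haplotypes, s2.haplotypes):
            assert np.array_equal(h1.tracts[0][0], h2.tracts[0][0])

    def test_distinct_individuals_and_odd_n_rejected(self, small_model, rng):
        res = run_simulation(small_model, SelectionModel(()), seed=8)
        samples = sample_haplotypes(res, 40, rng)
        assert len(np.unique(samples.individuals)) == 20
        with pytest.raises(ValueError):
            sample_haplotypes(res, 41, rng)
        with pytest.raises(ValueError):
            sample_haplotypes(res, 10 * res.population.n_diploid, rng)


class TestAncestryProfile:
    def test_trivial_profiles(self):
        from paintscan.simulate import SampleSet

        L = 1e6
        all1 = [make_haplotype([L], [1], L) for _ in range(4)]
        half = all1[:2] + [make_haplotype([L], [0], L) for _ in range(2)]
        s1 = SampleSet(all1, (L,), np.arange(2))
        s2 = SampleSet(half, (L,), np.arange(2))
        assert np.all(ancestry_proportion_profile(s1, [0, 5e5]) == 1.0)
        assert np.all(ancestry_proportion_profile(s2, [0, 5e5]) == 0.5)

    @pytest.mark.parametrize("m", [0.1, 0.5, 0.9])
    def test_neutral_mean_matches_admixture_fraction(self, m):
        # 15 replicates per admixture fraction; mean sampled ancestry within
        # 4 empirical SEs of m
        model = scenarios.baseline_model(m=m, N0=500, generations=20)
        means = []
        for i in range(15):
            rng = np.random.default_rng((17, i))
            res = run_simulation(model, SelectionModel(()), rng=rng)
            samples = sample_haplotypes(res, 200, rng)
            prof = ancestry_proportion_profile(samples, np.linspace(0, 49e6, 20))
            means.append(prof.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - m) < 4 * se


def test_hitchhiking_local_ancestry_peak():
    """Selection lifts ancestry at the selected site above distant loci."""
    model = scenarios.baseline_model(N0=1_000, generations=50)
    wins = 0
    n = 25
    for i in range(n):
        rng = np.random.default_rng((55, i))
        sel = SelectionModel((SelectedSite(0, 5e6, 0.3, 0.5, 1.0, 0.0),))
        res = run_simulation(model, sel, rng=rng)
        samples = sample_haplotypes(res, 200, rng)
        prof = ancestry_proportion_profile(samples, [5e6, 30e6, 45e6])
        wins += prof[0] > max(prof[1], prof[2])
    assert wins >= int(0.85 * n)
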