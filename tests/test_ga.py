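import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibga import (
    FeedforwardNet,
    GAConfig,
    Individual,
    NetworkConfig,
    crossover,
    evolve_generation,
    fib_fitness,
    ge_fitness,
    mean_abs_error,
    mutate,
    mutation_sigma,
    rank_population,
    selection_probabilities,
    sus_select,
    train_ga,
)
from fibga.ga import FIBFitness, GEFitness

from conftest import exact_xor_net

NC6 = NetworkConfig(n_hidden=6)


class TestFitness:
    def test_zero_genome_scores_half_on_xor(self, xor):
        z = np.zeros(25)
        assert ge_fitness(z, xor, NC6) == pytest.approx(0.5)
        # every single-fault variant of the zero net is still the zero net
        assert fib_fitness(z, xor, NC6) == pytest.approx(0.5)

    def test_hand_built_xor_solution_converged(self, xor):
        assert ge_fitness(exact_xor_net().to_vector(), xor, NC6) < 1e-3

    def test_ge_equals_forward_plus_error_composition(self, rng, xor):
        for _ in range(5):
            g = rng.uniform(-2, 2, 25)
            net = FeedforwardNet.from_vector(NC6, g)
            want = mean_abs_error(net.forward(xor.inputs), xor.targets)
            assert ge_fitness(g, xor, NC6) == pytest.approx(want, abs=1e-15)

    @pytest.mark.parametrize("H", [3, 6, 9])
    def test_fib_matches_brute_force_oracle(self, rng, xor, H):
        nc = NetworkConfig(n_hidden=H)
        for _ in range(3):
            g = rng.uniform(-2, 2, nc.n_params)
            per_fault = []
            for i in range(nc.n_params):
                v = g.copy()
                v[i] = 0.0
                net = FeedforwardNet.from_vector(nc, v)
                per_fault.append(mean_abs_error(net.forward(xor.inputs), xor.targets))
            assert fib_fitness(g, xor, nc) == pytest.approx(
                np.mean(per_fault), abs=1e-12
            )

    def test_zeroing_a_zero_parameter_reproduces_fault_free_error(self, rng, xor):
        g = rng.uniform(-2, 2, 25)
        g[7] = 0.0
        fault_free = ge_fitness(g, xor, NC6)
        v = g.copy()
        v[7] = 0.0
        assert ge_fitness(v, xor, NC6) == pytest.approx(fault_free)

    def test_batch_matches_scalar_calls(self, rng, xor):
        genomes = rng.uniform(-1, 1, size=(6, 25))
        fn = FIBFitness(xor, NC6)
        batched = fn.batch(genomes)
        assert np.allclose(batched, [fn(g) for g in genomes], atol=1e-14)


class TestRanking:
    def test_ranks_are_permutation(self, rng):
        pop = [Individual(genome=np.zeros(3), fitness=f) for f in rng.uniform(size=20)]
        rank_population(pop)
        assert sorted(ind.rank for ind in pop) == list(range(1, 21))

    def test_ties_broken_by_population_index(self):
        pop = [Individual(genome=np.zeros(1), fitness=f) for f in [0.5, 0.2, 0.2, 0.1]]
        rank_population(pop)
        assert [ind.rank for ind in pop] == [4, 2, 3, 1]

    def test_unevaluated_rejected(self):
        with pytest.raises(ValueError):
            rank_population([Individual(genome=np.zeros(1))])


class TestSelectionProbabilities:
    def test_pop20_normalizer(self):
        # Σ_{j=1..20} 1/sqrt(j) printed as 7.5953
        denom = np.sum(1 / np.sqrt(np.arange(1, 21)))
        assert round(denom, 4) == 7.5953
        probs = selection_probabilities(list(range(1, 21)), 20)
        assert probs[0] == pytest.approx(1 / denom)

    def test_sum_to_one_and_monotone(self):
        probs = selection_probabilities(list(range(1, 21)), 20)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(np.diff(probs) < 0)

    def test_rank1_to_rank4_ratio_is_two(self):
        probs = selection_probabilities(list(range(1, 21)), 20)
        assert probs[0] / probs[3] == pytest.approx(2.0)

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ValueError):
            selection_probabilities([1, 1, 3], 3)


class TestSUS:
    def test_canonical_parent_count(self, rng):
        probs = selection_probabilities(list(range(1, 21)), 20)
        assert len(sus_select(probs, GAConfig().n_parents, rng)) == 32

    def test_certain_individual_always_selected(self, rng):
        probs = np.array([0.0, 1.0, 0.0])
        assert np.all(sus_select(probs, 32, rng) == 1)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    @settings(max_examples=40, deadline=None)
    def test_floor_ceil_count_bounds(self, seed, n_items):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 1.0, size=n_items)
        probs = w / w.sum()
        n = 32
        counts = np.bincount(sus_select(probs, n, rng), minlength=n_items)
        for c, p in zip(counts, probs):
            assert np.floor(n * p) <= c <= np.ceil(n * p)


class TestVariation:
    def test_crossover_coordinates_come_from_parents(self, rng):
        p1 = np.arange(25, dtype=float)
        p2 = -np.arange(25, dtype=float)
        child = crossover(p1, p2, rng)
        assert all(c in (a, b) for c, a, b in zip(child, p1, p2))

    def test_crossover_mask_is_balanced(self):
        rng = np.random.default_rng(0)
        p1, p2 = np.ones(25), np.zeros(25)
        share = np.mean([crossover(p1, p2, rng).mean() for _ in range(400)])
        assert abs(share - 0.5) < 0.03

    def test_sigma_schedule_endpoints_and_midpoint(self):
        assert mutation_sigma(1, 1000) == 1.0
        assert mutation_sigma(1000, 1000) == 0.0
        assert mutation_sigma(501, 1001) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            mutation_sigma(0, 1000)
        with pytest.raises(ValueError):
            mutation_sigma(1001, 1000)

    def test_sigma_schedule_linear_nonincreasing(self):
        sig = [mutation_sigma(g, 1000) for g in range(1, 1001)]
        assert np.all(np.diff(sig) < 0)
        assert np.allclose(np.diff(sig, 2), 0, atol=1e-12)

    def test_mutate_sigma_zero_is_identity(self, rng):
        p = rng.normal(size=25)
        assert np.array_equal(mutate(p, 0.0, rng), p)

    def test_mutate_deterministic_and_scaled(self):
        p = np.zeros(25)
        a = mutate(p, 0.3, np.random.default_rng(5))
        b = mutate(p, 0.3, np.random.default_rng(5))
        assert np.array_equal(a, b)
        draws = mutate(np.zeros(10_000), 0.3, np.random.default_rng(6))
        assert abs(draws.std() - 0.3) < 0.01


class TestEvolution:
    def _initial_pop(self, fn, rng, config=GAConfig()):
        genomes = rng.uniform(-1, 1, size=(config.pop_size, 25))
        pop = [
            Individual(genome=g, fitness=float(fn(g))) for g in genomes
        ]
        return rank_population(pop)

    def test_population_size_and_elitism(self, rng, xor):
        fn = GEFitness(xor, NC6)
        pop = self._initial_pop(fn, rng)
        best_before = min(ind.fitness for ind in pop)
        new = evolve_generation(pop, fn, 2, GAConfig(), rng)
        assert len(new) == 20
        assert min(ind.fitness for ind in new) <= best_before

    def test_elites_copied_unchanged(self, rng, xor):
        fn = GEFitness(xor, NC6)
        pop = self._initial_pop(fn, rng)
        best = sorted(pop, key=lambda i: i.rank)[:2]
        new = evolve_generation(pop, fn, 2, GAConfig(), rng)
        for elite, child in zip(best, new[:2]):
            assert np.array_equal(elite.genome, child.genome)

    def test_requires_ranked_population(self, rng, xor):
        fn = GEFitness(xor, NC6)
        pop = [Individual(genome=g, fitness=1.0) for g in rng.uniform(size=(20, 25))]
        with pytest.raises(ValueError):
            evolve_generation(pop, fn, 2, GAConfig(), rng)


class TestTrainGA:
    def test_trace_monotone_and_deterministic(self, xor):
        cfg = GAConfig(max_generations=60)
        a = train_ga(xor, cfg, NC6, "GE", seed=3)
        b = train_ga(xor, cfg, NC6, "GE", seed=3)
        assert np.all(np.diff(a.best_error_trace) <= 0)
        assert np.array_equal(a.best_error_trace, b.best_error_trace)
        assert np.array_equal(a.best_net.to_vector(), b.best_net.to_vector())

    def test_trace_length_matches_termination(self, xor):
        res = train_ga(xor, GAConfig(max_generations=40), NC6, "FIB", seed=0)
        assert len(res.best_error_trace) == res.terminated_at == 40
        assert res.termination_reason == "max_iterations"

    def test_tolerance_termination(self, xor):
        # a loose tolerance triggers the 'tolerance' branch within a few generations
        res = train_ga(
            xor, GAConfig(max_generations=200, error_tolerance=0.4), NC6, "GE", seed=1
        )
        assert res.termination_reason == "tolerance"
        assert res.terminated_at < 200
        assert res.final_error < 0.4

    def test_unknown_fitness_rejected(self, xor):
        with pytest.raises(ValueError):
            train_ga(xor, GAConfig(), NC6, "XX", seed=0)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(n_elite=3)
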