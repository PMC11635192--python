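"""Genetic algorithm: operators, fitness functions, generational loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabletune.evolution import (
    DAC_MAX,
    EvolutionError,
    GAConfig,
    Individual,
    WORST_FITNESS,
    evolve,
    fitness_lambda,
    fitness_lambda_amplitude,
    fitness_multisite,
    init_population,
    make_evaluator,
    mutate_gene,
    mutate_individual,
    one_point_crossover,
    select_elites,
    tournament_select,
)
from cabletune.experiment import (
    AmplitudeMatrix,
    AttenuationFit,
    Observation,
    TargetObservation,
)


def _obs(lam, h0):
    amps = np.array([h0, h0 / 2, h0 / 4, h0 / 8, h0 / 16], dtype=float)
    fit = AttenuationFit(a=h0, lambda_emp=lam, c=0.0, residual=0.0)
    return Observation(amplitudes=amps, lambda_emp=lam, fit=fit)


class TestFitnessFunctions:
    def test_lambda_distance(self):
        tgt = TargetObservation(lambda_hat=1.07)
        assert fitness_lambda(_obs(1.07, 150), tgt) == 0.0
        assert fitness_lambda(_obs(1.12, 150), tgt) == pytest.approx(0.05)
        # symmetric in the two length constants
        assert fitness_lambda(_obs(1.02, 150), tgt) == pytest.approx(
            fitness_lambda(_obs(1.12, 150), tgt)
        )

    def test_two_observable_fitness(self):
        tgt = TargetObservation(lambda_hat=1.07, h0_hat=147.0)
        assert fitness_lambda_amplitude(_obs(1.07, 147), tgt) == 0.0
        assert fitness_lambda_amplitude(_obs(1.12, 140), tgt) == pytest.approx(
            0.004452, abs=1e-6
        )

    def test_two_observable_fitness_quadratic_homogeneity(self):
        tgt = TargetObservation(lambda_hat=1.0, h0_hat=100.0)
        f_small = fitness_lambda_amplitude(_obs(1.01, 101), tgt)
        f_big = fitness_lambda_amplitude(_obs(1.02, 102), tgt)
        assert f_big == pytest.approx(4 * f_small, rel=1e-9)

    def test_multisite_sum_of_squares(self, rng):
        a = rng.uniform(0, 200, (5, 5))
        b = rng.uniform(0, 200, (5, 5))
        # independent double-loop oracle
        expected = 0.0
        for i in range(5):
            for j in range(5):
                expected += (b[i, j] - a[i, j]) ** 2
        got = fitness_multisite(AmplitudeMatrix(h=a), AmplitudeMatrix(h=b))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_multisite_single_entry_off_by_two(self):
        a = np.zeros((5, 5))
        b = np.zeros((5, 5))
        b[2, 3] = 2.0
        assert fitness_multisite(AmplitudeMatrix(h=a), AmplitudeMatrix(h=b)) == 4.0

    def test_multisite_shape_mismatch(self):
        with pytest.raises(EvolutionError):
            fitness_multisite(
                AmplitudeMatrix(h=np.zeros((4, 4))), AmplitudeMatrix(h=np.zeros((5, 5)))
            )


class TestPopulation:
    def test_init_reproducible_and_bounded(self):
        cfg = GAConfig()
        p1 = init_population(cfg, 2, np.random.default_rng(3))
        p2 = init_population(cfg, 2, np.random.default_rng(3))
        assert len(p1) == cfg.n_individuals
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.genes, b.genes)
        genes = np.concatenate([ind.genes for ind in p1])
        assert genes.min() >= 0 and genes.max() <= DAC_MAX

    def test_init_uniform_mean(self):
        cfg = GAConfig(n_individuals=5000)
        pop = init_population(cfg, 2, np.random.default_rng(4))
        genes = np.concatenate([ind.genes for ind in pop])
        se = (DAC_MAX + 1) / np.sqrt(12) / np.sqrt(genes.size)
        assert abs(genes.mean() - DAC_MAX / 2) < 3 * se

    def test_elites_are_the_argmins(self):
        pop = [Individual(genes=[i, i], fitness=f) for i, f in
               enumerate([5.0, 1.0, 3.0, 0.5, 2.0])]
        elites = select_elites(pop, 2)
        assert [e.fitness for e in elites] == [0.5, 1.0]

    def test_elite_ties_broken_by_population_order(self):
        pop = [Individual(genes=[i, i], fitness=1.0) for i in range(5)]
        elites = select_elites(pop, 3)
        assert [int(e.genes[0]) for e in elites] == [0, 1, 2]

    def test_elites_are_copies(self):
        pop = [Individual(genes=[i, i], fitness=float(i)) for i in range(5)]
        elites = select_elites(pop, 1)
        elites[0].genes[0] = 999
        assert pop[0].genes[0] == 0

    def test_unevaluated_population_rejected(self):
        pop = [Individual(genes=[1, 1])]
        with pytest.raises(EvolutionError):
            select_elites(pop, 1)


class TestTournament:
    def _pop(self):
        return [Individual(genes=[i, i], fitness=float(10 - i)) for i in range(10)]

    def test_full_size_tournament_selects_global_best(self):
        pop = self._pop()
        rng = np.random.default_rng(0)
        winners = tournament_select(pop, k=10, n_select=5, rng=rng)
        assert all(w.fitness == 1.0 for w in winners)

    def test_k1_is_uniform_sampling(self):
        pop = self._pop()
        rng = np.random.default_rng(1)
        winners = tournament_select(pop, k=1, n_select=5000, rng=rng)
        picks = np.array([int(w.genes[0]) for w in winners])
        counts = np.bincount(picks, minlength=10) / picks.size
        assert np.all(np.abs(counts - 0.1) < 0.02)

    def test_seeded_winner_sequence_reproducible(self):
        pop = self._pop()
        w1 = tournament_select(pop, 3, 8, np.random.default_rng(7))
        w2 = tournament_select(pop, 3, 8, np.random.default_rng(7))
        assert [w.fitness for w in w1] == [w.fitness for w in w2]

    def test_oversized_tournament_rejected(self):
        with pytest.raises(EvolutionError):
            tournament_select(self._pop(), 11, 1, np.random.default_rng(0))


class TestCrossover:
    def test_two_gene_worked_example(self):
        # parents (408, 139) and (364, 975) cut after the first gene
        o1, o2 = one_point_crossover(
            Individual(genes=[408, 139]), Individual(genes=[364, 975]), cut_point=1
        )
        assert list(o1.genes) == [364, 139]
        assert list(o2.genes) == [408, 975]

    def test_nine_gene_cut_swaps_leading_segment(self):
        p1 = Individual(genes=list(range(9)))
        p2 = Individual(genes=list(range(100, 109)))
        o1, o2 = one_point_crossover(p1, p2, cut_point=4)
        assert list(o1.genes) == [100, 101, 102, 103, 4, 5, 6, 7, 8]
        assert list(o2.genes) == [0, 1, 2, 3, 104, 105, 106, 107, 108]

    @given(
        st.lists(st.integers(0, DAC_MAX), min_size=2, max_size=9),
        st.data(),
    )
    @settings(derandomize=True, max_examples=60)
    def test_positionwise_gene_multiset_preserved(self, genes, data):
        other = data.draw(
            st.lists(
                st.integers(0, DAC_MAX), min_size=len(genes), max_size=len(genes)
            )
        )
        cut = data.draw(st.integers(1, len(genes) - 1))
        o1, o2 = one_point_crossover(
            Individual(genes=genes), Individual(genes=other), cut
        )
        for pos in range(len(genes)):
            assert {int(o1.genes[pos]), int(o2.genes[pos])} == {
                genes[pos], other[pos]
            }

    def test_invalid_cut_rejected(self):
        with pytest.raises(EvolutionError):
            one_point_crossover(
                Individual(genes=[1, 2]), Individual(genes=[3, 4]), cut_point=2
            )


class TestMutation:
    def test_step_is_power_of_two_and_in_bounds(self):
        rng = np.random.default_rng(0)
        powers = {1 << x for x in range(10)}
        for g in (0, 1, 511, 1000, DAC_MAX):
            for _ in range(200):
                new = mutate_gene(g, rng)
                assert 0 <= new <= DAC_MAX
                assert abs(new - g) in powers

    def test_lower_boundary_forces_addition(self):
        rng = np.random.default_rng(1)
        assert all(mutate_gene(0, rng) >= 1 for _ in range(100))

    def test_magnitudes_follow_renormalized_uniform_law(self):
        # at the boundary all ten magnitudes of one sign are valid:
        # exactly uniform.  At mid-range the +-512 steps are both out of
        # bounds, so the nine reachable magnitudes carry 2/18 each.
        rng = np.random.default_rng(2)
        draws0 = np.array([abs(mutate_gene(0, rng)) for _ in range(100000)])
        for x in range(10):
            assert abs(np.mean(draws0 == (1 << x)) - 0.1) < 0.01
        draws511 = np.array([abs(mutate_gene(511, rng) - 511) for _ in range(100000)])
        assert not np.any(draws511 == 512)
        for x in range(9):
            assert abs(np.mean(draws511 == (1 << x)) - 1 / 9) < 0.01

    def test_individual_mutation_rates(self):
        rng = np.random.default_rng(3)
        ind = Individual(genes=[100, 200, 300], fitness=1.0)
        same = mutate_individual(ind, p_gen=0.0, rng=rng)
        np.testing.assert_array_equal(same.genes, ind.genes)
        assert same.fitness == 1.0
        changed = mutate_individual(ind, p_gen=1.0, rng=rng)
        assert np.all(changed.genes != ind.genes)
        assert changed.fitness is None


def _toy(genes, rng):
    return float(abs(int(genes[0]) - 400) + abs(int(genes[1]) - 600))


class TestEvolve:
    def test_best_fitness_non_increasing_with_deterministic_evaluator(self):
        for seed in range(10):
            res = evolve(_toy, GAConfig(seed=seed), 2)
            bests = [r.best_fitness for r in res.records]
            assert all(b2 <= b1 for b1, b2 in zip(bests, bests[1:]))

    def test_toy_problem_converges(self):
        # endgame needs rare unit-step mutations; by generation 30 the
        # best is within a few DAC codes, and exact zero is reached well
        # within 100 generations
        for seed in range(3):
            res = evolve(_toy, GAConfig(seed=seed, n_generations=100), 2)
            bests = [r.best_fitness for r in res.records]
            assert bests[29] <= 4.0
            assert min(bests) == 0.0

    def test_population_size_and_bounds_every_generation(self):
        res = evolve(_toy, GAConfig(seed=1), 2)
        assert len(res.records) == 30
        for rec in res.records:
            assert rec.genes.shape == (50, 2)
            assert rec.genes.min() >= 0 and rec.genes.max() <= DAC_MAX
            assert rec.best_fitness == rec.fitnesses.min()

    def test_identical_config_identical_history(self):
        r1 = evolve(_toy, GAConfig(seed=9), 2)
        r2 = evolve(_toy, GAConfig(seed=9), 2)
        for a, b in zip(r1.records, r2.records):
            np.testing.assert_array_equal(a.genes, b.genes)
            np.testing.assert_array_equal(a.fitnesses, b.fitnesses)

    def test_early_stop_on_threshold(self):
        res = evolve(_toy, GAConfig(seed=1, stop_fitness=50.0), 2)
        assert res.n_generations_run < 30
        assert res.best.fitness <= 50.0

    def test_evaluator_degenerate_observation_maps_to_sentinel(
        self, substrate_cfg, proto, monkeypatch
    ):
        import cabletune.evolution as evo
        from cabletune.experiment import DegenerateFitError

        def boom(*a, **k):
            raise DegenerateFitError("flat")

        monkeypatch.setattr(evo.xp, "run_attenuation_experiment", boom)
        evaluator = make_evaluator(
            "lambda_only", TargetObservation(lambda_hat=1.0), substrate_cfg, proto
        )
        assert evaluator(np.array([0, 0]), np.random.default_rng(0)) == WORST_FITNESS
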