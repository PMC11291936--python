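"""Stress, fitness, mating, inheritance and generational replacement."""

import numpy as np
import pytest

from epiplast.development import DevelopmentConfig
from epiplast.genome import NeutralGenome, ResponseGenome, SensitivityGenome
from epiplast.population import (
    Individual,
    SelectionParams,
    advance_generation,
    fitness,
    form_pairs,
    found_population,
    make_offspring,
    population_fitness,
    reproduce,
    stress,
)

PARAMS = SelectionParams()


class TestStress:
    def test_zero_at_matching_phenotype(self):
        assert stress(2.0, 2.0, 2.2) == 0.0

    def test_one_tolerance_unit_of_mismatch(self):
        # 1 - exp(-1/2) at |x - p| = gamma
        assert stress(4.4, 2.2, 2.2) == pytest.approx(0.3934693402873666, rel=1e-12)

    def test_saturates_below_one_for_huge_mismatch(self):
        rho = stress(1e6 * 2.2, 0.0, 2.2)
        assert rho <= 1.0
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_mismatch(self):
        mism = np.linspace(0, 50, 200)
        rho = stress(mism, 0.0, 2.2)
        assert np.all(np.diff(rho) >= 0)
        assert np.all((rho >= 0) & (rho <= 1))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            stress(1.0, 0.0, 0.0)


class TestFitness:
    def test_baseline_at_carrying_capacity_equals_r(self):
        assert fitness(2.0, 0.0, 1000, 2.0, PARAMS) == pytest.approx(1.0)

    def test_cost_term_subtracts_omega_c(self):
        params = SelectionParams(C=0.5)
        assert fitness(2.0, 0.03, 1000, 2.0, params) == pytest.approx(0.985)

    def test_vanishes_in_full_stress_limit_without_cost(self):
        assert fitness(1e9, 0.0, 1000, 0.0, PARAMS) == pytest.approx(0.0, abs=1e-9)

    def test_bounded_by_density_baseline_and_decreasing_in_omega(self, rng):
        params = SelectionParams(C=0.3, K=500.0)
        x = rng.normal(size=50)
        n = 400
        w0 = fitness(x, 0.0, n, 0.0, params)
        w1 = fitness(x, 1.0, n, 0.0, params)
        cap = params.R * np.exp(1 - n / params.K)
        assert np.all(w0 <= cap + 1e-12)
        assert np.all(w1 < w0)

    def test_can_go_negative_with_cost(self):
        params = SelectionParams(C=1.0)
        assert fitness(0.0, 5.0, 1000, 0.0, params) < 0


class TestPairing:
    def found(self, n, rng, omega=0.0):
        return found_population(n, rng, fixed_omega=omega)

    def test_no_males_signals_extinction(self, rng):
        pop = self.found(1, rng)  # M = floor(1/2) = 0
        mothers, fathers, rates = form_pairs(pop, 0.0, PARAMS, rng)
        assert mothers.size == fathers.size == 0

    def test_single_male_fathers_everyone(self, rng):
        pop = self.found(7, rng)
        # force a 1-male split by shrinking: N=2 -> M=1, F=1; use N=3 -> M=1, F=2
        pop3 = self.found(3, rng)
        mothers, fathers, _ = form_pairs(pop3, 0.0, PARAMS, rng)
        assert np.unique(fathers).size == 1
        assert mothers.size == 2

    def test_pair_rate_is_clamped_nonnegative(self, rng):
        pop = self.found(10, rng, omega=10.0)
        params = SelectionParams(C=1.0)  # W = -10 + baseline < 0 for everyone
        _, _, rates = form_pairs(pop, 0.0, params, rng)
        assert np.all(rates == 0.0)

    def test_expected_offspring_two_per_unit_fitness_pair(self, rng):
        # W = 1 for all (x = p, N = K): pair rate 2, E[next N] = 2F
        totals = []
        for rep in range(300):
            r = np.random.default_rng(rep)
            pop = found_population(100, r)
            pop.x = np.zeros(100)  # perfect match
            params = SelectionParams(K=100.0)
            nxt = reproduce(pop, 0.0, params, r)
            totals.append(nxt.N)
        mean = np.mean(totals)
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(mean - 100.0) < 3 * se + 1e-9


def random_parent(rng, with_aux=False):
    genome = ResponseGenome(rng.normal(size=(10, 2)), B=1)
    sens = SensitivityGenome(rng.normal(size=2)) if with_aux else None
    neut = NeutralGenome(rng.normal(size=2)) if with_aux else None
    return Individual.at_birth(genome, sensitivity_genome=sens, neutral_genome=neut)


class TestInheritance:
    def test_homozygous_parents_transmit_exactly_without_mutation(self, rng):
        alleles = np.tile(np.arange(10.0)[:, None], (1, 2))
        mother = Individual.at_birth(ResponseGenome(alleles, B=1))
        father = Individual.at_birth(ResponseGenome(alleles * -1, B=1))
        params = SelectionParams(mu_m=0.0)
        child = make_offspring(mother, father, params, rng)
        np.testing.assert_array_equal(
            np.sort(child.response_genome.alleles, axis=1),
            np.sort(np.column_stack([alleles[:, 0], -alleles[:, 0]]), axis=1),
        )

    def test_zero_effect_mutations_change_nothing(self, rng):
        mother, father = random_parent(rng), random_parent(rng)
        certain = SelectionParams(mu_m=1.0, sigma_m=0.0)
        child = make_offspring(mother, father, certain, rng)
        for j in range(10):
            for k, parent in enumerate((mother, father)):
                assert child.response_genome.alleles[j, k] in parent.response_genome.alleles[j]

    def test_mendelian_transmission_conserves_allele_multiset(self, rng):
        mother, father = random_parent(rng, True), random_parent(rng, True)
        params = SelectionParams(mu_m=0.0)
        for _ in range(20):
            child = make_offspring(mother, father, params, rng)
            for j in range(10):
                assert child.response_genome.alleles[j, 0] in mother.response_genome.alleles[j]
                assert child.response_genome.alleles[j, 1] in father.response_genome.alleles[j]
            assert child.sensitivity_genome.lambda_alleles[0] in mother.sensitivity_genome.lambda_alleles
            assert child.neutral_genome.nu_alleles[1] in father.neutral_genome.nu_alleles

    def test_offspring_born_unmarked_with_recomputed_traits(self, rng):
        mother, father = random_parent(rng, True), random_parent(rng, True)
        child = make_offspring(mother, father, PARAMS, rng)
        np.testing.assert_array_equal(child.tags, np.ones(9, dtype=np.uint8))
        assert child.x == pytest.approx(child.response_genome.alleles.sum())
        assert child.omega == pytest.approx(
            abs(child.sensitivity_genome.lambda_alleles.sum()) / 42.0
        )

    def test_mutation_incidence_matches_rate_binomially(self, rng):
        # 1e6 transmitted allele copies at mu_m = 1e-4: expect 100 +/- 3*10
        from epiplast.population import _transmit

        n_off, L = 50_000, 10
        alleles = np.zeros((100, L, 2))
        mothers = rng.integers(0, 100, n_off)
        fathers = rng.integers(0, 100, n_off)
        params = SelectionParams(mu_m=1e-4, sigma_m=1.0)
        child = _transmit(alleles, mothers, fathers, params, rng)
        n_copies = child.size
        assert n_copies == 1_000_000
        n_mutated = int(np.count_nonzero(child))
        expected = params.mu_m * n_copies
        assert abs(n_mutated - expected) < 3 * np.sqrt(expected)


class TestGenerationTurnover:
    def test_single_individual_population_goes_extinct(self, rng):
        pop = found_population(1, rng)
        nxt = advance_generation(pop, 0.0, PARAMS, DevelopmentConfig(tau=1), rng)
        assert nxt.extinct

    def test_extinct_population_stays_extinct(self, rng):
        pop = found_population(2, rng)
        empty = pop._empty_like(t=1)
        nxt = advance_generation(empty, 0.0, PARAMS, DevelopmentConfig(tau=1), rng)
        assert nxt.extinct and nxt.t == 2

    def test_neutral_inheritance_is_unbiased(self):
        # mu_m = 0, omega = 0: allele frequencies move only by drift
        founder_means, offspring_means = [], []
        params = SelectionParams(mu_m=0.0, K=60.0)
        for rep in range(1000):
            rng = np.random.default_rng(rep)
            pop = found_population(60, rng)
            pop.x = np.zeros(60)  # remove selection on the trait entirely
            founder_means.append(pop.alleles.mean())
            nxt = reproduce(pop, 0.0, params, rng)
            if nxt.N:
                offspring_means.append(nxt.alleles.mean())
        diff = np.mean(offspring_means) - np.mean(founder_means)
        se = np.std(offspring_means) / np.sqrt(len(offspring_means))
        assert abs(diff) < 3 * se + 1e-12

    def test_haploid_clonal_offspring_copy_parent_without_mutation(self, rng):
        pop = found_population(40, rng, ploidy=1, fixed_omega=0.0)
        pop.x = np.zeros(40)
        params = SelectionParams(mu_m=0.0, K=40.0)
        nxt = reproduce(pop, 0.0, params, rng)
        assert nxt.N > 0
        parent_rows = {tuple(row) for row in pop.alleles.reshape(40, -1).round(12)}
        child_rows = {tuple(row) for row in nxt.alleles.reshape(nxt.N, -1).round(12)}
        assert child_rows <= parent_rows

    def test_population_fitness_uses_current_density(self, rng):
        pop = found_population(500, rng)
        w = population_fitness(pop, 0.0, SelectionParams(K=1000.0))
        assert w.shape == (500,)
        assert np.all(w <= np.exp(0.5) + 1e-12)
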