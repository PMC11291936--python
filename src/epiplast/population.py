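"""Selection, mating, reproduction and generational replacement.

Generations are discrete and non-overlapping. Each generation the population
of N individuals is split into M = floor(N/2) males and F = N - M females by
random permutation; every female mates once with a male drawn uniformly with
replacement, and the pair's offspring count is Poisson with rate
max(0, W_female + W_male), where individual fitness is

    W(x, omega, N) = (1 - rho(x)) * R * exp(1 - N/K) - omega * C,

with the stress

    rho(x) = 1 - exp(-((x - p) / gamma)^2 / 2)

evaluated at the end-of-development phenotype. Offspring inherit one allele
per parent per locus (free recombination), each inherited allele copy
mutates with probability mu_m by adding a N(0, sigma_m^2) deviate, and the
offspring cohort wholly replaces the parents; a total offspring count of
zero is extinction.

The vectorised :class:`Population` container (one array per genomic
component) is the engine's working representation; :class:`Individual` is
the single-organism view used by the per-individual API and worked examples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .development import DevelopmentConfig, develop_arrays
from .genome import (
    NeutralGenome,
    ResponseGenome,
    SensitivityGenome,
    combine_sensitivity,
    compute_phenotype,
    compute_sensitivity,
    init_response_alleles,
    phenotypes_from_locus_sums,
)

__all__ = [
    "SelectionParams",
    "Individual",
    "Population",
    "stress",
    "fitness",
    "population_fitness",
    "form_pairs",
    "make_offspring",
    "reproduce",
    "advance_generation",
    "found_population",
]


@dataclass(frozen=True)
class SelectionParams:
    """Demographic and genetic parameters of selection and inheritance.

    Defaults follow the standard parameterisation: intrinsic reproduction
    factor R = 1, carrying capacity K = 1000, stress tolerance gamma = 2.2,
    plasticity cost C = 0, allelic mutation rate mu_m = 1e-4 per locus per
    generation with effect standard deviation sigma_m = 1.
    """

    R: float = 1.0
    K: float = 1000.0
    gamma: float = 2.2
    C: float = 0.0
    mu_m: float = 1e-4
    sigma_m: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if not 0.0 <= self.mu_m <= 1.0:
            raise ValueError("mu_m must be in [0, 1]")
        if self.sigma_m < 0 or self.C < 0 or self.R <= 0:
            raise ValueError("need sigma_m >= 0, C >= 0, R > 0")


@dataclass(frozen=True)
class Individual:
    """Single-organism view: genomes, activation tags, developed phenotype."""

    response_genome: ResponseGenome
    tags: np.ndarray
    x: float
    omega: float = 0.0
    sensitivity_genome: SensitivityGenome | None = None
    neutral_genome: NeutralGenome | None = None
    sex: str | None = None

    @classmethod
    def at_birth(
        cls,
        response_genome: ResponseGenome,
        sensitivity_genome: SensitivityGenome | None = None,
        neutral_genome: NeutralGenome | None = None,
        fixed_omega: float = 0.0,
        combination: str = "divide",
    ) -> "Individual":
        """Newborn: all tags active, phenotype = unconditional allele sum."""
        tags = np.ones(response_genome.n_plastic, dtype=np.uint8)
        omega = (
            compute_sensitivity(sensitivity_genome, combination)
            if sensitivity_genome is not None
            else float(fixed_omega)
        )
        return cls(
            response_genome=response_genome,
            tags=tags,
            x=compute_phenotype(response_genome, tags),
            omega=omega,
            sensitivity_genome=sensitivity_genome,
            neutral_genome=neutral_genome,
        )


@dataclass
class Population:
    """Array-of-components population; N = 0 marks extinction.

    ``alleles`` is ``(N, L, ploidy)``; ``lam`` and ``nu`` are
    ``(N, ploidy)`` or ``None`` when the sensitivity / neutral loci are not
    genetically encoded (fixed-omega protocols). ``omega`` always holds the
    realised sensitivity of each individual.
    """

    alleles: np.ndarray
    B: int
    tags: np.ndarray
    x: np.ndarray
    omega: np.ndarray
    lam: np.ndarray | None = None
    nu: np.ndarray | None = None
    scale_s: float = 42.0
    combination: str = "divide"
    t: int = 0

    @property
    def N(self) -> int:
        return self.alleles.shape[0]

    @property
    def L(self) -> int:
        return self.alleles.shape[1]

    @property
    def ploidy(self) -> int:
        return self.alleles.shape[2]

    @property
    def extinct(self) -> bool:
        return self.N == 0

    def locus_sums(self) -> np.ndarray:
        return self.alleles.sum(axis=2)

    def x_unaltered(self) -> np.ndarray:
        """Phenotypes with every plastic locus active (no epigenetic marks)."""
        sums = self.locus_sums()
        return phenotypes_from_locus_sums(
            sums, self.B, np.ones((self.N, self.L - self.B), dtype=np.uint8)
        )

    def neutral_trait(self) -> np.ndarray:
        """Summed neutral allele values per individual (nu_1 + nu_2)."""
        if self.nu is None:
            raise ValueError("population has no neutral locus")
        return self.nu.sum(axis=1)

    def neutral_omega_null(self) -> np.ndarray:
        """The neutral marker pushed through the sensitivity map |.|/s.

        Drift-only null distribution against which evolved omega is judged.
        """
        return combine_sensitivity(
            self.neutral_trait(), self.scale_s, self.combination
        )

    def individuals(self) -> list[Individual]:
        out = []
        for i in range(self.N):
            sens = (
                SensitivityGenome(self.lam[i], self.scale_s)
                if self.lam is not None
                else None
            )
            neut = NeutralGenome(self.nu[i]) if self.nu is not None else None
            out.append(
                Individual(
                    response_genome=ResponseGenome(self.alleles[i], self.B),
                    tags=self.tags[i].copy(),
                    x=float(self.x[i]),
                    omega=float(self.omega[i]),
                    sensitivity_genome=sens,
                    neutral_genome=neut,
                )
            )
        return out

    def _empty_like(self, t: int) -> "Population":
        zeros = lambda shape: np.zeros(shape)  # noqa: E731
        return Population(
            alleles=zeros((0, self.L, self.ploidy)),
            B=self.B,
            tags=np.zeros((0, self.L - self.B), dtype=np.uint8),
            x=zeros(0),
            omega=zeros(0),
            lam=None if self.lam is None else zeros((0, self.ploidy)),
            nu=None if self.nu is None else zeros((0, self.ploidy)),
            scale_s=self.scale_s,
            combination=self.combination,
            t=t,
        )


def stress(x, p, gamma: float):
    """Individual stress rho in [0, 1): Gaussian-type in the mismatch.

    Zero at x = p, monotone in |x - p|, saturating below 1; gamma sets the
    tolerance (small gamma = strong selection).
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    out = -np.expm1(-0.5 * ((np.asarray(x, dtype=float) - p) / gamma) ** 2)
    if out.ndim == 0:
        return float(out)
    return out


def fitness(x, omega, N: int, p, params: SelectionParams):
    """Expected-offspring fitness W; density-dependent, may go negative if C > 0."""
    if np.any(np.asarray(N) < 1):
        raise ValueError("N must be >= 1 to evaluate density dependence")
    rho = stress(x, p, params.gamma)
    out = (1.0 - np.asarray(rho)) * params.R * np.exp(1.0 - N / params.K) - np.asarray(
        omega, dtype=float
    ) * params.C
    if out.ndim == 0:
        return float(out)
    return out


def population_fitness(pop: Population, p: float, params: SelectionParams) -> np.ndarray:
    """Fitness of every individual at the current population size."""
    return np.asarray(fitness(pop.x, pop.omega, pop.N, p, params))


def form_pairs(
    pop: Population,
    p: float,
    params: SelectionParams,
    rng: np.random.Generator,
    W: np.ndarray | None = None,
):
    """Assign sexes, mate every female, and return the pair Poisson rates.

    Sexes are assigned by random permutation: the first floor(N/2)
    individuals are males, the rest females. Returns
    ``(mothers, fathers, rates)`` index/rate arrays; all empty when the
    population lacks males or females (the extinction signal).
    """
    N = pop.N
    empty = (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
    if N == 0:
        return empty
    perm = rng.permutation(N)
    M = N // 2
    males, females = perm[:M], perm[M:]
    if males.size == 0 or females.size == 0:
        return empty
    if W is None:
        W = population_fitness(pop, p, params)
    fathers = males[rng.integers(0, males.size, size=females.size)]
    rates = np.maximum(W[females] + W[fathers], 0.0)
    return females, fathers, rates


def _gametes(
    alleles: np.ndarray, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype per offspring: free recombination across loci."""
    n, L = parents.size, alleles.shape[1]
    picks = rng.integers(0, alleles.shape[2], size=(n, L))
    return alleles[parents[:, None], np.arange(L)[None, :], picks]


def _mutate(
    values: np.ndarray, mu_m: float, sigma_m: float, rng: np.random.Generator
) -> np.ndarray:
    mask = rng.random(values.shape) < mu_m
    k = int(mask.sum())
    if k == 0:
        return values
    out = values.copy()
    out[mask] += rng.normal(0.0, sigma_m, size=k)
    return out


def _transmit(
    alleles: np.ndarray,
    mothers: np.ndarray,
    fathers: np.ndarray,
    params: SelectionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploid transmission: one freely recombined, mutated haplotype per parent."""
    ga = np.stack(
        [_gametes(alleles, mothers, rng), _gametes(alleles, fathers, rng)], axis=-1
    )
    return _mutate(ga, params.mu_m, params.sigma_m, rng)


def make_offspring(
    mother: Individual,
    father: Individual,
    params: SelectionParams,
    rng: np.random.Generator,
    combination: str = "divide",
) -> Individual:
    """Build one diploid offspring from two parents.

    Uses the same transmission kernel as the population engine: per locus,
    one allele copy is drawn uniformly from each parent (no linkage), then
    each inherited copy mutates with probability mu_m. Tags start all
    active; omega is recomputed from the inherited lambda alleles.
    """
    mg, fg = mother.response_genome, father.response_genome
    if mg.ploidy != 2 or fg.ploidy != 2:
        raise ValueError("make_offspring requires diploid parents")
    stacked = np.stack([mg.alleles, fg.alleles])  # (2, L, 2)
    child_alleles = _transmit(
        stacked, np.array([0]), np.array([1]), params, rng
    )[0]
    genome = ResponseGenome(child_alleles, B=mg.B)

    sens = neut = None
    if mother.sensitivity_genome is not None and father.sensitivity_genome is not None:
        lam = np.stack(
            [
                mother.sensitivity_genome.lambda_alleles,
                father.sensitivity_genome.lambda_alleles,
            ]
        )[:, None, :]
        child_lam = _transmit(lam, np.array([0]), np.array([1]), params, rng)[0, 0]
        sens = SensitivityGenome(child_lam, mother.sensitivity_genome.scale_s)
    if mother.neutral_genome is not None and father.neutral_genome is not None:
        nu = np.stack(
            [mother.neutral_genome.nu_alleles, father.neutral_genome.nu_alleles]
        )[:, None, :]
        child_nu = _transmit(nu, np.array([0]), np.array([1]), params, rng)[0, 0]
        neut = NeutralGenome(child_nu)

    return Individual.at_birth(
        genome,
        sensitivity_genome=sens,
        neutral_genome=neut,
        fixed_omega=mother.omega if sens is None else 0.0,
        combination=combination,
    )


def reproduce(
    pop: Population,
    p: float,
    params: SelectionParams,
    rng_demography: np.random.Generator,
    rng_response: np.random.Generator | None = None,
    rng_aux: np.random.Generator | None = None,
    aux_mu_m: float | None = None,
    W: np.ndarray | None = None,
) -> Population:
    """Produce the next generation; the offspring wholly replace the parents.

    Separate streams for demography (sexes, mates, Poisson counts), response
    inheritance, and sensitivity/neutral inheritance keep the response-trait
    dynamics identical whether or not the auxiliary loci are simulated.
    ``aux_mu_m`` overrides the mutation rate of the lambda/nu loci (default:
    the shared mu_m, as all allele types mutate alike).
    """
    if rng_response is None:
        rng_response = rng_demography
    if rng_aux is None:
        rng_aux = rng_response
    if pop.ploidy == 1:
        return _reproduce_asexual(
            pop, p, params, rng_demography, rng_response, rng_aux, aux_mu_m, W
        )
    mothers, fathers, rates = form_pairs(pop, p, params, rng_demography, W=W)
    if mothers.size == 0:
        return pop._empty_like(pop.t + 1)
    counts = rng_demography.poisson(rates)
    mi = np.repeat(mothers, counts)
    fi = np.repeat(fathers, counts)
    return _build_offspring(pop, mi, fi, params, rng_response, rng_aux, aux_mu_m)


def _reproduce_asexual(
    pop, p, params, rng_demography, rng_response, rng_aux, aux_mu_m, W
):
    """Haploid clonal reproduction: offspring ~ Poisson(max(0, 2 W_i)).

    The doubled rate keeps the per-capita expected offspring equal to the
    diploid two-parent scheme, where each pair draws Poisson(W_m + W_f).
    """
    if pop.N == 0:
        return pop._empty_like(pop.t + 1)
    if W is None:
        W = population_fitness(pop, p, params)
    counts = rng_demography.poisson(np.maximum(2.0 * W, 0.0))
    parents = np.repeat(np.arange(pop.N), counts)
    if parents.size == 0:
        return pop._empty_like(pop.t + 1)
    return _build_offspring(pop, parents, None, params, rng_response, rng_aux, aux_mu_m)


def _build_offspring(pop, mi, fi, params, rng_response, rng_aux, aux_mu_m):
    if mi.size == 0:
        return pop._empty_like(pop.t + 1)
    if fi is None:  # clonal: copy + mutate
        child_alleles = _mutate(
            pop.alleles[mi], params.mu_m, params.sigma_m, rng_response
        )
    else:
        child_alleles = _transmit(pop.alleles, mi, fi, params, rng_response)

    aux_params = (
        params
        if aux_mu_m is None
        else dataclasses.replace(params, mu_m=float(aux_mu_m))
    )
    lam = nu = None
    if pop.lam is not None:
        lam = _transmit_aux(pop.lam, mi, fi, aux_params, rng_aux)
    if pop.nu is not None:
        nu = _transmit_aux(pop.nu, mi, fi, aux_params, rng_aux)

    n_off = mi.size
    tags = np.ones((n_off, pop.L - pop.B), dtype=np.uint8)
    x = phenotypes_from_locus_sums(child_alleles.sum(axis=2), pop.B, tags)
    if lam is not None:
        omega = np.asarray(
            combine_sensitivity(lam.sum(axis=1), pop.scale_s, pop.combination)
        )
    else:
        omega = pop.omega[mi]
    return Population(
        alleles=child_alleles,
        B=pop.B,
        tags=tags,
        x=x,
        omega=omega,
        lam=lam,
        nu=nu,
        scale_s=pop.scale_s,
        combination=pop.combination,
        t=pop.t + 1,
    )


def _transmit_aux(values, mi, fi, params, rng):
    """Transmission for a single-locus (N, ploidy) component (lambda or nu)."""
    if fi is None:
        return _mutate(values[mi], params.mu_m, params.sigma_m, rng)
    return _transmit(values[:, None, :], mi, fi, params, rng)[:, 0, :]


def develop_population(
    pop: Population, p: float, dev: DevelopmentConfig, rng: np.random.Generator
):
    """Develop the whole cohort in place; returns the optional trajectory."""
    tags, x, traj = develop_arrays(
        pop.locus_sums(),
        pop.B,
        pop.tags,
        pop.omega,
        p,
        dev.tau,
        rng,
        record=dev.record_trajectories,
    )
    pop.tags, pop.x = tags, x
    return traj


def advance_generation(
    pop: Population,
    p: float,
    params: SelectionParams,
    dev: DevelopmentConfig,
    rng: np.random.Generator,
) -> Population:
    """One full generation: develop, evaluate fitness, mate, replace.

    Single-stream convenience wrapper around :func:`develop_population` and
    :func:`reproduce` (the protocol engine uses separate streams so that the
    metrics can be recorded between the two phases). An extinct input is
    returned unchanged except for the generation counter.
    """
    if pop.extinct:
        return pop._empty_like(pop.t + 1)
    develop_population(pop, p, dev, rng)
    W = population_fitness(pop, p, params)
    return reproduce(pop, p, params, rng, W=W)


def found_population(
    n: int,
    rng: np.random.Generator,
    L: int = 10,
    B: int = 1,
    ploidy: int = 2,
    sigma_G: float = 1.0,
    distribution: str = "normal",
    scale_s: float = 42.0,
    combination: str = "divide",
    fixed_omega: float = 0.0,
    encode_sensitivity: bool = False,
    track_neutral: bool = False,
) -> Population:
    """Found a population from the stated sampling distributions.

    Response alleles ~ N(0, sigma_G^2 / (ploidy L)) per copy by default;
    lambda and nu alleles start at 0 when encoded (the non-plastic founding
    condition of the plasticity-evolution protocol); tags all active.
    """
    alleles = init_response_alleles(
        n, L, sigma_G, distribution=distribution, rng=rng, ploidy=ploidy
    )
    lam = np.zeros((n, ploidy)) if encode_sensitivity else None
    nu = np.zeros((n, ploidy)) if track_neutral else None
    omega = (
        np.zeros(n)
        if encode_sensitivity
        else np.full(n, float(fixed_omega))
    )
    tags = np.ones((n, L - B), dtype=np.uint8)
    pop = Population(
        alleles=alleles,
        B=B,
        tags=tags,
        x=phenotypes_from_locus_sums(alleles.sum(axis=2), B, tags),
        omega=omega,
        lam=lam,
        nu=nu,
        scale_s=scale_s,
        combination=combination,
        t=0,
    )
    return pop
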