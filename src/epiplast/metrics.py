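"""Per-generation population summaries.

Three diagnostics track what the plasticity mechanism does to a population:

* mean stress, the arithmetic mean of individual rho values — population-
  level mismatch with the environment;
* genetic load, (W_max^o - W_mean^o) / W_max^o computed on fitnesses with
  every plastic locus active (the epigenetically unaltered reference) —
  accumulation of suboptimal genotypes shielded by plasticity;
* variance ratio V_tau / V_0, the end- over start-of-development sum of
  squared phenotype deviations — below 1 means canalization (heterogeneous
  genotypes converging on matching phenotypes), above 1 means epimutation-
  driven variance release (developmental noise / uncovered cryptic
  variation).

Undefined metrics (extinct population, zero pre-development variance,
non-positive maximal unaltered fitness) are returned as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Population, SelectionParams, fitness, stress

__all__ = [
    "GenerationRecord",
    "population_stress",
    "genetic_load",
    "variance_ratio",
    "record_generation",
]


@dataclass(frozen=True)
class GenerationRecord:
    """Summary of one generation, taken after development, before selection."""

    t: int
    p: float
    N: int
    mean_stress: float
    genetic_load: float
    variance_ratio: float
    mean_omega: float
    sd_omega: float
    mean_neutral: float = float("nan")
    sd_neutral: float = float("nan")
    neutral_omega_null: float = float("nan")
    extinct: bool = False


def population_stress(pop: Population, p: float, gamma: float) -> float:
    """Mean individual stress (NaN for an empty population)."""
    if pop.N == 0:
        return float("nan")
    return float(np.mean(stress(pop.x, p, gamma)))


def genetic_load(
    pop: Population, p: float, N_eval: int, params: SelectionParams
) -> float:
    """Relative fitness shortfall of the epigenetically unaltered population.

    Every individual's phenotype is recomputed with all tags active, Eq.-4
    style fitness (including the density and cost terms) is evaluated at the
    shared ``N_eval`` and ``p``, and (max - mean) / max is returned — the
    reference genotype being the best one currently present, adequate or
    not. NaN when the population is empty or the maximal unaltered fitness
    is not positive.
    """
    if pop.N == 0:
        return float("nan")
    w = np.asarray(fitness(pop.x_unaltered(), pop.omega, N_eval, p, params))
    w_max = w.max()
    if w_max <= 0:
        return float("nan")
    return float((w_max - w.mean()) / w_max)


def variance_ratio(x_start: np.ndarray, x_end: np.ndarray) -> float:
    """Sum-of-squared-deviations ratio V_tau / V_0 across development.

    Both vectors must come from the same cohort (same length >= 2). The raw
    sums are used; since the same N divides numerator and denominator, the
    ratio equals the ratio of variances. NaN when the cohort shows no
    pre-development variance.
    """
    x_start = np.asarray(x_start, dtype=float)
    x_end = np.asarray(x_end, dtype=float)
    if x_start.shape != x_end.shape or x_start.ndim != 1 or x_start.size < 2:
        raise ValueError("x_start and x_end must be equal-length vectors (n >= 2)")
    v0 = np.sum((x_start - x_start.mean()) ** 2)
    if v0 == 0:
        return float("nan")
    vt = np.sum((x_end - x_end.mean()) ** 2)
    return float(vt / v0)


def record_generation(
    pop: Population,
    p: float,
    params: SelectionParams,
    x_start: np.ndarray,
    extinct: bool = False,
) -> GenerationRecord:
    """Assemble the per-generation record for a developed population."""
    has_nu = pop.nu is not None and pop.N > 0
    neutral = pop.neutral_trait() if has_nu else None
    null = pop.neutral_omega_null() if has_nu else None
    return GenerationRecord(
        t=pop.t,
        p=float(p),
        N=pop.N,
        mean_stress=population_stress(pop, p, params.gamma),
        genetic_load=genetic_load(pop, p, pop.N, params),
        variance_ratio=(
            variance_ratio(x_start, pop.x) if pop.N >= 2 else float("nan")
        ),
        mean_omega=float(np.mean(pop.omega)) if pop.N else float("nan"),
        sd_omega=float(np.std(pop.omega)) if pop.N else float("nan"),
        mean_neutral=float(np.mean(neutral)) if has_nu else float("nan"),
        sd_neutral=float(np.std(neutral)) if has_nu else float("nan"),
        neutral_omega_null=float(np.mean(null)) if has_nu else float("nan"),
        extinct=extinct,
    )
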