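"""Deterministic worked-example genotypes and cohorts.

The simulator generates its own founders; this module pins the small
hand-checkable scenarios used by the tests and the documentation: the
"even numbers 2..20" genotype whose attainable-phenotype set is known in
closed form, the four many-to-one genotypes that all express x = 2, and
founder cohorts with non-normal (asymmetric / bimodal) trait distributions.

Every expected value carries a provenance tag: ``closed-form`` for values
that follow immediately from the definitions, ``enumeration`` for values
regenerated by the brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import (
    ActivationState,
    ResponseGenome,
    enumerate_attainable_phenotypes,
    init_response_alleles,
)

__all__ = ["Fixture", "fixture_even_numbers", "fixture_many_to_one", "fixture_cohort"]


@dataclass(frozen=True)
class Fixture:
    """Named genotypes plus a map of operation -> (expected value, provenance)."""

    name: str
    genotypes: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def fixture_even_numbers() -> Fixture:
    """All-ones diploid genome, L=10, B=1: one genotype, many phenotypes.

    With every allele equal to 1, each active locus contributes 2, so the
    attainable phenotypes are exactly the even numbers 2, 4, ..., 20 — a
    10-element set over the 2^9 activation states of the plastic loci.
    """
    genome = ResponseGenome(np.ones((10, 2)), B=1)
    attainable = enumerate_attainable_phenotypes(genome)
    return Fixture(
        name="even_numbers",
        genotypes={"all_ones": genome},
        expected={
            "attainable_set": (attainable, "enumeration"),
            "attainable_size": (10, "closed-form"),
            "min_attainable": (2.0, "closed-form"),
            "max_attainable": (20.0, "closed-form"),
        },
    )


def fixture_many_to_one(L: int = 10) -> Fixture:
    """Four distinct genotypes that all express x = 2 when fully active.

    (a) both alleles equal to one at a single locus, all others zero;
    (b) one allele equal to one at two different loci, all others zero;
    (c) all 2L allele copies equal to 1/L;
    (d) heterogeneous positive and negative alleles averaging 1/L.
    """
    a = np.zeros((L, 2))
    a[0] = 1.0
    b = np.zeros((L, 2))
    b[0, 0] = 1.0
    b[1, 0] = 1.0
    c = np.full((L, 2), 1.0 / L)
    # (d): alternate +/- values around the 1/L mean, summing to 2 overall
    d = np.full((L, 2), 1.0 / L)
    bump = np.tile([0.5, -0.5], L)[: 2 * L].reshape(L, 2)
    d = d + bump
    genotypes = {
        name: ResponseGenome(mat, B=1) for name, mat in zip("abcd", (a, b, c, d))
    }
    tags = ActivationState.all_active(L - 1)
    return Fixture(
        name="many_to_one",
        genotypes={**genotypes, "tags": tags},
        expected={"phenotype": (2.0, "closed-form")},
    )


def fixture_cohort(
    distribution: str, n: int, rng: np.random.Generator, L: int = 10, B: int = 1
):
    """Founder cohort whose pre-development trait distribution has a named shape.

    ``normal`` uses unit per-copy allele variance (trait sd sqrt(2L));
    ``bimodal`` has trait modes pinned at -2 and +2 (component sd 0.5);
    ``asymmetric`` is right-skewed with mean 0 (mean-centred lognormal,
    sigma = 0.5). Returns the ``(n, L, 2)`` allele array.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if distribution == "normal":
        return init_response_alleles(
            n, L, sigma_G=float(np.sqrt(2 * L)), distribution="normal", rng=rng
        )
    return init_response_alleles(n, L, sigma_G=1.0, distribution=distribution, rng=rng)
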