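"""Genotypes and the genotype-to-phenotype / genotype-to-sensitivity maps.

The response trait ``x`` is encoded additively by ``L`` loci with real-valued
alleles. The first ``B`` loci (``B >= 1``) are non-plastic and always
contribute; the remaining ``L - B`` plastic loci contribute only while their
activation tag ``a_j`` is 1, modelling methylation-controlled gene
expression:

    x = sum_{j<=B} (l_j1 + l_j2) + sum_{j>B} (l_j1 + l_j2) a_j

The sensitivity trait ``omega = |lambda_1 + lambda_2| / s`` (division is the
calibrated default; see :func:`compute_sensitivity`) controls how strongly
the daily epimutation rate reacts to trait-environment mismatch. A neutral
locus ``nu`` with the same inheritance rules but no fitness effect serves as
a drift control.

Because tags gate loci multiplicatively, a single genotype can realise up to
``2**(L-B)`` phenotypes, and many genotypes can realise the same phenotype
(many-to-one map). Both directions are exercised by the worked examples in
:mod:`epiplast.fixtures`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseGenome",
    "ActivationState",
    "SensitivityGenome",
    "NeutralGenome",
    "compute_phenotype",
    "phenotypes_from_locus_sums",
    "compute_sensitivity",
    "combine_sensitivity",
    "enumerate_attainable_phenotypes",
    "init_response_alleles",
    "genome_to_json",
    "genome_from_json",
]

SENSITIVITY_COMBINATIONS = ("divide", "multiply", "power")

#: Hard ceiling on L - B for exhaustive phenotype enumeration (2**20 states).
ENUMERATION_GUARD = 20


@dataclass(frozen=True)
class ResponseGenome:
    """Additive multilocus genome for the response trait.

    Parameters
    ----------
    alleles
        ``(L, ploidy)`` array of real allelic values ``l_jk``; ploidy is 1
        (haploid) or 2 (diploid). Values are unbounded reals; no clipping is
        applied anywhere in the package.
    B
        Number of non-plastic (baseline) loci, ``1 <= B <= L``.
    """

    alleles: np.ndarray
    B: int = 1

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.alleles, dtype=float))
        if a.ndim != 2 or a.shape[1] not in (1, 2):
            raise ValueError("alleles must be an (L, ploidy) array with ploidy 1 or 2")
        if not np.all(np.isfinite(a)):
            raise ValueError("allele values must be finite")
        if not 1 <= int(self.B) <= a.shape[0]:
            raise ValueError("need 1 <= B <= L (at least one non-plastic locus)")
        object.__setattr__(self, "alleles", a)
        object.__setattr__(self, "B", int(self.B))

    @property
    def L(self) -> int:
        return self.alleles.shape[0]

    @property
    def ploidy(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_plastic(self) -> int:
        return self.L - self.B

    def locus_sums(self) -> np.ndarray:
        """Per-locus allele sums ``l_j1 + l_j2`` (or the single haploid value)."""
        return self.alleles.sum(axis=1)


@dataclass(frozen=True)
class ActivationState:
    """Activation tags ``a_j`` of the plastic loci, one bit per locus."""

    tags: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tags, dtype=np.uint8).ravel()
        if not np.all((t == 0) | (t == 1)):
            raise ValueError("tags must be 0 or 1")
        object.__setattr__(self, "tags", t)

    @classmethod
    def all_active(cls, n_plastic: int) -> "ActivationState":
        """Birth state: every plastic locus expressed (no epigenetic marks)."""
        return cls(np.ones(n_plastic, dtype=np.uint8))

    def __len__(self) -> int:
        return self.tags.size


@dataclass(frozen=True)
class SensitivityGenome:
    """Single-locus genome of the sensitivity (plasticity) trait."""

    lambda_alleles: np.ndarray
    scale_s: float = 42.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_alleles, dtype=float).ravel()
        if lam.size not in (1, 2):
            raise ValueError("lambda_alleles must have length 1 or 2")
        if not np.all(np.isfinite(lam)):
            raise ValueError("lambda values must be finite")
        if not self.scale_s > 0:
            raise ValueError("scale_s must be > 0")
        object.__setattr__(self, "lambda_alleles", lam)


@dataclass(frozen=True)
class NeutralGenome:
    """Neutral marker locus: inherited and mutating like the others, no fitness effect."""

    nu_alleles: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_alleles, dtype=float).ravel()
        if not np.all(np.isfinite(nu)):
            raise ValueError("nu values must be finite")
        object.__setattr__(self, "nu_alleles", nu)


def _tags_array(state, n_plastic: int) -> np.ndarray:
    tags = state.tags if isinstance(state, ActivationState) else np.asarray(state)
    if tags.shape != (n_plastic,):
        raise ValueError(
            f"expected {n_plastic} activation tags, got shape {tags.shape}"
        )
    if not np.all((tags == 0) | (tags == 1)):
        raise ValueError("tags must be 0 or 1")
    return tags


def phenotypes_from_locus_sums(
    locus_sums: np.ndarray, B: int, tags: np.ndarray
) -> np.ndarray:
    """Vectorised tag-gated phenotype for a cohort.

    ``locus_sums`` is ``(n, L)``, ``tags`` is ``(n, L - B)``. Every caller
    in the package funnels through this single expression so that identical
    inputs give bitwise-identical phenotypes (the omega = 0 variance-ratio
    identity relies on it).
    """
    locus_sums = np.asarray(locus_sums, dtype=float)
    return locus_sums[:, :B].sum(axis=1) + (locus_sums[:, B:] * tags).sum(axis=1)


def compute_phenotype(genome: ResponseGenome, state) -> float:
    """Response trait of one individual given its activation tags.

    Non-plastic loci always contribute their allele sum; plastic loci
    contribute only where the tag is 1. With all tags active this is the
    unconditional sum of every allele value — the "no epigenetic
    alterations" reference phenotype used by the genetic-load metric.
    """
    tags = _tags_array(state, genome.n_plastic)
    return float(
        phenotypes_from_locus_sums(
            genome.locus_sums()[None, :], genome.B, tags[None, :]
        )[0]
    )


def combine_sensitivity(
    lam_sum, scale_s: float, combination: str = "divide"
):
    """Map a summed sensitivity allele value to omega under a convention.

    ``divide`` (default) is the calibration under which a single mutation of
    typical effect (sigma_m = 1) yields omega ~ 1/42 ~ 0.024, in the
    moderate-plasticity regime; ``multiply`` and ``power`` are provided for
    sensitivity analysis.
    """
    if combination not in SENSITIVITY_COMBINATIONS:
        raise ValueError(f"unknown sensitivity_combination {combination!r}")
    if not scale_s > 0:
        raise ValueError("scale_s must be > 0")
    mag = np.abs(lam_sum)
    if combination == "divide":
        return mag / scale_s
    if combination == "multiply":
        return mag * scale_s
    return mag**scale_s


def compute_sensitivity(
    genome: SensitivityGenome, combination: str = "divide"
) -> float:
    """Sensitivity trait omega >= 0; zero iff the allele sum is zero."""
    return float(
        combine_sensitivity(genome.lambda_alleles.sum(), genome.scale_s, combination)
    )


def enumerate_attainable_phenotypes(
    genome: ResponseGenome, max_plastic: int = ENUMERATION_GUARD
) -> np.ndarray:
    """Distinct phenotypes reachable over all 2**(L-B) activation states.

    Uses subset-sum doubling over the plastic locus sums, so the cost is
    O(2**(L-B)) values rather than an explicit loop over tag vectors.
    Refuses genomes with more than ``max_plastic`` plastic loci.
    """
    n = genome.n_plastic
    if n > max_plastic:
        raise ValueError(
            f"{n} plastic loci exceeds the enumeration guard ({max_plastic})"
        )
    s = genome.locus_sums()
    base = float(s[: genome.B].sum())
    sums = np.zeros(1)
    for v in s[genome.B :]:
        sums = np.concatenate([sums, sums + v])
    return np.unique(base + sums)


def _shape_targets(distribution: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-individual trait targets for the non-normal founder shapes.

    Pinned shapes: 'bimodal' is an equal mixture of N(-2, 0.5^2) and
    N(+2, 0.5^2); 'asymmetric' is a mean-centred lognormal (sigma = 0.5),
    right-skewed with mean 0.
    """
    if distribution == "bimodal":
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        return sign * 2.0 + rng.normal(0.0, 0.5, size=n)
    if distribution == "asymmetric":
        z = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        return z - np.exp(0.125)  # subtract E[lognormal(0, 0.5^2)]
    raise ValueError(f"unknown founder distribution {distribution!r}")


def init_response_alleles(
    n_individuals: int,
    L: int,
    sigma_G: float,
    distribution: str = "normal",
    rng: np.random.Generator | None = None,
    ploidy: int = 2,
) -> np.ndarray:
    """Sample founder response alleles, shape ``(n, L, ploidy)``.

    ``normal`` draws every allele copy independently from
    N(0, sigma_G^2 / (ploidy * L)), so the founder trait standard deviation
    (all tags active) is sigma_G. ``bimodal`` and ``asymmetric`` instead
    draw a per-individual trait target with the pinned shape, spread it
    evenly over the allele copies, and add a small residual
    (trait-level sd 0.2) so genotypes are not internally uniform.
    """
    if n_individuals < 1 or L < 1:
        raise ValueError("need n_individuals >= 1 and L >= 1")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if not sigma_G > 0:
        raise ValueError("sigma_G must be > 0 (degenerate founders rejected)")
    if rng is None:
        rng = np.random.default_rng()
    n_copies = ploidy * L
    if distribution == "normal":
        sd = sigma_G / np.sqrt(n_copies)
        return rng.normal(0.0, sd, size=(n_individuals, L, ploidy))
    targets = _shape_targets(distribution, n_individuals, rng)
    residual_sd = 0.2 / np.sqrt(n_copies)
    alleles = rng.normal(0.0, residual_sd, size=(n_individuals, L, ploidy))
    return alleles + targets[:, None, None] / n_copies


def genome_to_json(genome: ResponseGenome, state=None) -> str:
    """Serialise a worked-example genotype to the JSON fixture format."""
    tags = (
        ActivationState.all_active(genome.n_plastic) if state is None else state
    )
    payload = {
        "L": genome.L,
        "B": genome.B,
        "ploidy": genome.ploidy,
        "alleles": genome.alleles.tolist(),
        "tags": _tags_array(tags, genome.n_plastic).tolist(),
    }
    return json.dumps(payload)


def genome_from_json(text: str) -> tuple[ResponseGenome, ActivationState]:
    payload = json.loads(text)
    alleles = np.asarray(payload["alleles"], dtype=float)
    if alleles.shape != (payload["L"], payload["ploidy"]):
        raise ValueError("allele matrix does not match declared L / ploidy")
    genome = ResponseGenome(alleles, B=payload["B"])
    return genome, ActivationState(np.asarray(payload["tags"]))
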