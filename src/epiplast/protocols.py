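"""Experiment protocols: development-only, fixed-omega evolution, evolving omega.

Three designs, mirroring the questions the simulator answers:

1. ``development_only`` — a single cohort develops once under a constant
   environment; no selection or reproduction. Shows the plasticity
   mechanism itself (canalization at moderate omega, developmental noise at
   high omega).
2. ``fixed_omega_evolution`` — response alleles evolve for many generations
   while every individual shares one fixed omega (plasticity costs are
   meaningless here, so C is forced to 0). Shows what plasticity does to
   stress, genetic load and cryptic variation under periodic or directional
   environmental change.
3. ``evolving_omega`` — the sensitivity locus (and a neutral marker as
   drift control) also mutates, starting from omega = 0 for everyone.
   Shows when plasticity itself is favoured by selection.

Replicates get independent child RNG streams spawned deterministically from
the master seed; given the same spec the output is bit-reproducible. Each
replicate uses five sub-streams (founders, development, demography,
response inheritance, auxiliary-locus inheritance) so that runs with and
without the auxiliary loci share identical response-trait dynamics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .development import DevelopmentConfig, DevelopmentTrajectory
from .environment import EnvironmentSpec, env_value
from .metrics import record_generation, variance_ratio
from .population import (
    Population,
    SelectionParams,
    found_population,
    population_fitness,
    develop_population,
    reproduce,
)

__all__ = [
    "GenomeParams",
    "ProtocolSpec",
    "Protocol1Result",
    "run_protocol1",
    "run_protocol2",
    "run_protocol3",
    "run_replicates",
    "desk_scale",
    "paper_scale",
    "fig2_genome",
]

PROTOCOLS = ("development_only", "fixed_omega_evolution", "evolving_omega")

RECORD_COLUMNS = [
    "t",
    "p",
    "N",
    "mean_stress",
    "genetic_load",
    "variance_ratio",
    "mean_omega",
    "sd_omega",
    "mean_neutral",
    "sd_neutral",
    "neutral_omega_null",
    "extinct",
]


@dataclass(frozen=True)
class GenomeParams:
    """Genetic architecture: locus counts, sensitivity scale, founder sampling."""

    L: int = 10
    B: int = 1
    s: float = 42.0
    sigma_G: float = 1.0
    ploidy: int = 2
    combination: str = "divide"
    distribution: str = "normal"

    def __post_init__(self) -> None:
        if not 1 <= self.B <= self.L:
            raise ValueError("need 1 <= B <= L")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if not self.s > 0 or not self.sigma_G > 0:
            raise ValueError("s and sigma_G must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Complete description of one experiment (all replicates)."""

    protocol: str
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    selection: SelectionParams = field(default_factory=SelectionParams)
    development: DevelopmentConfig = field(default_factory=DevelopmentConfig)
    genome: GenomeParams = field(default_factory=GenomeParams)
    n_generations: int = 2000
    n_replicates: int = 1
    fixed_omega: float = 0.0
    founding_N: int = 1000
    cohort_size: int = 100
    master_seed: int = 0
    aux_mu_m: float | None = None

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n_replicates < 1 or self.n_generations < 1:
            raise ValueError("replicates and generations must be >= 1")
        if self.fixed_omega < 0:
            raise ValueError("fixed_omega must be >= 0")


@dataclass(frozen=True)
class Protocol1Result:
    """Single-generation development of one cohort."""

    x_start: np.ndarray
    x_end: np.ndarray
    trajectory: DevelopmentTrajectory | None
    variance_ratio: float


def _streams(seedseq: np.random.SeedSequence) -> dict[str, np.random.Generator]:
    names = ("founders", "development", "demography", "response", "aux")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, seedseq.spawn(len(names)))
    }


def _found(spec: ProtocolSpec, n: int, rng, evolve_sensitivity: bool) -> Population:
    g = spec.genome
    return found_population(
        n,
        rng,
        L=g.L,
        B=g.B,
        ploidy=g.ploidy,
        sigma_G=g.sigma_G,
        distribution=g.distribution,
        scale_s=g.s,
        combination=g.combination,
        fixed_omega=spec.fixed_omega,
        encode_sensitivity=evolve_sensitivity,
        track_neutral=evolve_sensitivity,
    )


def run_protocol1(
    spec: ProtocolSpec, seed_sequence: np.random.SeedSequence | None = None
) -> Protocol1Result:
    """Develop one founding cohort for tau days under a constant environment.

    The cohort shares the fixed omega; the environment value is the
    constant-regime p0 (or the regime's value at t = 1). Trajectories are
    recorded when the development config asks for them.
    """
    if spec.protocol != "development_only":
        raise ValueError("run_protocol1 requires protocol='development_only'")
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(spec.master_seed)
    streams = _streams(seed_sequence)
    pop = _found(spec, spec.cohort_size, streams["founders"], False)
    p = env_value(spec.environment, 1) if spec.environment.regime != "constant" else spec.environment.p0
    x_start = pop.x.copy()
    traj = develop_population(pop, p, spec.development, streams["development"])
    return Protocol1Result(
        x_start=x_start,
        x_end=pop.x.copy(),
        trajectory=traj,
        variance_ratio=variance_ratio(x_start, pop.x),
    )


def _run_evolution_replicate(
    spec: ProtocolSpec,
    seedseq: np.random.SeedSequence,
    evolve_sensitivity: bool,
) -> pd.DataFrame:
    streams = _streams(seedseq)
    params = spec.selection
    if not evolve_sensitivity:
        # shared omega: plasticity costs are meaningless, forced to zero
        params = dataclasses.replace(params, C=0.0)
    pop = _found(spec, spec.founding_N, streams["founders"], evolve_sensitivity)
    rows = []
    for t in range(1, spec.n_generations + 1):
        pop.t = t
        p = env_value(spec.environment, t)
        x_start = pop.x.copy()  # newborn tags are all active
        develop_population(pop, p, spec.development, streams["development"])
        W = population_fitness(pop, p, params)
        nxt = reproduce(
            pop,
            p,
            params,
            streams["demography"],
            rng_response=streams["response"],
            rng_aux=streams["aux"],
            aux_mu_m=spec.aux_mu_m,
            W=W,
        )
        rows.append(
            record_generation(pop, p, params, x_start, extinct=nxt.extinct)
        )
        pop = nxt
        if pop.extinct:
            break
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return frame[RECORD_COLUMNS]


def run_replicates(spec: ProtocolSpec) -> pd.DataFrame:
    """Run all replicates of an evolution protocol into one tidy table.

    Child seeds are spawned deterministically from ``master_seed``; the
    output is bit-reproducible and replicate-exchangeable.
    """
    if spec.protocol == "development_only":
        raise ValueError("development_only runs through run_protocol1")
    evolve = spec.protocol == "evolving_omega"
    children = np.random.SeedSequence(spec.master_seed).spawn(spec.n_replicates)
    frames = []
    for rep, child in enumerate(children):
        frame = _run_evolution_replicate(spec, child, evolve)
        frame.insert(0, "replicate", rep)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.insert(1, "protocol", spec.protocol)
    out.insert(2, "regime", spec.environment.regime)
    return out


def run_protocol2(spec: ProtocolSpec) -> pd.DataFrame:
    """Fixed-omega evolution of the response trait (C forced to 0)."""
    if spec.protocol != "fixed_omega_evolution":
        raise ValueError("run_protocol2 requires protocol='fixed_omega_evolution'")
    return run_replicates(spec)


def run_protocol3(spec: ProtocolSpec) -> pd.DataFrame:
    """Evolution of plasticity: lambda and the neutral marker start at 0 and mutate."""
    if spec.protocol != "evolving_omega":
        raise ValueError("run_protocol3 requires protocol='evolving_omega'")
    return run_replicates(spec)


def paper_scale(spec: ProtocolSpec) -> ProtocolSpec:
    """Full published scale: K = N = 1000, 2000 generations, 30 replicates."""
    return dataclasses.replace(
        spec,
        selection=dataclasses.replace(spec.selection, K=1000.0),
        founding_N=1000,
        n_generations=2000,
        n_replicates=30,
    )


def desk_scale(spec: ProtocolSpec) -> ProtocolSpec:
    """Reduced scale for quick runs: K = N = 250, 400 generations, 10 replicates."""
    return dataclasses.replace(
        spec,
        selection=dataclasses.replace(spec.selection, K=250.0),
        founding_N=250,
        n_generations=400,
        n_replicates=10,
    )


def fig2_genome(L: int = 10, B: int = 1, ploidy: int = 2) -> GenomeParams:
    """Genome parameters of the single-generation development setup.

    The development-only cohort samples every allele copy with unit
    variance (founder trait sd sqrt(ploidy * L)), unlike the evolution
    protocols' sigma_G = 1 rule.
    """
    return GenomeParams(
        L=L, B=B, ploidy=ploidy, sigma_G=math.sqrt(float(ploidy * L))
    )
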