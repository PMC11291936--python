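"""Within-generation development: stress-sensitive epimutation of plastic loci.

During a development period of ``tau`` days, each plastic locus of an
individual flips its activation tag (active <-> silenced) independently each
day with probability

    mu_e(x | omega, p) = 1 - exp(-omega (x - p)^2),

evaluated once per individual per day from the start-of-day phenotype. The
rate is zero when the phenotype matches the environment (x = p) or when the
individual is non-plastic (omega = 0), and saturates below 1. Because a
well-matched phenotype stops mutating, the random flips behave like
trial-and-error learning with an absorbing target; an overly sensitive
genotype (large omega) instead churns its tags every day and develops noise
rather than adaptation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .genome import phenotypes_from_locus_sums

__all__ = [
    "DevelopmentConfig",
    "DevelopmentTrajectory",
    "epimutation_rate",
    "develop_arrays",
    "develop_day",
    "develop",
]


@dataclass(frozen=True)
class DevelopmentConfig:
    """Length of the development period (days) and trajectory recording."""

    tau: int = 33
    record_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


@dataclass(frozen=True)
class DevelopmentTrajectory:
    """Per-day record of a developing cohort.

    ``phenotypes`` has shape ``(n, tau + 1)`` (day 0 is the pre-development
    state); ``rates`` has shape ``(n, tau)`` with the realized mu_e of each
    individual on each day.
    """

    phenotypes: np.ndarray
    rates: np.ndarray


def epimutation_rate(x, p, omega):
    """Daily per-locus epimutation probability, Gaussian-type in the mismatch.

    Vectorised over ``x`` and ``omega``. Always in [0, 1); exactly 0 iff
    omega = 0 or x = p.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")
    out = -np.expm1(-omega * (np.asarray(x, dtype=float) - p) ** 2)
    if out.ndim == 0:
        return float(out)
    return out


def develop_arrays(
    locus_sums: np.ndarray,
    B: int,
    tags: np.ndarray,
    omega: np.ndarray,
    p: float,
    tau: int,
    rng: np.random.Generator,
    record: bool = False,
):
    """Vectorised development of a cohort.

    Parameters
    ----------
    locus_sums
        ``(n, L)`` per-locus allele sums of the cohort.
    tags
        ``(n, L - B)`` activation tags; not modified in place.

    Returns ``(tags, x, trajectory_or_None)`` where ``x`` is the end-of-
    development phenotype. Each day, mu_e is computed once per individual
    from the start-of-day phenotype, all plastic loci flip independently and
    simultaneously with that probability, and the phenotype is recomputed.
    """
    locus_sums = np.asarray(locus_sums, dtype=float)
    n = locus_sums.shape[0]
    tags = np.asarray(tags, dtype=np.uint8).copy()
    omega = np.broadcast_to(np.asarray(omega, dtype=float), (n,))
    x = phenotypes_from_locus_sums(locus_sums, B, tags)
    traj_x = traj_mu = None
    if record:
        traj_x = np.empty((n, tau + 1))
        traj_x[:, 0] = x
        traj_mu = np.empty((n, tau))
    for day in range(tau):
        mu = epimutation_rate(x, p, omega)
        flips = rng.random(tags.shape) < np.asarray(mu)[:, None]
        tags ^= flips.astype(np.uint8)
        x = phenotypes_from_locus_sums(locus_sums, B, tags)
        if record:
            traj_mu[:, day] = mu
            traj_x[:, day + 1] = x
    trajectory = DevelopmentTrajectory(traj_x, traj_mu) if record else None
    return tags, x, trajectory


def _develop_individual(individual, p: float, tau: int, rng, record: bool):
    genome = individual.response_genome
    tags, x, traj = develop_arrays(
        genome.locus_sums()[None, :],
        genome.B,
        np.asarray(individual.tags, dtype=np.uint8)[None, :],
        np.asarray([individual.omega]),
        p,
        tau,
        rng,
        record=record,
    )
    updated = dataclasses.replace(individual, tags=tags[0], x=float(x[0]))
    return updated, traj


def develop_day(individual, p: float, rng: np.random.Generator):
    """One day of development for a single individual (alleles untouched)."""
    updated, _ = _develop_individual(individual, p, 1, rng, record=False)
    return updated


def develop(
    individual,
    p: float,
    config: DevelopmentConfig,
    rng: np.random.Generator,
):
    """Full development of one individual under a constant environment ``p``.

    Returns ``(individual, trajectory)``; the trajectory is ``None`` unless
    ``config.record_trajectories`` is set.
    """
    return _develop_individual(
        individual, p, config.tau, rng, record=config.record_trajectories
    )
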