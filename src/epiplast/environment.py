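"""Deterministic environmental trends across generations.

The environmental parameter ``p(t)`` changes only between discrete
generations and carries no stochastic component. Three regimes:

* ``constant``:     p(t) = p0
* ``periodic``:     p(t) = p0 + A sin(2 pi t / T)
* ``directional``:  p(t) = p0 + eta t

``t`` is the integer generation index; t = 0 denotes the founding state, so
p(0) = p0 (= 0 by default) is the optimum the founders are sampled around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnvironmentSpec", "env_value"]

REGIMES = ("constant", "periodic", "directional")


@dataclass(frozen=True)
class EnvironmentSpec:
    """Environment regime and its parameters.

    ``A`` (amplitude) and ``T`` (period, generations) apply to the periodic
    regime; ``eta`` (change per generation) to the directional regime.
    """

    regime: str = "constant"
    p0: float = 0.0
    A: float = 1.0
    T: float = 200.0
    eta: float = 0.001

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown environment regime {self.regime!r}")
        if self.regime == "periodic" and not self.T > 0:
            raise ValueError("period T must be > 0")


def env_value(spec: EnvironmentSpec, t):
    """p at generation ``t`` (vectorised over ``t``)."""
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("generation index must be >= 0")
    if spec.regime == "constant":
        out = np.broadcast_to(np.asarray(spec.p0, dtype=float), t.shape)
    elif spec.regime == "periodic":
        out = spec.p0 + spec.A * np.sin(2.0 * np.pi * t / spec.T)
    else:
        out = spec.p0 + spec.eta * t
    if out.ndim == 0:
        return float(out)
    return np.array(out, dtype=float)
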