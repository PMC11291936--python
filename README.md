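# epiplast

Individual-based simulation of phenotypic plasticity that emerges from
stress-sensitive epigenetic mutations.

## The problem

Classical models of plasticity treat the reaction norm itself as the target
of selection and stay silent about the mechanism that produces it. This
package implements a mechanistic alternative inspired by DNA
methylation/demethylation: a quantitative trait is encoded by loci that can
be randomly silenced and re-activated during development, at a rate that
rises with the organism's current stress. Plasticity then *emerges* as
trial-and-error developmental learning — and carries intrinsic limits
(developmental noise) and population-level side effects (genetic load,
cryptic genetic variation) that phenomenological models cannot express. The
package is aimed at evolutionary ecologists and theoreticians who want to
simulate this mechanism under controlled regimes of environmental change.

## The model

An individual's response trait is additive over `L` diploid loci, the last
`L − B` of which are gated by activation tags `a_j ∈ {0, 1}`:

    x = Σ_{j≤B} (l_j1 + l_j2) + Σ_{j>B} (l_j1 + l_j2) a_j

During a development period of `τ` days each plastic locus flips its tag
daily with probability

    μ_e(x | ω, p) = 1 − exp(−ω (x − p)²)

where `p` is the environmental optimum and `ω = |λ1 + λ2| / s` is a
heritable sensitivity trait (non-plastic when `ω = 0`). Because `μ_e`
vanishes as `x → p`, well-matched phenotypes stop changing — a learning-like
negative feedback. Fitness after development is density-dependent with a
Gaussian-type stress term and a linear plasticity cost:

    W = (1 − ρ(x)) · R e^{1 − N/K} − ωC,   ρ(x) = 1 − exp(−½((x − p)/γ)²)

Generations are discrete and non-overlapping: females mate once with a
random male, pair offspring counts are Poisson(max(0, W♀ + W♂)), alleles
recombine freely and mutate at rate `μ_m` with N(0, σ_m²) effects, and tags
are never inherited. The environment is deterministic: constant, periodic
`p(t) = A sin(2πt/T)`, or directional `p(t) = ηt`.

Per-generation diagnostics: mean stress, genetic load
`(W_max° − W̄°)/W_max°` on the epigenetically unaltered fitnesses, and the
developmental variance ratio `V_τ/V_0` (< 1 = canalization, > 1 = variance
release). A neutral locus `ν`, pushed through the same `|·|/s` map, provides
the drift null for deciding whether `ω` is under selection.

## Worked example

Develop a cohort of 1,000 individuals (unit-variance allele copies,
`L = 10`, `B = 1`) for 33 days toward an environment at `p = 2`:

```python
from epiplast import (DevelopmentConfig, EnvironmentSpec, ProtocolSpec,
                      fig2_genome, run_protocol1)

for omega in (0.0, 0.03, 1.0):
    spec = ProtocolSpec(
        "development_only",
        environment=EnvironmentSpec("constant", p0=2.0),
        genome=fig2_genome(),
        development=DevelopmentConfig(tau=33),
        fixed_omega=omega,
        cohort_size=1000,
        master_seed=1,
    )
    r = run_protocol1(spec)
    print(f"omega={omega:<5} V_tau/V_0 = {r.variance_ratio:.3f}  "
          f"mean|x-p| end = {abs(r.x_end - 2.0).mean():.2f}")
```

prints

```
omega=0.0   V_tau/V_0 = 1.000  mean|x-p| end = 3.94
omega=0.03  V_tau/V_0 = 0.208  mean|x-p| end = 1.18
omega=1.0   V_tau/V_0 = 0.363  mean|x-p| end = 2.72
```

A non-plastic cohort (`ω = 0`) keeps its trait distribution unchanged
(ratio exactly 1). Moderate sensitivity canalizes heterogeneous genotypes
onto the optimum — the variance collapses five-fold and the mean mismatch
drops from ~4 to ~1.2 trait units. Excessive sensitivity (`ω = 1`) flips
tags so often that much of that gain is lost to developmental noise.

The same machinery runs multi-generation experiments from the shell:

```sh
epiplast evolve --scale desk --omega 0.03 --regime periodic --seed 1 --out out/
epiplast evolve-plasticity --scale desk --cost 0.5 --regime directional --seed 1 --out out/
epiplast sweep --scale desk --costs 0,0.5,0.8 --regimes constant,periodic --seed 1 --out out/
```

Each writes a tidy per-generation CSV (stress, genetic load, variance
ratio, mean ω, neutral-marker statistics, extinction flags).

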