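# Methods

## Model summary

`epiplast` simulates a single quantitative response trait `x` under
stabilising selection toward a moving environmental optimum `p(t)`, where
the genotype-phenotype map can be altered *within* a generation by random
epigenetic mutations. Two nested time scales: a developmental scale of `τ`
days inside each generation, and a generational scale on which selection,
reproduction and allelic mutation act.

**Genotype-phenotype map.** `L` diploid loci with unbounded real allelic
values; the first `B ≥ 1` loci are constitutive, the remaining `L − B`
plastic loci are gated by binary activation tags. At least one constitutive
locus is required, otherwise a fully silenced genome would have an
indeterminate trait. A genotype therefore spans up to `2^(L−B)` phenotypes
(one per tag vector), and many genotypes can share a phenotype; both
directions of this many-to-many structure are exercised by the worked
examples in `epiplast.fixtures`.

**Development.** Each day, an individual's per-locus flip probability
`μ_e = 1 − exp(−ω (x − p)²)` is evaluated once from its start-of-day
phenotype; all plastic loci then flip independently and simultaneously with
that probability, and the phenotype is recomputed. This once-per-day
granularity is a modelling choice: the rate is defined per locus per day
with no intra-day recursion, and simultaneous application keeps loci
exchangeable. An individual whose phenotype reaches `p` has flip
probability 0 and is absorbed there — the "learning" fixed point. There is
no mortality during development; mismatch has fitness consequences only at
selection. Newborns start with all tags active (epigenetic marks are not
inherited), so the pre-development phenotype equals the unconditional
allele sum.

**Sensitivity trait.** `ω` is encoded by one diploid locus as
`|λ1 + λ2|` combined with a positive scale `s = 42`. The combination is
configurable (`divide`, `multiply`, `power`); the default is division,
calibrated so that a single allelic mutation of typical effect
(`σ_m = 1`) yields `ω ≈ 0.024` — inside the moderate-plasticity regime
(`ω ≈ 0.03`) where trial-and-error learning works, rather than the
noise-dominated regime (`ω ≳ 1`).

**Selection and reproduction.** Discrete non-overlapping generations.
After development, fitness `W = (1 − ρ(x)) R e^{1−N/K} − ωC` is evaluated
at the parental population size N. Sexes are then assigned by random
permutation (`floor(N/2)` males) — a per-generation population operation,
not a birth trait. Each female mates once with a uniformly drawn male
(males reusable); pair offspring counts are Poisson with rate
`max(0, W♀ + W♂)`. The clamp at zero is required for a Poisson rate and
reads as "no reproduction" when costs push a pair's summed fitness
negative; individual fitnesses are not floored. Offspring inherit one
uniformly chosen allele per parent per locus (free recombination, no
linkage), and each transmitted copy mutates with probability `μ_m`
(additive N(0, σ_m²) effect) — mutation acts on the germline at
transmission, once per generation. Offspring replace parents entirely;
zero total offspring is extinction. There is no hard cap on N; regulation
is purely through the `e^{1−N/K}` factor.

**Haploid asexual mode.** With `ploidy = 1` the per-locus contribution is
the single allele value and `ω = |λ|/s`. Reproduction is clonal with
offspring counts Poisson(`max(0, 2W)`); the doubled rate keeps per-capita
expected offspring equal to the diploid two-parent scheme, whose pair rate
is the sum of two fitnesses.

**Environment.** Deterministic only: constant, periodic
`p0 + A sin(2πt/T)`, or directional `p0 + ηt`, changing between discrete
generations. `t` counts selected generations from 1; `t = 0` is the
founding state with `p(0) = p0 = 0`, which is also the founders' trait
mean — hence no burn-in phase is needed.

## Metrics

* **Mean stress** — arithmetic mean of `ρ(x_i)` after development.
* **Genetic load** — `(W_max° − W̄°)/W_max°` where `°` marks fitnesses
  recomputed with all tags active, at the generation's shared N and p and
  including the density and cost terms (the definition says "fitness", so
  the full expression is used; with C = 0 the choice is inert). The
  reference is the best genotype currently present, adequate or not.
* **Variance ratio** `V_τ/V_0` — ratio of raw sums of squared deviations
  of the same cohort's phenotypes after vs before its development. Raw
  sums and n-normalised variances give the identical ratio since the same
  N appears in both; raw sums are used. For `ω = 0` cohorts the ratio is
  exactly 1 by construction: every phenotype evaluation funnels through
  one shared kernel (`phenotypes_from_locus_sums`), so unchanged tags give
  bitwise-identical phenotypes.
* **Neutral null for ω** — the neutral locus `ν` (initialised 0, inherited
  and mutating like `λ`, fitness-inert) pushed through the same `|·|/s`
  map. Evolved `ω` is "favoured by selection" when its across-replicate
  final mean exceeds this drift-only null.

Undefined metrics (empty population, zero pre-development variance,
non-positive maximal unaltered fitness) are NaN in all outputs, never 0.
Note that `μ_e` and `ρ` are strictly below 1 in exact arithmetic but round
to 1.0 in double precision once the exponential underflows (mismatch
beyond ~40 tolerance units); tests assert strictness only inside the
representable range.

## Parameters and defaults

| Symbol | Meaning | Default |
|---|---|---|
| L, B | response loci / constitutive loci | 10, 1 |
| s | sensitivity scale | 42 (division) |
| τ | development time, days | 33 |
| μ_m | allelic mutation rate per locus per generation | 1e-4 |
| σ_m | sd of allelic mutational effects | 1 |
| σ_G | founder trait sd (alleles ~ N(0, σ_G²/2L)) | 1 |
| γ | stress tolerance | 2.2 |
| R | intrinsic reproduction factor | 1 |
| K | carrying capacity | 1000 |
| C | plasticity cost per unit ω | 0–1 (grid step 0.1) |
| T, A | period / amplitude of cycling | 200; 1 or 4 |
| η | directional change per generation | 0.001 or 0.004 |

The development-only protocol instead samples every allele copy with unit
variance (founder trait sd `√(2L) ≈ 4.5`), the convention of the
single-generation experiments; `fig2_genome()` builds it. Both conventions
are available through `GenomeParams(sigma_G=...)`.

## Protocols and problem sizes

1. **development_only** — one cohort (default 100; the shipped experiments
   use 1,000–2,000 for stable density estimates), one development period,
   no selection.
2. **fixed_omega_evolution** — response alleles evolve; everyone shares a
   fixed ω, so the cost C is forced to 0 (costs of a universal trait are
   meaningless and would only rescale fitness).
3. **evolving_omega** — λ and the neutral ν also mutate, starting from
   `ω = ν = 0` for all.

Full scale is K = N = 1000, 2,000 generations, 30 replicates
(`paper_scale`). The package's own experiments and tests run at reduced
scale (`desk_scale`: K = N = 250, 400 generations, 10 replicates; the
plasticity-evolution comparisons use K = 250, 1,000 generations, 20
replicates), chosen so the qualitative contrasts — plastic populations
show lower stress but higher genetic load than non-plastic under moderate
periodic change; ω beats the neutral null at zero cost under periodic
change but not under fast directional change (η = 0.004) — are
reproducible in seconds to minutes. These are ensemble directions, not
figure-identical reproductions.

## Randomness and reproducibility

One master seed per experiment. Replicates get child `SeedSequence`s
spawned deterministically; each replicate further splits into five named
streams (founders, development, demography, response inheritance,
auxiliary-locus inheritance). The split makes runs with and without the
sensitivity machinery draw-for-draw identical on the response trait — a
tested identity (`fixed_omega_evolution` at ω = 0 vs `evolving_omega`
with non-mutating λ) — and makes replicate outputs exchangeable. The
development step draws its uniforms even when every flip probability is
zero, to keep streams aligned across configurations.

## What the synthetic founders do and do not emulate

Founders are drawn at linkage and Hardy-Weinberg equilibrium with
independent normal allele values, i.e. a mutation-drift population that has
never experienced selection; the non-normal options (pinned here:
equal-mixture normals at ±2 with sd 0.5 for "bimodal"; mean-centred
lognormal, σ = 0.5, for "asymmetric", both spread evenly over allele
copies plus a small residual with trait-level sd 0.2) emulate trait
distributions shaped by past selection or mutation pressure only at the
trait level, not via an explicit history. Passing tests therefore show the
mechanism's behaviour under idealised standing variation; they do not show
robustness to realistic linkage disequilibrium, allele-frequency spectra,
or correlated environments, none of which the generator produces.

## Known limitations

* No environmental stochasticity (deterministic trends only, by design).
* No linkage, dominance, epistasis, age structure, or mate choice.
* Single trait, single stress axis; no diversity of epigenetic marks.
* Fitness comparisons at reduced scale have replicate-level noise;
  directional claims are tested as ensemble means, and the
  extreme-directional "ω does not beat the null" outcome is the noisiest
  of them (the null itself is a heavy-tailed drift distribution).
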