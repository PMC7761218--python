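# Methods

## The model

`evometa` simulates the evolution of a single quantitative trait `x` in a
metacommunity of asexually reproducing populations ("lineages") that inhabit
`k` habitat patches. The trait sets two things at once:

1. **Carrying capacity.** Each patch has an optimum trait value `x_opt` and a
   Gaussian resource distribution

   `K(x) = K_max · exp(−(x_opt − x)² / (2 σ_K²))`,

   so a lineage's sustainable abundance falls off with its distance from the
   local optimum. `K(x)` is density-independent environmental selection.

2. **Competition.** The per-capita effect of a lineage with trait `x_j` on one
   with trait `x_i` is

   `α(x_i, x_j) = 1 / (1 + (x_i − x_j)² / (2 σ_α²))`,

   a symmetric kernel with heavier-than-Gaussian tails. The total competition
   felt by phenotype `x` is `C(x) = Σ_j N_j α(x, x_j)` over all resident
   lineages of the patch, all species pooled. Competition is frequency- and
   density-dependent selection; the heavy tails are what allow discrete
   coexisting phenotypic clusters instead of a continuum.

Population dynamics are discrete-logistic:

`G(x_i) = r (1 − C(x_i)/K(x_i))`, `N_{t+1} = N_t (1 + G)`.

Each generation a lineage produces `r·N` births, of which a
`Poisson(μ·r·N)`-distributed number (capped at the birth count) are mutants;
each mutant founds a new lineage of size 1 with trait drawn
`Normal(parent, σ_μ²)` and the parent's species identity. Lineages below one
individual are removed; lineages with `1 ≤ N < θ` are removed with
probability `ρ` per generation. Individuals disperse with probability `d`
per generation, moving equiprobably to any other patch. Environmental change
is a constant per-generation increment `Δ` of every patch optimum.

Whether a monomorphic population at the optimum splits into several clusters
("evolutionary branching") is governed by the ratio `σ_α/σ_K`: when
`σ_α < σ_K`, there is a region of trait space off the optimum where
`K(x) > C(x)` and rare mutants grow; when `σ_α > σ_K` no mutant can invade a
resident equilibrium at the optimum. The three niche widths used throughout
(0.68, 0.85, 1.5 with `σ_K = 1`) produce 4, 2 and 1 stable branches.

## Default parameters

| symbol | field | default | meaning |
|---|---|---|---|
| r | `r` | 1.9 | intrinsic rate of increase per generation (stable discrete logistic: r < 2) |
| K_max | `K_max` | 10 000 | maximum carrying capacity, individuals |
| σ_K | `sigma_K` | 1.0 | width of the resource distribution, trait units |
| σ_α | `sigma_alpha` | 0.68 | niche width of competition, trait units |
| μ | `mu` | 1e−5 | mutation probability per birth (1e−4 in the scaled burn-in) |
| σ_μ | `sigma_mu` | 0.05 | mutation-effect SD, trait units |
| θ | `theta` | 2 | stochastic-extinction threshold, individuals |
| ρ | `rho` | 0.025 | stochastic-extinction probability per generation |
| d | `d` | 0 | per-individual dispersal probability |
| Δ | `delta_env` | 0 | optimum increment per generation (study levels 0, 1e−5, 4e−4) |
| δ | `delta_spacing` | 0.5 | among-patch optimum spacing |
| k | `k` | 3 | number of patches |

## Initialization protocol

Each patch is seeded with one monomorphic founder (`N0 = 500`, trait `x0`)
and coevolved in isolation at `x_opt = 0` (no dispersal, no environmental
change). Species are defined as the distinct lineages surviving at the end of
this burn-in; all later mutants are subpopulations of their ancestor species
and no new species labels are ever created. The three coevolved communities
are then placed at local optima (−δ, 0, +δ) by shifting every trait by the
same offset as its patch optimum, which preserves each lineage's distance to
its optimum exactly.

The full protocol runs 10⁶ generations at μ = 1e−5. The package's default
desk-scale protocol (`InitConfig.scaled`) runs 2×10⁵ generations at μ = 1e−4:
raising the mutation supply shortens the branching timescale roughly
proportionally, and the branched end states are qualitatively the same
configuration; `InitConfig.full` retains the long protocol. All acceptance
checks and examples use the scaled protocol; its 4/2/1 modal branch counts
are a reproduction of the model's qualitative prediction, not a bitwise
replication of any particular long run.

Founder traits default to fixed values drawn once uniformly from
[−0.5, 0.5] (`DEFAULT_FOUNDER_TRAITS`); branch positions and counts do not
depend on the founder, which is asserted statistically in the tests.

## Resolved ambiguities (design choices)

These points are under-determined by the model statement above; the package
fixes them as follows and exposes the relevant knobs.

- **Mutant count integerization.** The expected mutant number `μrN` is
  fractional; the count is drawn `Poisson(μrN)` capped at the births `⌊rN⌋`,
  preserving the stated mean and reflecting individual-level mutation
  events. A deterministic rounded-expectation mode exists for debugging
  (`draw_mutants(..., deterministic=True)`).
- **Mutants and density regulation.** Mutants are subtracted from the
  parent's births *before* density regulation: `N_{t+1} = N_t + (rN_t −
  N_m)(1 − C/K)`. Newborn mutants neither experience nor exert competition in
  their birth generation; their N = 1 contribution to C is negligible and
  results do not qualitatively depend on it.
- **Within-generation order.** growth+mutation → extinction → dispersal →
  environment increment. Extinction is specified to act at the end of a
  generation; placing dispersal after it means emigrants are drawn from the
  post-extinction pool and immigrants face competition only from the next
  generation onward. A corollary is that a lineage partly emptied by
  emigration can dip below one individual and is only removed at the *next*
  generation's extinction pass (lineages emptied exactly to zero are dropped
  immediately).
- **Dispersal integerization.** Emigrants per lineage are
  `Binomial(⌊N⌋, d)`; the fractional part of N never emigrates (it is below
  the one-individual viability unit). Destinations are multinomial-uniform
  over the other k−1 patches, implemented as sequential binomial thinning.
  Total abundance is conserved exactly (only integer packets move).
- **Lineage merging.** An immigrant packet merges with a destination lineage
  of identical species and *bit-identical* trait; otherwise it founds a new
  lineage. Continuous mutation makes accidental trait collisions
  measure-zero, so merging effectively reunites migrant streams of the same
  lineage.
- **Negative abundances.** The discrete update can overshoot below zero for
  strongly maladapted lineages; abundances are clamped at 0 and such lineages
  are removed at the extinction pass.
- **K(x) underflow.** For extremely maladapted traits `K(x)` underflows to
  zero; growth is then taken as the maximal decline `G = −r` (logged).
- **RNG contract.** All draws consume one `numpy.random.Generator` in a fixed
  order (per patch: Poisson mutant counts, Normal mutation effects; then per
  patch a uniform vector for stochastic extinction; then per patch Binomial
  emigrant counts and the destination split). Runs are bit-reproducible from
  (state, parameters, seed); the test-suite oracle relies on this order.
- **Cluster counting.** "Branches" are counted by sorting lineages by trait,
  merging neighbours with gaps ≤ 0.1 (= 2σ_μ) and discarding clusters below
  1% of patch abundance (the frequency floor used for density plots). Both
  thresholds are honest free parameters of the diagnostic, exposed as
  arguments; the model itself has no sharp cluster definition.
- **β diversity.** The default is `¹D_β = mean(¹D_α)/¹D_γ`, although the multiplicative
  partition convention is the reciprocal; `convention="gamma_over_alpha"`
  gives γ/ᾱ. With identical patches the printed form equals 1.
- **CV window.** No window is prescribed; the default summary uses all
  recorded generations after a burn-in of 1000 and reports the window used.
- **SSD weighting.** "All individuals" is read as abundance-weighted over
  lineages, `Σ N_i (x_i − x_opt)²`; `weighted=False` gives the per-lineage
  variant.
- **Fast environmental change rate.** 4×10⁻⁴ per generation (the value used
  in the scenario grid); a variant figure mentions 4.4×10⁻⁴ once, treated as
  a typo.
- **Scenario seeds.** Each grid cell derives its seed from the base seed plus
  a stable function of its (σ_α, d, Δ) indices, so cells are independent but
  individually reproducible; seeds are recorded in run manifests.

## Numerical and runtime choices

The inner update is vectorized: a patch's lineages live in parallel numpy
arrays and the competition matrix is built once per patch per generation
(O(L²) for L lineages; L stays in the tens at these parameters). A scaled
burn-in (2×10⁵ generations) takes roughly ten seconds on one core; a 10⁴
generation 3-patch scenario a few seconds. Problem sizes used by the test
suite and acceptance script — 5 replicate seeds per stochastic claim,
scaled burn-ins, collapse runs of ≤ 9×10³ generations — were chosen as the
smallest designs that make the modal/majority criteria statistically stable.

## What the simulations do and do not show

The simulator generates all of its own data; there is no empirical input.
Passing checks demonstrate the model's internal predictions — branching
counts set by σ_α/σ_K, species sorting and its erosion by dispersal,
collapse to a single species under fast environmental change, selection
landscapes whose positive-growth region x_fit widens with dispersal — under
the stated parameters. They say nothing about any real community: the model
assumes asexual reproduction, a single trait, identical K_max everywhere,
uniform all-to-all dispersal, and mutation of small effect. Reproduction targets are therefore qualitative and distributional, and
the long-horizon protocols remain available via the full-protocol
presets (`InitConfig.full`, CLI `--preset full`).

## Known limitations

- Dispersal merging keys on exact float equality of traits; two lineages
  that coincide after independent mutations would stay separate (measure-zero
  event, and harmless: they are ecologically equivalent).
- The per-generation metrics recompute species pools in Python dictionaries;
  for 50 000-generation full-grid runs use `metrics_every > 1`.
- Early termination reports `"extinct"` but does not distinguish ecological
  collapse from the optimum racing out of reach.
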