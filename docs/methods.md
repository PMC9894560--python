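# Methods

This note documents the models implemented in `cifdrive`, the numerical
choices behind them, and what the test suite does and does not
demonstrate.

## Genetic architectures and the cross engine

Three diploid architectures share one cross engine:

| architecture | loci | alleles | genotypes |
|---|---|---|---|
| CIFAB | 1 | `d` (cifA+cifB), `w` | 3 |
| SL_ONE_LOCUS | 1 | `w`, `a` (cifA), `b` (cifB) | 6 |
| SL_TWO_LOCUS | 2 (unlinked) | `w1`/`a`, `w2`/`b` | 9 |

Genotypes are unordered (parental origin is never tracked; nothing in the
dynamics distinguishes it). For every ordered parental pair the engine
computes a fertility `1 − toxin(male)·(1 − antidote(female))` and a
Mendelian offspring distribution (one allele per parent per locus,
independent assortment across loci). Birth weights — the per-offspring-
genotype "sum over combinations" of the dynamic models — are produced by
generic enumeration over this pair tensor rather than hard-coded
polynomials, so a single engine serves all three architectures; the
closed-form CIFAB polynomials are retained only as a regression oracle
and the two agree to 1e−12 on random states.

**Efficiencies are per-allele and multiplicative.** A male with `n`
toxin-competent allele copies causes CI with probability
`1 − (1 − E_t)^n`; a female with `m` cifA copies rescues with probability
`1 − (1 − E_a)^m`. In CIFAB, `d` counts for both genes. For the
self-limiting architectures two toxin rules are supported: AB_REQUIRED
(both genes needed in the male; `n = min(n_cifA, n_cifB)`) and
B_SUFFICIENT (`n = n_cifB`). The `min`-count convention for partial
efficiency under AB_REQUIRED is our choice — the self-limiting analyses
of interest fix efficiency to 1, where it reduces to the all-or-nothing
rule — and is flagged for sensitivity analysis.

**Fitness** is a viability/fecundity multiplier of the cost-bearing
genotype: the drive allele in CIFAB, cifA copies only in the
self-limiting designs (the cargo is assumed to ride with the rescue;
cifB is costless). Multiplicative mode gives heterozygotes `√F`;
dominance mode gives `1 − c(1 − F)`.

## Panmictic deterministic models

Continuous-generation dynamics use the density-dependent pair
`b(N) = Nλ/(N(λ−1)+1)`, `d(N) = N²` with `λ = 9` and capacity `K = 1`;
genotype equations multiply birth weights by `λ/((λ−1)N+1)` and subtract
`x_g·N`. The birth weights enter as raw abundance products. We note for
completeness that the genotype-level equations then give a total birth
term of `N·b(N)` rather than `b(N)` away from capacity; we verified
numerically that normalizing the weights by `N` (which restores `b(N)`
exactly) changes none of the thresholds or boundaries reported here, so
the equations are kept in their stated product form. Both forms drive
`N → 1` from any positive density in the absence of the drive.

Integration uses LSODA with rtol 1e−9 / atol 1e−12; output is sampled at
10 points per generation for the trapezoidal integral metrics (averages
of absolute allele/carrier numbers over the first 100 generations divided
by the population-size integral). Any component pushed slightly negative
by discretization is clamped to zero.

**Threshold search.** Establishment means drive carrier frequency above
70% at generation 1000 (by then the system has settled onto its
equilibrium branch, and every nonzero equilibrium lies above 70%). The
bisection brackets [0, 1], terminates at width 1e−5 (0.001 percentage
points), and returns 1 when even `I = 1 − 1e−5` fails. The ideal drive
(F = 1, E_t = E_a = 1) yields 36.051%; establishment ceases entirely
below F = 0.73 (on a 0.01 grid; at F = 0.72 the drive dies even from a
99% release) and below a joint efficiency of ~0.26–0.30 with thresholds
climbing continuously toward 1 in that range.

**Discrete-generation map.** The infinite-population expectation of the
individual-based model: mothers weighted by frequency × fitness, fathers
sampled proportional to frequency × fitness, pair fertility from the CI
rules, Mendelian offspring, renormalized. The 10-candidate rejection cap
of the simulator is ignored (exact when all male fitnesses are 1). The
same bisection yields 36.455% — higher than the continuous threshold
because the post-release dip in allele frequency is deeper under discrete
generations (both models dip; the test suite checks the ordering).

**Two demes.** Following the model's stated formulation, migration
exchanges per-genotype *growth rates*: `dn₁/dt = (1−m)g₁ + m g₂`. This
differs from standard density migration `g₁ + m(n₂ − n₁)`, which is also
implemented behind a flag; the growth-rate form is the default.

**Influx.** A continuous source `φ·N` of drive homozygotes (fraction of
the *current* population per generation; a capacity-normalized constant
source is available behind a flag). At F = 0.95 the critical rate
computes to 3.9% per generation; at subcritical rates the allele
frequency equilibrates low (10.5% at 0.9·φ*). We note the published
value for this scenario is ~4.5%; we could not reproduce it under either
source normalization, any fitness in [0.90, 0.97], or shorter success
horizons, and report our computed value.

## Spatial deterministic model

The same reaction terms are embedded in a diffusion equation with
`D = v²/2` on the unit arena. Two symmetric reductions are solved by
method of lines (second-order central differences, BDF time stepping with
a sparse Jacobian pattern, rtol 1e−6 / atol 1e−9):

- **Slab** (512 nodes default): left 30% drive homozygotes at carrying
  density. Wave speed is `(x₂−x₁)/(t₂−t₁)` from the first times pointwise
  carrier frequency reaches 50% at x₁ = 0.5 and x₂ = 0.7. Runs are
  abandoned early once the front recedes behind x = 0.25 (inside the
  initial slab), which cannot precede an advancing wave. Boundary scans
  use a 5000-generation horizon because near-critical fronts move at
  ~1e−4 arena units per generation; the formation boundaries (F* = 0.93
  and joint efficiency 0.76 at v = 0.05, 0.01 grids) are unchanged from
  256 to 1024 nodes.
- **Radial** (400 nodes default, max radius 0.5): the polar term
  `(1/r)∂n/∂r` is replaced by its symmetric limit `∂²n/∂r²` at the
  origin; both ends are zero-flux. Whole-arena frequencies use
  annulus-weighted (2πr) trapezoidal quadrature. A coarse full-2D
  Cartesian solver is kept as an independent check and agrees with the
  radial reduction on symmetric inputs within discretization error.

Boundary conditions are reflecting everywhere — the dispersal rule of the
stochastic simulator (redraw until inside the arena) has no flux through
the edges, and the deterministic model mirrors that.

**Releases and critical sizes.** Circular releases come in additive mode
(drive density added on top of wild type at carrying density; a uniform
80% release has drive density `I/(1−I) = 4` inside the radius) and
replacement mode (total density held at carrying density). Release-size
formulas: `Vc = πR²·I/(1−I)` (uniform), `⅔πkR³ + πbR²` (linear radial
`kr+b`), `hπ(2r₀d + d²)` (ring, density capped at h ≤ 99; a ring needing
more is reported not-applicable). Two success criteria are exposed:
**expansion** (whole-arena carrier frequency at generation 15 above that
at generation 10 — the transient test used for circular releases) and
**establishment** (carrier above 70% within 200 generations). For the
uniform 80% release at v = 0.03, F = 1 the expansion criterion with
additive initialization gives a critical radius of 0.2293 (stable under
grid refinement), which matches the published 0.2305; the establishment
criterion gives larger radii (0.286 additive, 0.306 replacement) because
near-critical expanding transients can still stall and collapse later.
The corresponding release size `πbR²` is 0.66. The published size of
0.33 for this release equals `2πR²` at our radius — exactly half — and is
mutually inconsistent with the published radius under any single
criterion; we report the value our formula produces and flag the
discrepancy rather than resolving it.

## Individual-based simulator

Discrete, non-overlapping generations; every individual has a sex and a
genotype (and a position in the spatial mode). Each female samples
candidate males uniformly (spatially: uniformly among males within the
mating radius `r_m = v`), accepting each with probability equal to his
fitness relative to the population maximum, and gives up after 10
rejections. A sterile pairing consumes her reproduction. Offspring
counts are Binomial(M = 50, p = 2Fσ/M) with the mother's fitness and a
density factor σ; offspring sexes are uniform and genotypes draw one
allele per parent per locus. All randomness flows from one seeded
generator; identical seeds reproduce runs exactly.

Panmictic σ = (λ+1)/(λN/K + 1): two offspring per female at capacity,
~2(λ+1) near zero density. Spatial σ replaces `N/K` with `c_a/c_e`,
where `c_a` sums the triangular kernel `1 − r/r_c` over neighbours within
`r_c = 0.01` and `c_e = K·π r_c²/3` is its expectation at uniform
carrying density (we read the density in the expected-competition formula
as the carrying density, which makes σ average 1 at capacity — required
for the stated two-offspring equilibrium; the alternative reading, the
current population size, would cancel `c_a` entirely and remove density
regulation). Neighbour searches use a k-d tree whose results are exact,
matching brute force.

Because σ is convex in `c_a` and the expected neighbour count within
`r_c` is small (≈ π r_c² K ≈ 3 at K = 10⁴), many females see zero
competitors and realize σ far above its value at the mean; the spatial
stationary density therefore sits above the nominal K. This asymmetric-
competition artifact is intrinsic to the kernel, does not affect
frequency dynamics, and is the known cause of establishment-rate curves
converging below 50% in this model family.

Establishment (stochastic) means carrier frequency reaching 99% within
300 generations. At the discrete-map threshold frequency the
establishment probability is ~50% independent of K (the release sits
exactly on the separatrix of the expectation map, and the first
stochastic deviation decides the branch with symmetric probability); the
acceptance script estimates it from 500 replicates at K = 1000.
Spatial wave speed uses two 0.05-wide strips at x ∈ [0.5, 0.55] and
[0.7, 0.75] and the first generations their carrier frequencies exceed
50%; at v ≤ 0.07 it matches the deterministic PDE within stochastic
error (1–2% in our runs at K = 10⁴).

## Problem sizes and defaults

Deterministic thresholds use 1000-generation integrations and 1e−5
bisection precision; viability-boundary scans use 1e−3 precision (only
the threshold-equals-1 classification matters). Slab scans use 512 nodes
and a 5000-generation horizon with early abandonment; radial searches use
400 nodes with 2e−4 radius precision. The stochastic establishment
experiment uses 500 replicates at K = 1000; the spatial IBM comparison
uses one K = 10⁴ run. Grid-refinement tests confirm the reported
quantities are stable at half and double these resolutions.

## Known limitations

- No mutation, resistance alleles, sex-linked inheritance, linkage
  between the two self-limiting loci, or maternal (cytoplasmic)
  transmission — the constructs are ordinary nuclear transgenes.
- Constant carrying capacity and homogeneous, isotropic terrain; no age
  structure, seasonality, or interspecific interactions.
- The deterministic models assume infinite populations; the simulator
  covers finite-size stochasticity but with synchronized generations.
- The printed-value discrepancies discussed above (efficiency viability
  boundary, uniform-circle release size, critical influx) are reported
  as computed; the flags that expose alternative criteria, initialization
  modes, and source normalizations are the supported instruments for
  exploring them.
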