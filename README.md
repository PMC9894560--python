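# cifdrive

Population-dynamic models of gene drives built from the *Wolbachia*
cytoplasmic-incompatibility genes *cifA* and *cifB*.

Cytoplasmic incompatibility (CI) is a paternal "toxin" with a maternal
"antidote": when a male expressing the toxin (CifB, in some systems only
together with CifA) mates with a female that does not express the rescue
(CifA), the cross produces no viable offspring. Inserting the two genes
into an insect genome — instead of infecting the insect with *Wolbachia*
itself — yields a Mendelian toxin–antidote element. With both genes in
one construct (the **CifAB drive**) the element behaves as a confined,
high-threshold modification drive; with the genes on separate constructs
it is a **self-limiting** killer–rescue system. `cifdrive` implements the
full modeling stack for both designs:

- **genetics** — the cross engine for three architectures (one-locus
  CifAB, one-locus three-allele *w/a/b*, two unlinked loci): genotype
  fitness, toxin/antidote probabilities, cross sterility, Mendelian
  offspring distributions, and birth weights by generic pair enumeration.
- **panmictic** — continuous-generation ODEs, the discrete-generation
  expectation map, two demes linked by migration, a continuous drive
  influx, trajectory metrics, and threshold bisections.
- **selflimiting** — killer–rescue variants and protection-time metrics.
- **spatial** — 1D slab and radially symmetric reaction–diffusion models,
  wave-speed measurement, and critical-release-size searches for uniform,
  linear-radial, and ring releases.
- **ibm** — an individual-based stochastic simulator (panmictic and 2D
  spatial) with fitness-dependent mate choice, CI sterility, binomial
  offspring numbers, a local competition kernel, and Gaussian dispersal.

## The model

All abundances are relative to the carrying capacity `K = 1`. A
wild-type population follows

```
dN/dt = b(N) − d(N),   b(N) = Nλ / (N(λ−1) + 1),   d(N) = N²
```

with low-density growth rate `λ = 9`, so the per-capita growth rate is λ
near zero density and zero at capacity. With genotypes `x₁ = dd`,
`x₂ = dw`, `x₃ = ww`, each genotype's abundance obeys

```
dx_g/dt = F_g · Σcombinations(g) · λ/((λ−1)N + 1) − x_g N
```

where `Σcombinations(g)` sums, over ordered parental pairs, the product
of parental abundances, the pair's fertility under CI, and the Mendelian
probability of producing `g`. Fertility of a (male m, female f) pairing
is `1 − toxin(m)·(1 − antidote(f))` with per-allele multiplicative
efficiencies: a drive-homozygous male has toxin probability
`1 − (1 − E_t)²`, a female with one *cifA* copy has antidote probability
`E_a`. Fitness costs are multiplicative by default (heterozygote `√F`),
or `1 − c(1 − F)` under an explicit dominance coefficient, and attach to
*cifA* copies only in the self-limiting architectures.

Because drive males sterilize wild-type females, the CifAB drive has an
unstable internal equilibrium at 50% carriers: releases above a critical
introduction frequency drive the allele to fixation, releases below it
are eliminated. The spatial models embed the same reaction terms in a
diffusion equation with `D = v²/2`, where `v` is the per-axis standard
deviation of parent–offspring displacement.

## Worked example

Find the introduction threshold of the ideal drive and summarize a 50%
release:

```
$ cifdrive threshold
{ ... "metrics": { "threshold": 0.3605119893264771 } ... }

$ cifdrive trajectory -i 0.5 --t-end 1000
{ ... "metrics": {
  "average_allele_frequency": 0.9154071352410227,
  "average_carrier_frequency": 0.9784889999559345,
  "equilibrium_allele_frequency": 0.9979759580483093,
  "equilibrium_carrier_frequency": 0.9999959032375597,
  "first_generation_carrier_70": 2.1 } ... }
```

The threshold — the minimum release frequency of drive homozygotes for
carrier frequency to exceed 70% by generation 1000 — is 36.051% for a
cost-free, fully efficient drive. A 50% release is comfortably above it:
carriers pass 70% within ~2 generations and the allele approaches
fixation, with an average carrier frequency of 97.8% over the first 100
generations.

A self-limiting two-locus release shows confinement in time instead:

```
$ cifdrive self-limiting -i 0.5 --fitness 0.95
{ ... "metrics": {
  "protection_time": 722.1548923607178,
  "max_cifA_carrier": 0.9941380689172343,
  "generation_of_max": 166.0, ... } ... }
```

The *cifA* carrier frequency peaks at 99.4% around generation 166 and
stays above 80% for 722 generations; because *cifB* males gain no
transmission advantage, the toxin allele is lost, after which the costly
rescue declines and the wild type returns.

Other subcommands: `two-deme`, `influx`, `wave-speed`,
`critical-release`, `ibm-establish`, `ibm-wave` (see `cifdrive --help`).

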