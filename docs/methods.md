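# Methods

## Model

`udsim` implements a deterministic, discrete-generation population-genetics
model of a two-locus engineered underdominance (UD) gene drive in a closed,
panmictic population of effectively infinite size. The two constructs sit at
unlinked loci and segregate freely. Each construct has three components —
lethal effector, cross-locus suppressor, cargo — and each component can be
irreversibly knocked out by a loss-of-function mutation, giving nine allele
states per locus (wild-type, intact construct, and the 2^3 − 1 = 7 knockout
classes). The state space is the 2025-dimensional simplex of genotype
frequencies (45 unordered allele pairs per locus, paired across loci).

**Viability.** A genotype is non-viable exactly when it carries at least one
functional lethal at one locus and zero functional suppressors at the other
locus, in either direction. Suppression is all-or-nothing: one functional
suppressor copy rescues any number of lethal copies; lethality is likewise
binary (no partial-penetrance parameter). Of the 2025 genotypes, 819 are
non-viable under this rule (the test suite re-derives this with an
independent 45 × 45 brute-force loop).

**Fitness.** Viable genotypes have multiplicative per-copy fitness
`eps_A^beta * eps_AM^phi * eps_B^mu * eps_BM^psi`, where `beta`/`mu` count
intact construct copies and `phi`/`psi` mutated copies per locus. All mutated
classes at a locus share one fitness value regardless of which or how many
components are broken; fitness is a survival-to-reproduction weight applied
once per generation to offspring.

**One generation.** (i) Post-selection adults produce a pooled Mendelian
gamete distribution over the 81 haplotypes; (ii) mutation acts on the pool;
(iii) offspring genotype frequencies follow random union of two independent
draws from the mutated pool; (iv) offspring are weighted by fitness and the
vector is renormalised by the population mean fitness. Working with the
81-dimensional gamete pool instead of the 2025 × 2025 mating table makes a
generation O(81²); the suite verifies numerical identity (to 1e-10, typically
machine precision) against an explicit mating-pair-table oracle rather than
assuming the algebraic equivalence.

**Mutation.** Each transmitted allele mutates independently during gamete
production. The per-locus 9 × 9 transition matrix places probability `m` on
each single-component knockout edge and `1 − k·m` on the diagonal (k =
number of still-functional components), so a construct with all three
components intact mutates at total rate 3m. Multiple hits within one
generation are excluded by construction (the transition is linear in m);
rows sum to one exactly, so no renormalisation is needed. The wild-type
allele and the fully knocked-out construct are absorbing; there is no
back-mutation. The joint haplotype transition is the Kronecker product of
the two per-locus matrices, applied as two 9 × 9 products.

**Releases.** A release at ratio `alpha` (introduced individuals relative to
the entire resident population at the moment of release) rescales resident
frequencies by `1/(1 + alpha)` and adds `alpha/(1 + alpha)` on the released
genotype. Released individuals are mutation-free. Generation 0 is the
post-release initial state, so a lone release at generation 0 reproduces the
textbook initial condition `G_wild = 1/(1+alpha)`, `G_released =
alpha/(1+alpha)`; "release at generation t" applies after t steps, before
step t + 1. Free-suppressor releases use the suppressor-only allele class:
in the full genotype model an engineered free-suppressor construct is
identical to the lethal-and-cargo-knockout allele (`A_LC`/`B_LC`, accepted in
labels as `A_Rev`/`B_Rev`) and carries the mutated-construct fitness.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `eps_A`, `eps_B` | fitness per intact construct copy (dimensionless, [0,1]) | 0.95 |
| `eps_AM`, `eps_BM` | fitness per mutated construct copy | 0.96 |
| `eps_Rev` | fitness per free-suppressor copy (three-allele reduced model only) | 0.96 |
| `m` | per-gene loss-of-function rate per generation, [0, 1/3] | 1e-6 |
| `alpha` | release ratio, introduced/resident | 1.0 (initial drive release) |

The defaults are the canonical study conditions: intact constructs cost 5%
per copy and mutated ones 4%, so mutants out-compete the drive but not the
wild-type — the regime in which mutation accumulates and eventually
dismantles the drive. With mutants *less* fit than intact constructs the
drive progresses without mutant accumulation (a property test covers this).
Mutation rates of interest span 1e-4–1e-8 per gene per generation, bracketing
per-gene knockout rates implied by measured per-nucleotide rates in
*Drosophila*, kilobase-scale components and a 1–10% essential-site fraction.

## Metrics

All "return to wild-type" judgements use the minimum of the two per-locus
wild-type allele frequencies (conservative; symmetric scenarios keep the loci
equal). Transgene *elimination* means the total non-wild allele frequency at
both loci has fallen below 1e-3 and is non-increasing. The *efficacious
period* counts generations in which the summed frequency of cargo-functional
transgenic alleles (intact construct plus lethal- and/or suppressor-knockouts
with cargo intact) exceeds the threshold (default 0.85) at **both** loci —
an allele-frequency convention, chosen over a carrier-frequency one because
the trajectory record is allele-based; with thinned recording each recorded
generation stands for the interval since the previous record.

The minimal reversing release ratio is found by bisection (default tolerance
0.005) on the outcome eliminated-vs-persistent, after establishing the drive
with a 1:1 release for 100 generations; each candidate release is iterated
until elimination or convergence (L1 step change < 1e-13) up to a 50 000
generation cap. Under the defaults this yields ≈ 1.74 for wild-type releases
at `eps = 0.95`, and thresholds indistinguishable from zero for
free-suppressor releases with a fitness edge over the drive.

## Reduced models and stability

The mutation-free reduced models track the adult gamete-pool (haplotype)
frequency vector on a small per-locus allele set: {wild, construct} (4
haplotypes) or {wild, construct, free suppressor} (9 haplotypes). The map is
the exact gamete-pool form of the genotype recursion restricted to the
reduced alleles, so reduced and full models produce identical allele
trajectories at m = 0 — verified to 1e-10 in the suite, not assumed.

Fixed points are located by forward iteration plus root polishing
(`scipy.optimize.root`, hybr) on simplex coordinates (last haplotype
frequency eliminated), deduplicated within 1e-8 and accepted at residual
< 1e-10. Stability is the spectral radius of a central-difference Jacobian
(step 1e-7) of the simplex-coordinate map — eliminating a coordinate removes
the spurious unit eigenvalue normalisation would contribute. Radii within
1e-6 of 1 are *marginal*: at `eps = 1` the all-construct fixation has
spectral radius exactly 1 because selection against rare wild alleles is
second-order there. An optional refinement settles marginal cases by a
deterministic perturbation ensemble (size-1e-4 Dirichlet mixtures iterated up
to 5 × 10^4 generations); at `eps = 1` the ensemble contracts, so the point
is classified stable by higher-order dynamics. The same ensemble is used to
cross-check every linear classification.

Key numerical outcomes (recomputed by the tests): the wild-type equilibrium
is stable for all `eps` in [0, 1]; the two-allele introgression equilibrium
is stable for `eps` between the release-ratio-dependent threshold `eps*`
(operationally defined by bisection to 5e-4 on introgression-vs-loss;
≈ 0.876 at a 1:1 release) and 1; adding a free-suppressor allele with
`eps_Rev ≥ eps` renders the introgression equilibrium unstable — the
mechanism by which arbitrarily small free-suppressor releases reverse an
established drive, with recovery times varying little across release ratios
spanning two orders of magnitude.

## Numerical choices

- Double precision throughout; the only clipping zeroes round-off negatives
  above −1e-15. Frequency conservation holds to 1e-12 per generation.
- A zero mean fitness (possible only for states supported on non-viable
  genotypes, which the recursion itself never produces) raises a
  `DegeneratePopulationError` rather than returning NaNs.
- Genotype indexing is canonical — alleles ordered wild-type, intact, then
  knockouts by count in L < S < C order; unordered pairs lexicographic — so
  trajectories are bit-reproducible and CSV round-trips are exact.
- Scenario runs support early stopping on a wild-type threshold or on
  convergence; the acceptance script runs the *m* = 1e-5 collapse to
  convergence (≈ 1.8 × 10^3 generations) and caps reversal searches at
  5 × 10^4 generations per candidate, sizes at which every reported quantity
  has visibly saturated.

## What the scenarios do and do not show

The simulated scenarios are self-contained: no external data enter, so
"passing" means the deterministic model behaves as analysed, not that a field
release would. The model omits, by design: finite-population (stochastic)
effects — particularly relevant to the very small free-suppressor releases,
where drift could extinguish the released allele; overlapping generations and
age structure; spatial structure and migration; density dependence; partial
loss of function (mutations are all-or-nothing); fitness differences among
mutated classes; recombination within a construct and multi-component
deletions; sex-specific effects; and pre-existing resistance polymorphisms in
the target population. Mutated-class fitness sharing a single per-locus value
is a deliberate simplification; the time scales reported are sensitive to it.

## Known limitations

- The reversal-threshold bisection assumes the eliminated/persistent outcome
  is monotone in the release ratio (true in all parameter regimes examined).
- Equilibrium finding samples a fixed start set; equilibria with basins far
  from those starts (none are known for these models) could be missed.
- `epsilon_star` and the stability report classify equilibria of the reduced
  models only; the full 2025-genotype model at m > 0 has no non-trivial
  equilibria to classify (mutation makes the drive states transient).
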