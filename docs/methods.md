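# Methods

`noiasim` studies how non-additive gene action (dominance and epistasis),
combined with allele-frequency divergence, drives the additive genetic
correlation between two populations (rg) below one.  It couples a
forward-in-time Wright–Fisher simulator of two diverging livestock-like
populations with the NOIA (natural and orthogonal interactions)
reparameterization of genotypic values, from which population-specific
average effects — and hence rg — are computed exactly from the known
functional effects.  No estimation from phenotypes is involved anywhere:
rg is a *true* parameter of the simulated system.

## Populations and genome

The genome is 10 chromosomes of 1 Morgan, each with 200 randomly placed
bi-allelic loci.  Meiosis follows a no-interference Poisson crossover
model (expected one crossover per Morgan); the per-generation simulator
draws, for each gamete, haplotype-switch indicators between consecutive
loci with Haldane probabilities r = (1 − e^(−2d))/2, which is
distributionally identical to explicit Poisson breakpoints at the locus
resolution (the single-meiosis routine implements the explicit
construction and the two are cross-checked in the test suite).

Founders can be produced two ways:

* **Historical burn-in** (`simulate_burn_in`): ~3000 generations of random
  mating (100 males/500 females) through a bottleneck to 150, recovery to
  600, then constant size, with recurrent allele-flip mutation at
  2.5×10⁻⁵ per locus per gamete.  Sizes between the stated endpoints are
  linearly interpolated at a 1:5 sex ratio (the endpoints are all that is
  specified; linear is the simplest monotone schedule).  The final
  generation is doubled to 200 males/1000 females.  The resulting
  spectrum of segregating loci is strongly U-shaped.
* **Fast founders** (`sample_founders_fast`, the default for tests and
  reproduction runs): allele frequencies drawn directly from a U-shaped
  density ∝ 1/(p(1−p)), genotypes in Hardy–Weinberg proportions, loci
  independent (zero LD).  The truncation bound of the density is 1e-4.
  This value was calibrated once against the burn-in route: the discrete
  mutation–drift process piles segregating loci into the lowest
  copy-number classes, and a continuous density truncated at the naive
  sample resolution 1/(2N) = 1/2400 underestimates that near-boundary
  mass (realized QTL-panel heterozygosity 0.066 instead of the burn-in's
  0.055, with knock-on effects on every variance fraction).  With the
  calibrated bound, loci drawn below the sample resolution mostly come
  out monomorphic in the founder sample and are excluded by the
  segregation filter — the same ascertainment that operates in the
  explicit history.  The bound (and the whole spectrum) is a parameter.

500 of the segregating loci become QTL.  Divergence proceeds for 50
non-overlapping generations in two disjoint populations founded by
100+500 / 100+500 parents sampled from generation 0.  Each generation,
100 sires and 500 dams are selected, each sire is assigned exactly 5 dams
uniformly at random, and each mating leaves exactly 5 offspring (2500
offspring, exactly 1250 of each sex).  Selection is either random (drift)
or truncation on own phenotype within sex (mass selection), with
selection only ever applied in population 1.  Ties in truncation
selection break by ascending individual index so runs are reproducible.
After QTL selection the simulation tracks only the QTL panel; the other
loci carry no effects and, with founder LD zero, do not influence any
reported quantity.

Because generation 0 contains exactly the 600 individuals each population
needs as parents, the first advance involves no selection; mass selection
first acts when the parents of generation 2 are chosen.

## Trait architectures

Functional (frequency-independent) effects per scenario:

* additive: a ~ N(0, 1) per QTL;
* dominance: d = δ|a| with δ ~ N(μδ, σδ²); presets σδ = 0.3 / 0.7 / 1.5
  (small / intermediate / large), μδ = 0.2 throughout;
* epistasis: a random 5-regular interaction graph over the QTL (1250
  pairs); ε_kl = γ_kl|a_k a_l| with γ ~ N(0, σγ²) and
  σγ = sqrt((μδ² + σδ²)/Nγ), which equates the expected total functional
  epistatic variance with the dominance analogue of the same magnitude.

A scenario has either dominance or epistasis, never both.  The epistatic
configuration is one of four canonical 3×3 two-locus tables — additive×
additive (outer product of (1,0,−1) scores), dominance×dominance (outer
product of (−1,1,−1)), complementary (value 1 unless either locus is the
recessive homozygote), multiplicative (product of allele counts) — each
flattened with the first locus's genotype varying fastest, centered and
scaled to unit SD over the 9 cells (unweighted, divisor 9) so that
configurations are comparable.  Frequency-weighted scaling would make the
contrast population-specific, contradicting its functional role.  The
`effect_multiplier` knob scales d and ε after sampling (×100 in the
magnitude-asymptote experiment) and leaves a untouched.

## From functional to statistical effects (NOIA)

Per locus with genotype frequencies (p_XX, p_Xx, p_xx), the NOIA design
W = [1, w_a, w_d] scores genotypes by the additive contrast
w_a = count − mean count and the dominance contrast
w_d = (−2p_Xx p_xx, 4p_XX p_xx, −2p_XX p_Xx)/(p_XX + p_xx − (p_XX − p_xx)²),
orthogonal under the population's own genotype frequencies.  Functional
per-locus values (a, d, −a) are projected exactly onto this basis (under
Hardy–Weinberg proportions the average effect reduces to the familiar
α = a + (1 − 2p)d).  Each pair's 9-cell table ε·t is partitioned by the
weighted least-squares projection b = (W′DW)⁻¹W′Dc with D the two-locus
genotype frequencies; with all 9 classes populated this is an exact
reparameterization, and the pair's α_k/α_l and d_k/d_l terms accumulate
onto the member loci:

    α_k = a_k + (1 − 2p_k) d_k + Σ_l α_k^(kl),   d*_k = d_k + Σ_l d_k^(kl).

Numerical choices:

* **Frequency source** — observed genotype frequencies of the current
  generation (NOIA is exact under arbitrary frequencies), except that a
  locus whose allele frequency leaves [0.005, 0.995], whose dominance
  denominator vanishes, or which has an empty genotype class is replaced
  by Hardy–Weinberg proportions at the clamped allele frequency.  An
  empty class would put one contrast in the null space of the weighting
  and make the projection singular; such near-fixed loci carry almost no
  additive variance, so the clamp has no measurable effect on rg or the
  variance fractions.
* **Two-locus weights** — the product of the two loci's marginal genotype
  frequencies (linkage-equilibrium weighting).  Founder QTL are in low
  LD by construction, and observed joint 9-cell tables routinely have
  empty cells.
* **Ordering** — two-locus cells and effect vectors are ordered with the
  genotype of the first locus varying fastest, so the pair design is
  kron(W_l, W_k); the exact-reconstruction property test fails loudly on
  any ordering mistake.

Breeding values are v = h_a′α with h_a the centered allele counts of the
genotyped population; genotypic values add the dominance term h_d′d* and
the four per-pair interaction terms.  Up to an additive constant (the μ
terms are dropped) they equal the frequency-independent functional
genotypic values, which is tested exactly.

Phenotypes are y = g + e with e ~ N(0, σe²) and broad-sense heritability
0.5; g is the functional genotypic value (frequency-independent, so no
per-generation repartitioning is needed for selection).  σe² equals the
genotypic variance of the current selection candidates, refreshed every
generation, so broad-sense heritability stays at 0.5 throughout even as
genetic variance erodes.  (The alternative — freezing σe² at its
generation-1 value — lets realized heritability decay with V_A and
weakens late-generation selection; `phenotypes` accepts an explicit
`sigma_e` for callers who want that convention.)

## Reported quantities

At generations 1–5 and every 5th generation to 50:

* **rg** — Pearson correlation, over population-1 individuals, of
  breeding values computed with α^P1 versus α^P2 (population-1 genotypes
  and centering; the mirrored variant exists but is not used in the
  headline runs).  rg = 1 exactly for a purely additive trait or when the
  populations share allele frequencies.
* **Δp̄** — mean |p^P1 − p^P2| over all 500 QTL, fixed loci included in
  the denominator.
* **Variance fractions** — variances over individuals of the additive,
  dominance and (summed) epistatic components of genotypic value, each
  divided by their sum.  Between-component covariances (from realized LD)
  are dropped so the fractions sum to one; the components are orthogonal
  under the NOIA weighting.  Fractions are averaged ratio-then-average
  across replicates.
* **ḡ** — mean genotypic value minus its generation-1 mean, in units of
  the generation-1 genotypic SD (a diagnostic of selection response).
* **V_A loss** — replicate-averaged 1 − V_A(50)/V_A(1).

## Replicates and seeding

Drift genotype trajectories are seeded independently of the trait
scenario, so all drift scenarios of a grid share the same genotype
replicates and differ only in the sampled architecture (the study design
reuses drift genotypes across scenarios); selection trajectories are
scenario-specific.  All streams derive from a master seed through named
seed sequences, making every run byte-reproducible (results CSVs are
rounded to 6 decimals).

## Problem sizes

Full population sizes (2500 offspring per generation per population) and
the full 50 generations are always used; they drive the phenomena.  The
package's reproduction runs (`scripts/acceptance.py`) use fast founders
and 10 replicates per scenario — replicate count only narrows the error
bars on replicate means, and 10 keeps a complete reproduction under ten
minutes on one core.  Property suites run on miniature populations in
seconds.

## What the generator does and does not emulate

The simulator reproduces the study conditions: a U-shaped founder
spectrum with low LD among QTL, hierarchical 100×500 mating with fixed
litter size, mass selection on own phenotype, and trait architectures
with proportional dominance/epistatic effects.  It does not attempt
sequence-level realism (no nucleotides or indels), overlapping
generations, migration, GxE, higher-order epistasis, or mutation after
generation 0 — the last of these means additive variance is never
replenished, and nearly all of it erodes over 50 generations of
selection.  Passing tests therefore validate the mechanism linking
non-additive gene action, frequency divergence and rg under these
idealized conditions; they say nothing about, e.g., traits whose
epistatic networks are directional or frequency-dependent.

## Known limitations

* The linear interpolation of the historical bottleneck sizes is an
  assumption; only the endpoints are specified.  The burn-in's effective
  size (and hence its exact spectrum) depends on it, which is one reason
  the fast founder spectrum is calibrated to the burn-in output rather
  than derived analytically.
* The exact 9-cell tables of the complementary and multiplicative
  configurations are taken in their textbook forms.
* With the hierarchical mating design the realized effective size per
  population is ≈350 (dam litter sizes are equalized), somewhat above
  the 4NmNf/(Nm+Nf) ≈ 333 of idealized random family sizes; drift-mode
  divergence reflects this.
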