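"""Founder generation.

Two routes produce the generation-0 founder population:

* :func:`simulate_burn_in` — an explicit historical population: thousands of
  generations of random mating through a bottleneck and recovery, with
  recurrent mutation, after which the allele-frequency spectrum of
  segregating loci has drifted to a U-shape and linkage disequilibrium
  among distant loci is low.
* :func:`sample_founders_fast` — a desk-scale shortcut that draws founder
  allele frequencies directly from a (by default U-shaped) spectrum and
  genotypes in Hardy-Weinberg proportions with zero LD, matching the
  burn-in's stated outcome without its cost.

Both return a :class:`~noiasim.population.Population` and are
interchangeable for every downstream module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genome import ConfigurationError, GenomeMap
from .meiosis import gamete_batch
from .population import FEMALE, MALE, Population

#: Per-locus per-gamete recurrent mutation rate during historical generations.
HISTORICAL_MUTATION_RATE = 2.5e-5


@dataclass(frozen=True)
class DemographyConfig:
    """Schedule of (n_males, n_females) per historical generation.

    ``schedule[t]`` gives the size of historical generation ``first_generation
    + t``; the last entry is generation 0, the founder generation.  Mutation
    (recurrent allele flip) operates during the historical generations only.
    """

    schedule: tuple[tuple[int, int], ...]
    mutation_rate: float = HISTORICAL_MUTATION_RATE
    first_generation: int = -3001

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ConfigurationError("mutation_rate must be in [0, 1)")
        for nm, nf in self.schedule:
            if nm <= 0 or nf <= 0:
                raise ConfigurationError("population sizes must be positive")

    @classmethod
    def default(cls) -> "DemographyConfig":
        """The full historical demography: 100 males / 500 females from
        generation -3001, a linear bottleneck to 25/125 over generations
        -3000..-2501, linear recovery to 100/500 over the next 100
        generations, constant size until generation -1, and a doubled
        final generation 0 of 200 males / 1000 females.  Sex ratio is 1:5
        throughout."""
        sched: list[tuple[int, int]] = [(100, 500)]            # gen -3001
        for g in range(-3000, -2500):                          # decline to 150
            frac = (g + 3000) / 499.0
            nm = round(100 + frac * (25 - 100))
            sched.append((nm, 5 * nm))
        for g in range(-2500, -2400):                          # recovery to 600
            frac = (g + 2500) / 99.0
            nm = round(25 + frac * (100 - 25))
            sched.append((nm, 5 * nm))
        for _ in range(-2400, 0):                              # equilibrium
            sched.append((100, 500))
        sched.append((200, 1000))                              # generation 0
        return cls(tuple(sched))

    @classmethod
    def constant(
        cls, n_generations: int, n_males: int, n_females: int,
        mutation_rate: float = HISTORICAL_MUTATION_RATE,
    ) -> "DemographyConfig":
        """Reduced constant-size schedule, mainly for testing."""
        return cls(
            tuple((n_males, n_females) for _ in range(n_generations + 1)),
            mutation_rate=mutation_rate,
            first_generation=-n_generations,
        )


def _random_hwe_population(
    freqs: np.ndarray, n_males: int, n_females: int, rng: np.random.Generator,
    generation: int,
) -> Population:
    n = n_males + n_females
    hap = (rng.random((n, freqs.size, 2)) < freqs[None, :, None]).astype(np.uint8)
    sex = np.concatenate([np.full(n_males, MALE, np.uint8),
                          np.full(n_females, FEMALE, np.uint8)])
    return Population(hap, sex, generation)


def _offspring_sexes(n_males: int, n_females: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.concatenate([np.full(n_males, MALE, np.uint8),
                          np.full(n_females, FEMALE, np.uint8)])
    return rng.permutation(sex)


def simulate_burn_in(
    genome: GenomeMap,
    demography: DemographyConfig,
    rng_seed: int | np.random.Generator = 0,
    initial_freq: np.ndarray | None = None,
) -> Population:
    """Run the historical random-mating population and return generation 0.

    Initial allele frequencies are uniform(0, 1) per locus unless
    ``initial_freq`` is given.  Each generation, every female is assigned
    one uniformly drawn male; offspring draw their mother uniformly from
    the females and inherit recombinant, mutated gametes.
    """
    rng = np.random.default_rng(rng_seed)
    if initial_freq is None:
        initial_freq = rng.uniform(0.0, 1.0, size=genome.n_loci)
    else:
        initial_freq = np.asarray(initial_freq, dtype=float)
        if initial_freq.size != genome.n_loci:
            raise ConfigurationError("initial_freq must have one entry per locus")

    nm0, nf0 = demography.schedule[0]
    pop = _random_hwe_population(initial_freq, nm0, nf0,
                                 rng, demography.first_generation)
    lmap = genome.locus_map
    mu = demography.mutation_rate

    for step, (nm, nf) in enumerate(demography.schedule[1:], start=1):
        males, females = pop.males, pop.females
        n_off = nm + nf
        mate_of = rng.choice(males, size=females.size)       # one male per female
        mother_slot = rng.integers(females.size, size=n_off)
        mothers = females[mother_slot]
        fathers = mate_of[mother_slot]
        mat = gamete_batch(pop.haplotypes, mothers, lmap, rng, mutation_rate=mu)
        pat = gamete_batch(pop.haplotypes, fathers, lmap, rng, mutation_rate=mu)
        hap = np.stack([mat, pat], axis=2)
        pop = Population(hap, _offspring_sexes(nm, nf, rng),
                         demography.first_generation + step)
    return pop


# ---------------------------------------------------------------------------
# Fast founder shortcut
# ---------------------------------------------------------------------------

SpectrumSampler = Callable[[np.random.Generator, int], np.ndarray]

#: Truncation bound of the default U-shaped founder spectrum.  Calibrated so
#: that the fast path's realized generation-0 spectrum matches the one the
#: historical burn-in produces (mean heterozygosity and near-boundary mass
#: of segregating loci): the discrete mutation-drift process piles more
#: loci into the lowest copy-number classes than a 1/(p(1-p)) density
#: truncated at the sample resolution 1/(2N) would, which an effective
#: bound of 1e-4 reproduces.  See docs/methods.md.
DEFAULT_SPECTRUM_BOUND = 1e-4


def u_shaped_spectrum(lower: float, upper: float) -> SpectrumSampler:
    """Sampler for the density proportional to ``1/(p(1-p))`` truncated to
    ``[lower, upper]`` — the classic mutation-drift-equilibrium shape.

    Its CDF is linear on the logit scale, so draws are ``expit`` of a
    uniform variate between ``logit(lower)`` and ``logit(upper)``.
    """
    if not (0.0 < lower < upper < 1.0):
        raise ConfigurationError(
            f"degenerate spectrum truncation bounds: [{lower}, {upper}]"
        )
    lo = math.log(lower / (1.0 - lower))
    hi = math.log(upper / (1.0 - upper))

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.uniform(lo, hi, size=size)
        return 1.0 / (1.0 + np.exp(-u))

    return sample


def point_mass_spectrum(p: float) -> SpectrumSampler:
    """Degenerate spectrum putting all loci at frequency ``p``."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, p)

    return sample


def sample_founders_fast(
    genome: GenomeMap,
    n_males: int = 200,
    n_females: int = 1000,
    spectrum: SpectrumSampler | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> Population:
    """Draw a generation-0 founder population directly from an
    allele-frequency spectrum.

    Genotypes are in Hardy-Weinberg proportions per locus and loci are
    mutually independent (zero LD by construction).  The default spectrum
    is U-shaped, ``∝ 1/(p(1-p))`` truncated to
    ``[DEFAULT_SPECTRUM_BOUND, 1 - DEFAULT_SPECTRUM_BOUND]``, which
    reproduces the generation-0 spectrum of the historical burn-in
    (loci drawn below the sample resolution mostly come out monomorphic
    and are excluded by the downstream segregation filter, exactly as in
    the explicit history).
    """
    if n_males <= 0 or n_females <= 0:
        raise ConfigurationError("founder counts must be positive")
    rng = np.random.default_rng(rng_seed)
    if spectrum is None:
        b = DEFAULT_SPECTRUM_BOUND
        spectrum = u_shaped_spectrum(b, 1.0 - b)
    freqs = spectrum(rng, genome.n_loci)
    return _random_hwe_population(freqs, n_males, n_females, rng, generation=0)


def select_qtl(
    pop: Population, n_qtl: int, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Randomly select ``n_qtl`` distinct segregating loci to become QTL.

    Raises
    ------
    ValueError
        If fewer than ``n_qtl`` loci segregate; the message reports the
        deficit.
    """
    rng = np.random.default_rng(rng_seed)
    seg = np.flatnonzero(pop.segregating())
    if seg.size < n_qtl:
        raise ValueError(
            f"requested {n_qtl} QTL but only {seg.size} loci segregate "
            f"(deficit {n_qtl - seg.size})"
        )
    return np.sort(rng.choice(seg, size=n_qtl, replace=False))


# ---------------------------------------------------------------------------
# Optional export
# ---------------------------------------------------------------------------

def write_vcf(pop: Population, genome: GenomeMap, path: str,
              sample_prefix: str = "ind") -> None:
    """Write phased diploid genotypes as a minimal VCFv4.2 text file.

    One contig per chromosome; genetic positions (Morgan) are scaled by
    1e6 and rounded to integer coordinates.  The counted allele is written
    as the ALT allele.
    """
    chrom = genome.chrom
    pos = np.rint(genome.positions * 1e6).astype(np.int64)
    n = pop.n_individuals
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    hap = pop.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=noiasim\n")
        for c in range(genome.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(genome.chrom_length * 1e6) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k in range(genome.n_loci):
            gts = "\t".join(f"{hap[i, k, 0]}|{hap[i, k, 1]}" for i in range(n))
            fh.write(f"chr{chrom[k] + 1}\t{pos[k]}\tlocus{k}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")
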