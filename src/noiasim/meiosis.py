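"""Meiosis: recombinant gametes on a genetic map.

Crossovers follow a homogeneous Poisson process along each chromosome
(no interference), with the expected number of crossovers per meiosis equal
to the chromosome's genetic length in Morgan.  Two implementations are
provided:

* :func:`make_gamete` draws explicit Poisson crossover counts and uniform
  breakpoints for a single meiosis.
* :func:`gamete_batch` draws, for many meioses at once, haplotype-switch
  indicators between consecutive loci with Haldane probabilities
  ``r = (1 - exp(-2 d)) / 2``.  By the Markov property of the Poisson
  crossover process the two constructions induce the same joint
  distribution of gametes at the locus resolution; the batch form is the
  one used in the per-generation simulation loop.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeMap, LocusMap


def _as_locus_map(genome) -> LocusMap:
    return genome.locus_map if isinstance(genome, GenomeMap) else genome


def switch_probabilities(lmap: LocusMap) -> np.ndarray:
    """Per-locus probability that the parental haplotype differs from the
    previous locus.  The first locus of each chromosome (and of the genome)
    gets 0.5: chromosomes segregate independently and the starting
    haplotype is a fair coin."""
    pos, chrom = lmap.positions, lmap.chrom
    r = np.empty(lmap.n_loci)
    r[0] = 0.5
    if lmap.n_loci > 1:
        d = np.diff(pos)
        same = chrom[1:] == chrom[:-1]
        r[1:] = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * d)), 0.5)
    return r


def gamete_batch(
    haplotypes: np.ndarray,
    parents: np.ndarray,
    genome,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> np.ndarray:
    """Draw one recombinant gamete per entry of ``parents``.

    Parameters
    ----------
    haplotypes
        (n, L, 2) phased genotypes of the parental population.
    parents
        (m,) individual indices; one gamete is produced per entry
        (repeats allowed).
    genome
        :class:`GenomeMap` or :class:`LocusMap` giving locus layout.
    mutation_rate
        Per-locus, per-gamete probability of a recurrent allele flip.

    Returns
    -------
    (m, L) uint8 array of gamete alleles.
    """
    lmap = _as_locus_map(genome)
    parents = np.asarray(parents)
    m, L = parents.size, lmap.n_loci
    r = switch_probabilities(lmap).astype(np.float32)
    switches = rng.random((m, L), dtype=np.float32) < r
    which = np.bitwise_xor.accumulate(switches, axis=1)   # parity of switches
    h = haplotypes[parents]                               # (m, L, 2)
    gam = np.where(which, h[:, :, 1], h[:, :, 0])
    if mutation_rate > 0.0:
        flips = rng.random((m, L)) < mutation_rate
        gam = gam ^ flips
    return gam.astype(np.uint8, copy=False)


def make_gamete(
    genome,
    parent_haplotypes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single meiosis with explicit Poisson crossovers.

    Per chromosome: crossover count ~ Poisson(genetic length in Morgan),
    breakpoint positions i.i.d. uniform, no interference; the starting
    haplotype is chosen by a fair coin.
    """
    lmap = _as_locus_map(genome)
    gamete = np.empty(lmap.n_loci, dtype=np.uint8)
    for c in np.unique(lmap.chrom):
        sel = lmap.chrom == c
        pos = lmap.positions[sel]
        k = rng.poisson(lmap.chrom_length)
        breaks = np.sort(rng.uniform(0.0, lmap.chrom_length, size=k))
        start = rng.integers(2)
        which = (start + np.searchsorted(breaks, pos)) % 2
        gamete[sel] = parent_haplotypes[sel, which]
    return gamete
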