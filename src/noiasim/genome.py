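"""Genome layout: chromosomes, locus positions, and recombination maps.

The simulated genome is a set of chromosomes of fixed genetic length
(in Morgan), each carrying a number of bi-allelic loci at random genetic
positions.  Genetic positions are all that matters here: recombination is
modelled directly on the genetic map and there is no nucleotide sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConfigurationError(ValueError):
    """Invalid simulation configuration (non-positive counts, bad bounds ...)."""


@dataclass(frozen=True)
class LocusMap:
    """Minimal locus layout used by the recombination machinery.

    A :class:`GenomeMap` restricted to a subset of loci (e.g. the QTL panel)
    is represented as a ``LocusMap``: chromosome assignment and genetic
    position per locus, plus the common chromosome length.
    """

    chrom: np.ndarray       # (L,) int, chromosome index per locus
    positions: np.ndarray   # (L,) float, genetic position in Morgan
    chrom_length: float

    @property
    def n_loci(self) -> int:
        return self.positions.size

    def subset(self, indices: np.ndarray) -> "LocusMap":
        idx = np.asarray(indices)
        return LocusMap(self.chrom[idx], self.positions[idx], self.chrom_length)


@dataclass(frozen=True)
class GenomeMap:
    """Complete genome layout: ``n_chromosomes`` of equal genetic length,
    each with exactly ``loci_per_chrom`` loci sorted by position."""

    n_chromosomes: int
    chrom_length: float
    loci_per_chrom: int
    positions: np.ndarray   # (n_chromosomes * loci_per_chrom,) sorted within chrom

    def __post_init__(self) -> None:
        if self.positions.size != self.n_chromosomes * self.loci_per_chrom:
            raise ConfigurationError(
                f"expected {self.n_chromosomes * self.loci_per_chrom} positions, "
                f"got {self.positions.size}"
            )
        if np.any(self.positions < 0) or np.any(self.positions > self.chrom_length):
            raise ConfigurationError("locus positions must lie within [0, chrom_length]")

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def chrom(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chromosomes), self.loci_per_chrom)

    @property
    def locus_map(self) -> LocusMap:
        return LocusMap(self.chrom, self.positions, self.chrom_length)

    def subset(self, indices: np.ndarray) -> LocusMap:
        """Locus map restricted to ``indices`` (e.g. the selected QTL)."""
        return self.locus_map.subset(indices)


def build_genome(
    n_chrom: int,
    length_morgan: float,
    loci_per_chrom: int,
    rng_seed: int | np.random.Generator = 0,
) -> GenomeMap:
    """Build a genome with uniformly random locus positions.

    Parameters
    ----------
    n_chrom
        Number of chromosomes.
    length_morgan
        Genetic length of every chromosome, in Morgan.
    loci_per_chrom
        Number of bi-allelic loci per chromosome; positions are drawn
        i.i.d. uniform on ``[0, length_morgan]`` and sorted within each
        chromosome.
    rng_seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    if n_chrom <= 0 or loci_per_chrom <= 0 or length_morgan <= 0:
        raise ConfigurationError(
            "n_chrom, length_morgan and loci_per_chrom must all be positive"
        )
    rng = np.random.default_rng(rng_seed)
    pos = rng.uniform(0.0, length_morgan, size=(n_chrom, loci_per_chrom))
    pos.sort(axis=1)
    return GenomeMap(n_chrom, float(length_morgan), loci_per_chrom, pos.ravel())
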