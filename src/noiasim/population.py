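"""Diploid population container.

Genotypes are stored as phased binary haplotypes: ``haplotypes[i, k, c]`` is
1 when haplotype copy ``c`` of individual ``i`` carries the counted allele at
locus ``k``.  Genotype classes are ordered ``(XX, Xx, xx)`` throughout the
package, where ``XX`` carries two copies of the counted allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

MALE, FEMALE = 1, 0


@dataclass
class Population:
    """Treated as immutable after construction: genotype summaries
    (``allele_counts`` and friends) are computed once and cached."""

    haplotypes: np.ndarray          # (n, L, 2) uint8 in {0, 1}
    sex: np.ndarray                 # (n,) uint8, 1 = male, 0 = female
    generation: int = 0

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise ValueError("haplotypes must have shape (n, n_loci, 2)")
        if self.sex.shape[0] != self.haplotypes.shape[0]:
            raise ValueError("sex must have one entry per individual")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    @cached_property
    def allele_counts(self) -> np.ndarray:
        """Counted-allele dosage per (individual, locus), values in {0, 1, 2}."""
        return self.haplotypes.sum(axis=2, dtype=np.int8)

    @cached_property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per locus."""
        return self.haplotypes.mean(axis=(0, 2))

    @cached_property
    def genotype_freq(self) -> np.ndarray:
        """Observed genotype frequencies per locus, shape (L, 3), order (XX, Xx, xx)."""
        counts = self.allele_counts
        n = self.n_individuals
        f_xx = (counts == 2).sum(axis=0) / n
        f_het = (counts == 1).sum(axis=0) / n
        return np.stack([f_xx, f_het, 1.0 - f_xx - f_het], axis=1)

    def segregating(self) -> np.ndarray:
        """Boolean mask of loci with 0 < allele frequency < 1."""
        p = self.allele_freq
        return (p > 0.0) & (p < 1.0)

    def subset_individuals(self, indices: np.ndarray) -> "Population":
        idx = np.asarray(indices)
        return Population(self.haplotypes[idx], self.sex[idx], self.generation)

    def subset_loci(self, indices: np.ndarray) -> "Population":
        idx = np.asarray(indices)
        return Population(self.haplotypes[:, idx, :], self.sex, self.generation)
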