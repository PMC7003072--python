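"""Population divergence: founder split and per-generation advance.

Two populations of 100 sires and 500 dams each descend from disjoint halves
of the founder generation and are advanced for 50 non-overlapping
generations.  Each generation, 100 sires and 500 dams are chosen — either
uniformly at random (drift) or by truncation on own phenotype (mass
selection) — each sire is assigned exactly 5 dams, and every mating leaves
5 offspring, giving 2500 offspring (exactly 1250 of each sex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .meiosis import gamete_batch, make_gamete  # noqa: F401  (re-export)
from .population import FEMALE, MALE, Population

RANDOM, MASS = "random", "mass"


@dataclass(frozen=True)
class MatingPlan:
    """Sires, dams and their pairing for one generation.

    ``dam_sire[j]`` is the individual index of the sire mated to dam
    ``dams[j]``; each sire is assigned exactly ``len(dams) / len(sires)``
    dams.
    """

    sires: np.ndarray            # (n_sires,) individual indices
    dams: np.ndarray             # (n_dams,)
    dam_sire: np.ndarray         # (n_dams,) sire individual index per dam
    offspring_per_mating: int = 5

    def __post_init__(self) -> None:
        if self.dams.size % self.sires.size != 0:
            raise ValueError("number of dams must be a multiple of number of sires")
        counts = np.unique(self.dam_sire, return_counts=True)[1]
        per = self.dams.size // self.sires.size
        if counts.size != self.sires.size or np.any(counts != per):
            raise ValueError(f"each sire must be assigned exactly {per} dams")

    @property
    def n_offspring(self) -> int:
        return self.dams.size * self.offspring_per_mating


def split_founders(
    pop: Population, rng_seed: int | np.random.Generator = 0,
    n_males: int = 100, n_females: int = 500,
) -> tuple[Population, Population]:
    """Split the founder generation into two disjoint populations of
    ``n_males`` males and ``n_females`` females each."""
    rng = np.random.default_rng(rng_seed)
    males, females = pop.males, pop.females
    if males.size < 2 * n_males or females.size < 2 * n_females:
        raise ValueError(
            f"need at least {2 * n_males} males and {2 * n_females} females, "
            f"have {males.size} and {females.size}"
        )
    pm = rng.permutation(males)
    pf = rng.permutation(females)
    idx1 = np.concatenate([pm[:n_males], pf[:n_females]])
    idx2 = np.concatenate([pm[n_males:2 * n_males], pf[n_females:2 * n_females]])
    return pop.subset_individuals(idx1), pop.subset_individuals(idx2)


def _truncate(candidates: np.ndarray, phenotypes: np.ndarray, k: int) -> np.ndarray:
    """Top-k candidates by phenotype; ties broken by ascending individual
    index (stable, reproducible)."""
    order = np.lexsort((candidates, -phenotypes[candidates]))
    return candidates[order[:k]]


def select_parents(
    pop: Population,
    mode: str,
    phenotypes: np.ndarray | None = None,
    rng_seed: int | np.random.Generator = 0,
    n_sires: int = 100,
    n_dams: int = 500,
    offspring_per_mating: int = 5,
) -> MatingPlan:
    """Choose parents and pair them.

    ``mode='mass'`` applies within-sex truncation selection on own
    phenotype; ``mode='random'`` draws uniformly without replacement.
    Dams are assigned to sires uniformly at random subject to an exactly
    balanced design (``n_dams / n_sires`` dams per sire).
    """
    rng = np.random.default_rng(rng_seed)
    males, females = pop.males, pop.females
    if males.size < n_sires or females.size < n_dams:
        raise ValueError("not enough candidates of each sex")
    if mode == MASS:
        if phenotypes is None:
            raise ValueError("mass selection requires phenotypes for all candidates")
        sires = _truncate(males, phenotypes, n_sires)
        dams = _truncate(females, phenotypes, n_dams)
    elif mode == RANDOM:
        sires = rng.choice(males, size=n_sires, replace=False)
        dams = rng.choice(females, size=n_dams, replace=False)
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")
    # balanced random dam->sire assignment
    per = n_dams // n_sires
    shuffled = rng.permutation(n_dams)
    dam_sire = np.empty(n_dams, dtype=sires.dtype)
    dam_sire[shuffled] = np.repeat(sires, per)
    return MatingPlan(sires, dams, dam_sire, offspring_per_mating)


def advance_generation(
    pop: Population,
    plan: MatingPlan,
    genome: GenomeMap,
    rng_seed: int | np.random.Generator = 0,
) -> Population:
    """Produce the next non-overlapping generation from a mating plan.

    Every dam leaves ``offspring_per_mating`` offspring with her assigned
    sire; each offspring combines one maternal and one paternal recombinant
    gamete.  Offspring sexes are an exact half/half permutation.
    """
    rng = np.random.default_rng(rng_seed)
    k = plan.offspring_per_mating
    mothers = np.repeat(plan.dams, k)
    fathers = np.repeat(plan.dam_sire, k)
    mat = gamete_batch(pop.haplotypes, mothers, genome, rng)
    pat = gamete_batch(pop.haplotypes, fathers, genome, rng)
    hap = np.stack([mat, pat], axis=2)
    n_off = mothers.size
    half = n_off // 2
    sex = np.concatenate([
        np.full(n_off - half, MALE, np.uint8), np.full(half, FEMALE, np.uint8)
    ])
    return Population(hap, rng.permutation(sex), pop.generation + 1)
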