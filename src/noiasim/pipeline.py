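"""Scenario orchestration.

A scenario is a (genetic model, magnitude, divergence mode) cell of the
experiment grid.  Each replicate builds a fresh genome and founder
population, splits it into two populations, advances both for
``n_generations`` (population 1 under drift or mass selection, population
2 always under drift), and records rg, the allele-frequency divergence,
variance components and the genetic trend at the measurement generations
(1-5 and every 5th generation thereafter).

Replicate seeding follows the original experimental design: in the drift
mode the genotype trajectory is seeded independently of the trait
scenario, so all drift scenarios of a grid share the same genotype
replicates and differ only in the sampled trait; selection trajectories
depend on the trait and are seeded per scenario.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import divergence as dv
from . import founders as fd
from . import metrics as mt
from . import noia
from .genome import ConfigurationError, build_genome
from .population import Population
from .trait import EffectConfig, sample_architecture

logger = logging.getLogger("noiasim")

DEFAULT_REPLICATES = {"drift": 50, "selection_drift": 20}


def default_schedule(n_generations: int) -> tuple[int, ...]:
    """Measurement generations: 1..5 and every 5th generation after 5."""
    gens = [g for g in range(1, min(5, n_generations) + 1)]
    gens += [g for g in range(10, n_generations + 1, 5)]
    return tuple(gens)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one scenario."""

    model: str
    magnitude: str = "none"
    divergence: str = "drift"               # 'drift' | 'selection_drift'
    n_generations: int = 50
    n_replicates: int | None = None         # default: 50 drift / 20 selection
    founder_mode: str = "fast"              # 'fast' | 'burn_in'
    effect_multiplier: float = 1.0
    n_gamma: int = 5
    master_seed: int = 0
    measurement_generations: tuple[int, ...] | None = None
    # population and genome structure
    n_chromosomes: int = 10
    chrom_length: float = 1.0
    loci_per_chrom: int = 200
    n_qtl: int = 500
    n_founder_males: int = 200
    n_founder_females: int = 1000
    n_sires: int = 100
    n_dams: int = 500
    offspring_per_mating: int = 5
    h2: float = 0.5

    def __post_init__(self) -> None:
        if self.divergence not in ("drift", "selection_drift"):
            raise ConfigurationError(f"unknown divergence mode {self.divergence!r}")
        if self.founder_mode not in ("fast", "burn_in"):
            raise ConfigurationError(f"unknown founder mode {self.founder_mode!r}")
        self.effect_config()                 # validates model/magnitude combo

    def effect_config(self) -> EffectConfig:
        return EffectConfig.from_preset(
            self.model, self.magnitude,
            n_gamma=self.n_gamma if self.model.startswith("E_") else 0,
            effect_multiplier=self.effect_multiplier,
        )

    @property
    def replicates(self) -> int:
        return (self.n_replicates if self.n_replicates is not None
                else DEFAULT_REPLICATES[self.divergence])

    @property
    def schedule(self) -> tuple[int, ...]:
        return (self.measurement_generations
                if self.measurement_generations is not None
                else default_schedule(self.n_generations))

    @property
    def scenario_id(self) -> str:
        sid = f"{self.model}_{self.magnitude}_{self.divergence}"
        if self.effect_multiplier != 1.0:
            sid += f"_x{self.effect_multiplier:g}"
        if self.model.startswith("E_") and self.n_gamma != 5:
            sid += f"_Ng{self.n_gamma}"
        return sid

    def _structure_key(self) -> tuple:
        return (self.divergence, self.n_generations, self.founder_mode,
                self.n_chromosomes, self.chrom_length, self.loci_per_chrom,
                self.n_qtl, self.n_founder_males, self.n_founder_females,
                self.n_sires, self.n_dams, self.offspring_per_mating,
                self.master_seed, self.schedule)


def _seed_seq(master_seed: int, *keys) -> np.random.SeedSequence:
    entropy = [int(master_seed) % (2**31)]
    entropy += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.SeedSequence(entropy)


def _genotype_rngs(cfg: ScenarioConfig, replicate: int) -> list[np.random.Generator]:
    """(genome, founders, qtl, split, trajectory) streams.  Drift streams
    are scenario-blind so scenarios share genotype replicates."""
    if cfg.divergence == "drift":
        seq = _seed_seq(cfg.master_seed, "geno", "drift", replicate)
    else:
        seq = _seed_seq(cfg.master_seed, "geno", "selection_drift",
                        cfg.scenario_id, replicate)
    return [np.random.default_rng(s) for s in seq.spawn(5)]


def _trait_rng(cfg: ScenarioConfig, replicate: int) -> np.random.Generator:
    seq = _seed_seq(cfg.master_seed, "trait", cfg.model, cfg.magnitude,
                    cfg.n_gamma, cfg.effect_multiplier, replicate)
    return np.random.default_rng(seq)


def _make_founders(cfg: ScenarioConfig, rng_genome, rng_found, rng_qtl):
    genome = build_genome(cfg.n_chromosomes, cfg.chrom_length,
                          cfg.loci_per_chrom, rng_genome)
    if cfg.founder_mode == "burn_in":
        demography = fd.DemographyConfig.default()
        pop0 = fd.simulate_burn_in(genome, demography, rng_found)
    else:
        pop0 = fd.sample_founders_fast(genome, cfg.n_founder_males,
                                       cfg.n_founder_females, rng_seed=rng_found)
    qtl = fd.select_qtl(pop0, cfg.n_qtl, rng_qtl)
    return genome.subset(qtl), pop0.subset_loci(qtl)


def run_replicate(cfg: ScenarioConfig, replicate: int) -> pd.DataFrame:
    """Run one replicate of one scenario; returns the per-generation
    records as a DataFrame (one row per measurement generation)."""
    return _simulate_replicate([cfg], replicate)


def _simulate_replicate(scenarios: Sequence[ScenarioConfig],
                        replicate: int) -> pd.DataFrame:
    """Advance one genotype trajectory and measure every scenario on it.

    All scenarios must share their structural parameters; more than one
    scenario is only meaningful in drift mode, where the genotype
    trajectory does not depend on the trait.
    """
    cfg0 = scenarios[0]
    keys = {c._structure_key() for c in scenarios}
    if len(keys) != 1:
        raise ConfigurationError("scenarios in one replicate must share structure")
    if cfg0.divergence == "selection_drift" and len(scenarios) != 1:
        raise ConfigurationError("selection trajectories are scenario-specific")

    t0 = time.perf_counter()
    rng_genome, rng_found, rng_qtl, rng_split, rng_traj = \
        _genotype_rngs(cfg0, replicate)
    qtl_map, founders0 = _make_founders(cfg0, rng_genome, rng_found, rng_qtl)
    pop1, pop2 = dv.split_founders(founders0, rng_split,
                                   cfg0.n_sires, cfg0.n_dams)

    archs = {
        c.scenario_id: sample_architecture(c.effect_config(), c.n_qtl,
                                           _trait_rng(c, replicate))
        for c in scenarios
    }
    selecting = cfg0.divergence == "selection_drift"
    sel_arch = archs[cfg0.scenario_id] if selecting else None
    baselines: dict[str, tuple[float, float]] = {}

    def plan(pop: Population, mass: bool) -> dv.MatingPlan:
        if mass:
            # sigma_e is refreshed from the candidates' genotypic variance,
            # holding broad-sense heritability at h2 every generation
            g = noia.functional_genotypic_values(pop, sel_arch)
            y = noia.phenotypes(g, rng_traj, h2=cfg0.h2)
            return dv.select_parents(pop, dv.MASS, y, rng_traj,
                                     cfg0.n_sires, cfg0.n_dams,
                                     cfg0.offspring_per_mating)
        return dv.select_parents(pop, dv.RANDOM, None, rng_traj,
                                 cfg0.n_sires, cfg0.n_dams,
                                 cfg0.offspring_per_mating)

    rows: list[dict] = []
    schedule = set(cfg0.schedule)
    for gen in range(1, cfg0.n_generations + 1):
        # founders (gen 0) are exactly the parents needed, so the first
        # advance involves no selection in either population
        mass1 = selecting and gen > 1
        pop1 = dv.advance_generation(pop1, plan(pop1, mass1), qtl_map, rng_traj)
        pop2 = dv.advance_generation(pop2, plan(pop2, False), qtl_map, rng_traj)

        if gen == 1:
            for sid, arch in archs.items():
                g1 = noia.functional_genotypic_values(pop1, arch)
                baselines[sid] = (float(np.mean(g1)), float(np.std(g1)))

        if gen in schedule:
            gf1, gf2 = pop1.genotype_freq, pop2.genotype_freq
            p1, p2 = pop1.allele_freq, pop2.allele_freq
            dpbar = mt.allele_freq_divergence(p1, p2)
            for c in scenarios:
                arch = archs[c.scenario_id]
                eff1 = noia.average_effects(arch, gf1)
                eff2 = noia.average_effects(arch, gf2)
                rg = mt.genetic_correlation(pop1, eff1, eff2)
                vc = mt.variance_components(pop1, arch, eff1)
                fr = vc.fractions
                g = noia.functional_genotypic_values(pop1, arch)
                mean1, sd1 = baselines[c.scenario_id]
                rows.append({
                    "scenario": c.scenario_id, "replicate": replicate,
                    "generation": gen, "rg": rg, "dpbar": dpbar,
                    "va_frac": fr[0], "vd_frac": fr[1], "vi_frac": fr[2],
                    "va": vc.va,
                    "gmean_sd": mt.mean_genotypic_sd(g, mean1, sd1),
                })
    logger.info("replicate %d (%s) done in %.1fs", replicate,
                ",".join(archs), time.perf_counter() - t0)
    return pd.DataFrame(rows, columns=list(mt.RESULT_COLUMNS))


def run_grid(
    cfgs: Sequence[ScenarioConfig], parallel_workers: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a grid of scenarios over their replicates.

    Drift scenarios with identical structure are grouped so each genotype
    replicate is simulated once and measured under every trait scenario.
    Returns the per-replicate records and a replicate-mean summary per
    (scenario, generation).  Failures are logged per task and the rest of
    the grid continues.
    """
    tasks: list[tuple[Sequence[ScenarioConfig], int]] = []
    drift_groups: dict[tuple, list[ScenarioConfig]] = {}
    for c in cfgs:
        if c.divergence == "drift":
            drift_groups.setdefault(c._structure_key(), []).append(c)
        else:
            tasks += [([c], r) for r in range(c.replicates)]
    for group in drift_groups.values():
        for r in range(max(c.replicates for c in group)):
            active = [c for c in group if r < c.replicates]
            tasks.append((active, r))

    def run(task):
        scen, rep = task
        try:
            return _simulate_replicate(scen, rep)
        except Exception:
            logger.exception("replicate %d of %s failed", rep,
                             [c.scenario_id for c in scen])
            return None

    if parallel_workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=parallel_workers)(delayed(run)(t) for t in tasks)
    else:
        results = [run(t) for t in tasks]

    frames = [r for r in results if r is not None and not r.empty]
    if not frames:
        raise RuntimeError("every replicate of the grid failed")
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["scenario", "replicate", "generation"],
                                  ignore_index=True)
    summary = summarize(records)
    return records, summary


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Replicate means (and replicate count) per scenario and generation."""
    value_cols = [c for c in records.columns
                  if c not in ("scenario", "replicate", "generation")]
    g = records.groupby(["scenario", "generation"], sort=True)
    summary = g[value_cols].mean()
    summary["n_replicates"] = g["replicate"].nunique()
    return summary.reset_index()


def write_results(records: pd.DataFrame, path: str) -> None:
    """Write a results table as CSV, rounded to 6 decimals for byte-stable
    reruns."""
    records.round(6).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Deterministic test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, **kwargs) -> dict:
    """Deterministic fixture bundles for unit tests and worked examples.

    ``two_locus``: two interacting loci with a = (1, 1) and gamma = 0.5;
    locus 1 sits at frequency ``p1`` in both populations while locus 2
    differs (``p2_pop1`` vs ``p2_pop2``).  Returns the per-population
    average-effect vectors and their difference.

    ``small_pop``: a seeded population of 20 individuals and 10 QTL with a
    matching small epistatic architecture, for round-tripping the full
    metrics path.
    """
    if kind == "two_locus":
        model = kwargs.get("model", "E_AA")
        p1 = kwargs.get("p1", 0.10)
        p2_pop1 = kwargs.get("p2_pop1", 0.5)
        p2_pop2 = kwargs.get("p2_pop2", 0.3)
        a = kwargs.get("a", (1.0, 1.0))
        gamma = kwargs.get("gamma", 0.5)
        al1 = noia.two_locus_average_effects(model, p1, p2_pop1, a, gamma)
        al2 = noia.two_locus_average_effects(model, p1, p2_pop2, a, gamma)
        return {
            "model": model, "a": np.asarray(a, dtype=float), "gamma": gamma,
            "p1": p1, "p2_pop1": p2_pop1, "p2_pop2": p2_pop2,
            "alpha_pop1": np.array(al1), "alpha_pop2": np.array(al2),
            "delta_alpha": np.array(al1) - np.array(al2),
        }
    if kind == "small_pop":
        rng = np.random.default_rng(kwargs.get("seed", 7))
        genome = build_genome(2, 1.0, 5, rng)
        pop = fd.sample_founders_fast(genome, 10, 10,
                                      fd.u_shaped_spectrum(0.1, 0.9), rng)
        cfg = EffectConfig.from_preset("E_AA", "small", n_gamma=2)
        arch = sample_architecture(cfg, 10, rng)
        return {"genome": genome, "population": pop, "architecture": arch}
    raise ConfigurationError(f"unknown fixture kind {kind!r}")
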