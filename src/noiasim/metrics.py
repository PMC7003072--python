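"""Per-generation summaries: rg, allele-frequency divergence, variance
components and genetic trend.

The central quantity is the additive genetic correlation between
populations,

    rg = cor(v_i^P1, v_i^P2) = cor(h_a,i' alpha^P1, h_a,i' alpha^P2),

the Pearson correlation — over the individuals of population 1 — between
their additive genetic values computed with each population's average
effects.  It equals an allele-frequency-weighted correlation of the two
alpha vectors and is 1 whenever the alpha vectors coincide (purely
additive traits, or identical allele frequencies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .noia import StatisticalEffects, genotypic_value_components
from .population import Population
from .trait import TraitArchitecture

#: Columns of the per-replicate results table, in output order.
RESULT_COLUMNS = (
    "scenario", "replicate", "generation", "rg", "dpbar",
    "va_frac", "vd_frac", "vi_frac", "va", "gmean_sd",
)


def genetic_correlation(
    pop1: Population,
    effects_p1: StatisticalEffects,
    effects_p2: StatisticalEffects,
) -> float:
    """rg from the genotypes of population 1.

    Both additive genetic values use population 1's centered allele
    counts; only the average-effect vectors differ.  The mirrored
    variant (weights from population 2, which generally gives a
    different value) is obtained by passing population 2 and swapping
    the effect sets.  Returns NaN with a warning when either value
    vector has zero variance.
    """
    counts = pop1.allele_counts.astype(float)
    h_a = counts - counts.mean(axis=0, keepdims=True)
    v1 = h_a @ effects_p1.alpha
    v2 = h_a @ effects_p2.alpha
    s1, s2 = v1.std(), v2.std()
    if s1 == 0.0 or s2 == 0.0:
        warnings.warn("zero additive variance: rg undefined")
        return float("nan")
    return float(np.mean((v1 - v1.mean()) * (v2 - v2.mean())) / (s1 * s2))


def allele_freq_divergence(p_a: np.ndarray, p_b: np.ndarray,
                           n_qtl: int | None = None) -> float:
    """Mean absolute allele-frequency difference over all QTL, fixed loci
    included in the denominator."""
    p_a, p_b = np.asarray(p_a), np.asarray(p_b)
    if p_a.shape != p_b.shape:
        raise ValueError("frequency vectors must have equal length")
    if n_qtl is None:
        n_qtl = p_a.size
    elif n_qtl != p_a.size:
        raise ValueError(f"expected {n_qtl} frequencies, got {p_a.size}")
    return float(np.abs(p_a - p_b).sum() / n_qtl)


@dataclass(frozen=True)
class VarianceComponents:
    """Variances over individuals of the additive, dominance and (summed)
    epistatic components of genotypic value."""

    va: float
    vd: float
    vi: float

    @property
    def total(self) -> float:
        return self.va + self.vd + self.vi

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(V_A, V_D, V_I) each divided by their sum; NaN when the total
        genetic variance is zero."""
        tot = self.total
        if tot == 0.0:
            warnings.warn("zero total genetic variance: fractions undefined")
            return (float("nan"),) * 3
        return (self.va / tot, self.vd / tot, self.vi / tot)


def variance_components(
    pop: Population, arch: TraitArchitecture, effects: StatisticalEffects
) -> VarianceComponents:
    """NOIA variance components in ``pop`` (effects must have been computed
    at this population's frequencies).  Between-component covariances are
    ignored: the components are orthogonal under the NOIA weighting, and
    the residual covariance from realized LD is dropped so the fractions
    sum to one."""
    g_add, g_dom, g_epi = genotypic_value_components(pop, arch, effects)
    return VarianceComponents(float(np.var(g_add)), float(np.var(g_dom)),
                              float(np.var(g_epi)))


def mean_genotypic_sd(g_current: np.ndarray, baseline_mean: float,
                      baseline_sd: float) -> float:
    """Mean genotypic value expressed in baseline genetic SD units:
    ``(mean(g) - baseline_mean) / baseline_sd``, where the baseline is the
    replicate's generation-1 genotypic mean and SD."""
    if baseline_sd <= 0.0:
        warnings.warn("non-positive baseline genetic SD")
        return float("nan")
    return float((np.mean(g_current) - baseline_mean) / baseline_sd)


def additive_variance_loss(records: pd.DataFrame, last_generation: int = 50) -> float:
    """Replicate-averaged fraction of additive genetic variance lost between
    generation 1 and ``last_generation``: mean over replicates of
    ``1 - V_A(last) / V_A(1)``.

    ``records`` is a per-replicate results table with columns
    ``replicate``, ``generation`` and ``va`` (absolute additive variance).
    """
    losses = []
    for _, grp in records.groupby("replicate"):
        va1 = grp.loc[grp["generation"] == 1, "va"]
        vaT = grp.loc[grp["generation"] == last_generation, "va"]
        if va1.empty or vaT.empty:
            continue
        v1 = float(va1.iloc[0])
        if v1 == 0.0:
            warnings.warn("zero generation-1 additive variance: loss undefined")
            continue
        losses.append(1.0 - float(vaT.iloc[0]) / v1)
    if not losses:
        raise ValueError("records contain no usable (generation 1, last) pairs")
    return float(np.mean(losses))
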