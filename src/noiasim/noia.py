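"""NOIA: natural and orthogonal partition of genetic effects.

The NOIA (natural and orthogonal interactions) parameterization expresses
genotypic values in a basis that is statistically orthogonal under the
population's own genotype frequencies.  Per locus, genotypes (XX, Xx, xx)
are scored by three contrasts — the mean (1), the additive contrast
``w_a`` and the dominance contrast ``w_d``:

    w_a(g) = allele count(g) - mean allele count,
    w_d    = (-2 p_Xx p_xx,  4 p_XX p_xx,  -2 p_XX p_Xx) / D,
    D      = p_XX + p_xx - (p_XX - p_xx)^2,

which satisfy ``sum_g p_g w_a(g) = 0``, ``sum_g p_g w_d(g) = 0`` and
``sum_g p_g w_a(g) w_d(g) = 0`` for arbitrary genotype frequencies.

Functional (frequency-independent) per-locus values ``(a, d, -a)`` and
two-locus epistatic tables ``epsilon * t`` are projected onto this basis
by weighted least squares; with all genotype classes populated the
projection is an exact reparameterization.  The resulting statistical
effects — the average (allele-substitution) effect ``alpha`` per QTL, the
statistical dominance effect ``d*``, and the four two-locus interaction
effects — are population-specific because the basis is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .population import Population
from .trait import TraitArchitecture

#: Allele-frequency clamp used when building codings for (near-)fixed loci.
FREQ_CLAMP = 0.005

_COUNTS = np.array([2.0, 1.0, 0.0])          # allele counts for (XX, Xx, xx)


@dataclass(frozen=True)
class NoiaCoding:
    """Per-locus NOIA design: columns (1, w_a, w_d) for rows (XX, Xx, xx)."""

    W: np.ndarray                             # (3, 3)
    genotype_freq: np.ndarray                 # (3,) frequencies used

    @property
    def w_a(self) -> np.ndarray:
        return self.W[:, 1]

    @property
    def w_d(self) -> np.ndarray:
        return self.W[:, 2]


@dataclass(frozen=True)
class PairPartition:
    """Statistical effects of one epistatic pair, ordered
    ``[mu, alpha_k, d_k, alpha_l, (aa), (da), d_l, (ad), (dd)]``."""

    b: np.ndarray                             # (9,)
    pair: tuple[int, int] | None = None


def _clamp_genotype_freq(gf: np.ndarray) -> np.ndarray:
    """Replace degenerate genotype-frequency vectors by Hardy-Weinberg
    proportions at a clamped allele frequency.

    A locus is degenerate when its allele frequency falls outside
    ``[FREQ_CLAMP, 1 - FREQ_CLAMP]``, when the dominance-contrast
    denominator vanishes (e.g. a fixed or an all-heterozygote locus), or
    when a genotype class is (essentially) absent — an empty class puts
    one NOIA contrast in the null space of the frequency weighting and
    the partition would be singular.  Clamping keeps the design
    full-rank; truly fixed loci carry no additive variance, so their
    (arbitrary) effects get zero weight in every variance or correlation
    computed downstream.
    """
    gf = np.atleast_2d(np.asarray(gf, dtype=float))
    p = gf[:, 0] + 0.5 * gf[:, 1]
    den = gf[:, 0] + gf[:, 2] - (gf[:, 0] - gf[:, 2]) ** 2
    bad = (
        (p < FREQ_CLAMP) | (p > 1.0 - FREQ_CLAMP) | (den < 1e-8)
        | (gf.min(axis=1) < 1e-6)
    )
    if np.any(bad):
        pc = np.clip(p[bad], FREQ_CLAMP, 1.0 - FREQ_CLAMP)
        gf = gf.copy()
        gf[bad] = np.stack([pc**2, 2 * pc * (1 - pc), (1 - pc) ** 2], axis=1)
    return gf


def _codings(gf: np.ndarray) -> np.ndarray:
    """Batch NOIA designs, shape (L, 3, 3), from clamped genotype freqs."""
    gf = _clamp_genotype_freq(gf)
    L = gf.shape[0]
    mean_count = 2 * gf[:, 0] + gf[:, 1]
    W = np.empty((L, 3, 3))
    W[:, :, 0] = 1.0
    W[:, :, 1] = _COUNTS[None, :] - mean_count[:, None]
    den = gf[:, 0] + gf[:, 2] - (gf[:, 0] - gf[:, 2]) ** 2
    W[:, 0, 2] = -2.0 * gf[:, 1] * gf[:, 2] / den
    W[:, 1, 2] = 4.0 * gf[:, 0] * gf[:, 2] / den
    W[:, 2, 2] = -2.0 * gf[:, 0] * gf[:, 1] / den
    return W


def noia_coding(genotype_freq) -> NoiaCoding:
    """NOIA design for a single locus from its (XX, Xx, xx) frequencies.

    Degenerate loci (fixed, or with a vanishing dominance denominator) are
    handled by clamping, never by raising.
    """
    gf = np.asarray(genotype_freq, dtype=float)
    if gf.shape != (3,):
        raise ValueError("genotype_freq must be a length-3 vector (XX, Xx, xx)")
    if np.any(gf < 0) or abs(gf.sum() - 1.0) > 1e-8:
        raise ValueError("genotype frequencies must be non-negative and sum to 1")
    gfc = _clamp_genotype_freq(gf)[0]
    return NoiaCoding(_codings(gfc[None, :])[0], gfc)


def _pair_design(Wk: np.ndarray, Wl: np.ndarray) -> np.ndarray:
    """Two-locus design with rows ordered genotype-of-k fastest and columns
    matching the ``b`` ordering; equals ``kron(W_l, W_k)``."""
    return np.kron(Wl, Wk)


def partition_pair(
    t: np.ndarray,
    epsilon: float,
    coding_k: NoiaCoding,
    coding_l: NoiaCoding,
    freq9: np.ndarray,
) -> PairPartition:
    """Project one pair's functional epistatic values onto the NOIA basis.

    Solves the weighted least-squares problem
    ``b = (W' D W)^{-1} W' D c`` with ``c = t * epsilon`` and ``D`` the
    diagonal of the 9 two-locus genotype frequencies.  With all classes
    populated the 9x9 system is full rank and the fit reconstructs ``c``
    exactly.
    """
    c = np.asarray(t, dtype=float) * float(epsilon)
    f9 = np.asarray(freq9, dtype=float)
    if f9.shape != (9,) or np.any(f9 < 0):
        raise ValueError("freq9 must be 9 non-negative frequencies")
    W9 = _pair_design(coding_k.W, coding_l.W)
    WD = W9 * f9[:, None]
    try:
        b = np.linalg.solve(WD.T @ W9, WD.T @ c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular NOIA normal matrix for pair (k, l) with freq9={f9}"
        ) from err
    return PairPartition(b)


@dataclass
class StatisticalEffects:
    """Population-specific statistical effects of a trait architecture.

    ``alpha`` and ``d_star`` are the average (substitution) and statistical
    dominance effects per QTL under this population's genotype
    frequencies, including all contributions from epistatic partners.
    ``pair_b`` stores the full 9-effect partition of every pair.
    """

    alpha: np.ndarray                 # (L,)
    d_star: np.ndarray                # (L,)
    W: np.ndarray                     # (L, 3, 3) per-locus designs
    pairs: np.ndarray                 # (P, 2)
    pair_b: np.ndarray                # (P, 9)
    genotype_freq: np.ndarray         # (L, 3) clamped frequencies used

    @property
    def allele_freq(self) -> np.ndarray:
        return self.genotype_freq[:, 0] + 0.5 * self.genotype_freq[:, 1]

    @property
    def w_a(self) -> np.ndarray:
        return self.W[:, :, 1]

    @property
    def w_d(self) -> np.ndarray:
        return self.W[:, :, 2]

    def to_frame(self, population: str = "", generation: int = 0):
        """Per-QTL statistical effects as a table (TSV-ready)."""
        import pandas as pd

        return pd.DataFrame({
            "qtl_id": np.arange(self.alpha.size),
            "population": population,
            "generation": generation,
            "alpha": self.alpha,
            "d_star": self.d_star,
        })


def average_effects(arch: TraitArchitecture, pop_freqs: np.ndarray) -> StatisticalEffects:
    """Statistical effects of ``arch`` under genotype frequencies ``pop_freqs``.

    Per locus, the functional values ``(a, d, -a)`` are partitioned exactly
    into mean, average effect and dominance effect (under Hardy-Weinberg
    proportions this reduces to the familiar ``alpha = a + (1 - 2p) d``).
    Per epistatic pair, the 9-cell table ``epsilon * t`` is partitioned
    under the product of the two loci's marginal genotype frequencies
    (linkage equilibrium weighting), and the pair's ``alpha_k``/``alpha_l``
    and ``d_k``/``d_l`` terms are accumulated onto the member loci.
    """
    gf = _clamp_genotype_freq(np.asarray(pop_freqs, dtype=float))
    L = arch.n_qtl
    if gf.shape != (L, 3):
        raise ValueError(f"pop_freqs must have shape ({L}, 3)")
    W = _codings(gf)

    # single-locus partition of (a, d, -a), batched 3x3 solves
    c_loc = np.stack([arch.a, arch.d, -arch.a], axis=1)       # (L, 3)
    WD = W * gf[:, :, None]
    M = np.einsum("lri,lrj->lij", WD, W)
    rhs = np.einsum("lri,lr->li", WD, c_loc)
    b_loc = np.linalg.solve(M, rhs[..., None])[..., 0]
    alpha = b_loc[:, 1].copy()
    d_star = b_loc[:, 2].copy()

    if arch.n_pairs:
        k, l = arch.pairs[:, 0], arch.pairs[:, 1]
        Wk, Wl = W[k], W[l]                                    # (P, 3, 3)
        # W9[p, 3*gl+gk, 3*il+ik] = Wk[gk, ik] * Wl[gl, il]
        P = k.size
        W9 = (Wl[:, :, None, :, None] * Wk[:, None, :, None, :]).reshape(P, 9, 9)
        f9 = (gf[l][:, :, None] * gf[k][:, None, :]).reshape(P, 9)
        c9 = arch.epsilon[:, None] * arch.contrast[None, :]
        WD9 = W9 * f9[:, :, None]
        M9 = np.einsum("pri,prj->pij", WD9, W9)
        rhs9 = np.einsum("pri,pr->pi", WD9, c9)
        b = np.linalg.solve(M9, rhs9[..., None])[..., 0]
        np.add.at(alpha, k, b[:, 1])
        np.add.at(alpha, l, b[:, 3])
        np.add.at(d_star, k, b[:, 2])
        np.add.at(d_star, l, b[:, 6])
    else:
        b = np.empty((0, 9))

    return StatisticalEffects(alpha, d_star, W, arch.pairs, b, gf)


# ---------------------------------------------------------------------------
# Genetic values
# ---------------------------------------------------------------------------

def _indicators(pop: Population, effects: StatisticalEffects) -> tuple[np.ndarray, np.ndarray]:
    """NOIA additive and dominance indicators h_a, h_d per individual/locus."""
    gidx = (2 - pop.allele_counts).astype(np.intp)            # 0=XX, 1=Xx, 2=xx
    cols = np.arange(pop.n_loci)[None, :]
    h_a = effects.w_a[cols, gidx]
    h_d = effects.w_d[cols, gidx]
    return h_a, h_d


def breeding_values(pop: Population, effects: StatisticalEffects) -> np.ndarray:
    """Additive genetic values ``v = h_a' alpha`` with allele counts centered
    by the genotyped population's own means (so ``mean(v) = 0`` there)."""
    counts = pop.allele_counts.astype(float)
    h_a = counts - counts.mean(axis=0, keepdims=True)
    return h_a @ effects.alpha


def genotypic_value_components(
    pop: Population, arch: TraitArchitecture, effects: StatisticalEffects
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(additive, dominance, epistatic) components of genotypic value per
    individual, in the NOIA basis of ``effects``."""
    h_a, h_d = _indicators(pop, effects)
    g_add = h_a @ effects.alpha
    g_dom = h_d @ effects.d_star
    if arch.n_pairs:
        k, l = arch.pairs[:, 0], arch.pairs[:, 1]
        b = effects.pair_b
        ha_k, ha_l = np.take(h_a, k, axis=1), np.take(h_a, l, axis=1)
        hd_k, hd_l = np.take(h_d, k, axis=1), np.take(h_d, l, axis=1)
        g_epi = (
            (ha_k * ha_l) @ b[:, 4]        # (alpha alpha)
            + (hd_k * ha_l) @ b[:, 5]      # (d alpha)
            + (ha_k * hd_l) @ b[:, 7]      # (alpha d)
            + (hd_k * hd_l) @ b[:, 8]      # (d d)
        )
    else:
        g_epi = np.zeros(pop.n_individuals)
    return g_add, g_dom, g_epi


def genotypic_values(
    pop: Population, arch: TraitArchitecture, effects: StatisticalEffects
) -> np.ndarray:
    """Genotypic values in the NOIA basis (mean terms omitted: equal to the
    functional genotypic values up to an additive constant)."""
    g_add, g_dom, g_epi = genotypic_value_components(pop, arch, effects)
    return g_add + g_dom + g_epi


def functional_genotypic_values(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """Frequency-independent genotypic values straight from the functional
    effects: per-locus values (a, d, -a) for (XX, Xx, xx) plus, per
    epistatic pair, the cell of ``epsilon * t`` selected by the two-locus
    genotype.  Used for phenotypes/selection and as the reconstruction
    oracle for the NOIA route."""
    counts = pop.allele_counts
    g = (counts - 1.0) @ arch.a + (counts == 1) @ arch.d
    if arch.n_pairs:
        gidx = (2 - counts).astype(np.int8)                   # genotype index
        cell = (3 * np.take(gidx, arch.pairs[:, 1], axis=1)
                + np.take(gidx, arch.pairs[:, 0], axis=1))
        g = g + np.take(arch.contrast, cell) @ arch.epsilon
    return g


def phenotypes(
    g: np.ndarray,
    rng_seed: int | np.random.Generator = 0,
    h2: float = 0.5,
    sigma_e: float | None = None,
) -> np.ndarray:
    """Phenotypes ``y = g + e`` with ``e ~ N(0, sigma_e^2)``.

    When ``sigma_e`` is not given it is derived from the variance of ``g``
    and the broad-sense heritability: ``sigma_e^2 = var(g) (1 - h2) / h2``
    (equal variances at the default ``h2 = 0.5``).  Callers that want a
    constant environmental variance across generations compute it once and
    pass it in.
    """
    rng = np.random.default_rng(rng_seed)
    if sigma_e is None:
        var_g = float(np.var(g))
        if var_g == 0.0:
            warnings.warn("zero genotypic variance: phenotypes equal genotypic values")
            sigma_e = 0.0
        else:
            sigma_e = float(np.sqrt(var_g * (1.0 - h2) / h2))
    return g + rng.normal(0.0, sigma_e, size=g.shape)


# ---------------------------------------------------------------------------
# Two-locus worked example
# ---------------------------------------------------------------------------

def two_locus_average_effects(
    model: str,
    p_k: float,
    p_l: float,
    a: tuple[float, float] = (1.0, 1.0),
    gamma: float = 0.5,
    d: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float]:
    """Average effects (alpha_k, alpha_l) of two interacting loci at
    Hardy-Weinberg frequencies ``p_k``, ``p_l``.

    The illustration behind the configuration mechanisms: additive-by-
    additive and multiplicative interactions make a locus's alpha depend
    only on the partner's allele frequency, while dominance-by-dominance
    and complementary interactions make it depend on the locus's own
    frequency as well.
    """
    from .trait import build_contrast

    def hwe(p: float) -> np.ndarray:
        return np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])

    gf = np.stack([hwe(p_k), hwe(p_l)])
    eps = gamma * abs(a[0] * a[1])
    ck = noia_coding(gf[0])
    cl = noia_coding(gf[1])
    f9 = (gf[1][:, None] * gf[0][None, :]).ravel()
    b = partition_pair(build_contrast(model), eps, ck, cl, f9).b

    alphas = []
    for i, (p, cod) in enumerate(((p_k, ck), (p_l, cl))):
        c_loc = np.array([a[i], d[i], -a[i]])
        gfi = cod.genotype_freq
        WD = cod.W * gfi[:, None]
        b_loc = np.linalg.solve(WD.T @ cod.W, WD.T @ c_loc)
        alphas.append(b_loc[1])
    return float(alphas[0] + b[1]), float(alphas[1] + b[3])
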