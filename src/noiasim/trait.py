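"""Functional (biological) trait architectures.

Functional effects are frequency-independent parameters of the
genotype-to-phenotype map:

* additive effects ``a ~ N(0, 1)`` per QTL,
* dominance effects ``d = delta * |a|`` with dominance coefficients
  ``delta ~ N(mu_delta, sigma_delta^2)``,
* pairwise epistatic effects ``epsilon_kl = gamma_kl * |a_k a_l|`` with
  ``gamma ~ N(mu_gamma, sigma_gamma^2)``, on a random ``n_gamma``-regular
  interaction graph over the QTL.

Epistatic interactions follow one of four two-locus configurations —
additive-by-additive (E_AA), dominance-by-dominance (E_DD), complementary
(E_C) or multiplicative (E_M) — encoded as a 9-cell contrast vector ``t``
that is centered and scaled to unit standard deviation over the 9
two-locus genotype classes.

The named magnitude presets (small / intermediate / large) fix the
dominance-coefficient distribution; for epistatic models ``sigma_gamma``
is derived from the matching dominance preset so that the expected total
functional epistatic variance equals the dominance analogue:
``n_gamma * (mu_gamma^2 + sigma_gamma^2) = mu_delta^2 + sigma_delta^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genome import ConfigurationError

MODELS = ("A", "D", "E_AA", "E_DD", "E_C", "E_M")
EPISTATIC_MODELS = ("E_AA", "E_DD", "E_C", "E_M")
MAGNITUDES = ("none", "small", "intermediate", "large")

#: (mu_delta, sigma_delta) per magnitude preset.
DELTA_PRESETS = {
    "small": (0.2, 0.3),
    "intermediate": (0.2, 0.7),
    "large": (0.2, 1.5),
}

DEFAULT_N_GAMMA = 5


def sigma_gamma(mu_delta: float, sigma_delta: float, n_gamma: int) -> float:
    """Epistatic-coefficient SD matching total functional dominance variance:
    ``sqrt((mu_delta^2 + sigma_delta^2) / n_gamma)``."""
    if n_gamma <= 0:
        raise ConfigurationError("n_gamma must be positive")
    return math.sqrt((mu_delta**2 + sigma_delta**2) / n_gamma)


def overdominance_fraction(mu_delta: float, sigma_delta: float) -> float:
    """Probability that ``|delta| > 1``, i.e. the heterozygote lies outside
    both homozygotes (closed form from the normal CDF)."""
    if sigma_delta == 0:
        return float(abs(mu_delta) > 1)
    lo = stats.norm.cdf(-1.0, loc=mu_delta, scale=sigma_delta)
    hi = stats.norm.sf(1.0, loc=mu_delta, scale=sigma_delta)
    return float(lo + hi)


@dataclass(frozen=True)
class EffectConfig:
    """Scenario-level description of the trait architecture."""

    model: str
    magnitude: str = "none"
    mu_delta: float = 0.0
    sigma_delta: float = 0.0
    mu_gamma: float = 0.0
    sigma_gamma: float = 0.0
    n_gamma: int = 0
    effect_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.magnitude not in MAGNITUDES:
            raise ConfigurationError(f"unknown magnitude {self.magnitude!r}")
        if (self.model == "A") != (self.magnitude == "none"):
            raise ConfigurationError(
                "model 'A' takes magnitude 'none' and vice versa"
            )
        if self.sigma_delta < 0 or self.sigma_gamma < 0 or self.n_gamma < 0:
            raise ConfigurationError("negative dispersion parameters")
        if self.model == "D" and self.n_gamma:
            raise ConfigurationError("dominance and epistasis are never combined")

    @classmethod
    def from_preset(
        cls,
        model: str,
        magnitude: str = "none",
        n_gamma: int = DEFAULT_N_GAMMA,
        effect_multiplier: float = 1.0,
    ) -> "EffectConfig":
        """Named scenario presets (model x magnitude)."""
        if model == "A":
            if magnitude != "none":
                raise ConfigurationError("model 'A' has no magnitude preset")
            return cls("A", "none", effect_multiplier=effect_multiplier)
        if magnitude not in DELTA_PRESETS:
            raise ConfigurationError(
                f"model {model!r} requires magnitude in {list(DELTA_PRESETS)}"
            )
        mu_d, sd_d = DELTA_PRESETS[magnitude]
        if model == "D":
            return cls("D", magnitude, mu_delta=mu_d, sigma_delta=sd_d,
                       effect_multiplier=effect_multiplier)
        if model in EPISTATIC_MODELS:
            return cls(model, magnitude, mu_gamma=0.0,
                       sigma_gamma=sigma_gamma(mu_d, sd_d, n_gamma),
                       n_gamma=n_gamma, effect_multiplier=effect_multiplier)
        raise ConfigurationError(f"unknown model {model!r}")


@dataclass
class TraitArchitecture:
    """Sampled functional effects for one scenario replicate.

    ``pairs`` holds unordered QTL index pairs (k, l); ``contrast`` is the
    shared, centered and unit-SD 9-cell epistatic contrast vector ordered
    with the genotype of locus k varying fastest:
    (WWYY, WwYY, wwYY, WWYy, ..., wwyy).
    """

    a: np.ndarray
    delta: np.ndarray
    d: np.ndarray
    pairs: np.ndarray                    # (P, 2) int
    gamma: np.ndarray                    # (P,)
    epsilon: np.ndarray                  # (P,)
    contrast: np.ndarray | None          # (9,) or None
    config: EffectConfig

    @property
    def n_qtl(self) -> int:
        return self.a.size

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def effects_frame(self) -> pd.DataFrame:
        """Per-QTL functional effects as a table (TSV-ready)."""
        return pd.DataFrame({
            "qtl_id": np.arange(self.n_qtl),
            "a": self.a, "delta": self.delta, "d": self.d,
        })

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.pairs[:, 0], "l": self.pairs[:, 1],
            "gamma": self.gamma, "epsilon": self.epsilon,
        })


# ---------------------------------------------------------------------------
# Sampling operations
# ---------------------------------------------------------------------------

def sample_additive(n_qtl: int, rng_seed: int | np.random.Generator = 0) -> np.ndarray:
    """i.i.d. standard-normal functional additive effects."""
    if n_qtl <= 0:
        raise ConfigurationError("n_qtl must be positive")
    rng = np.random.default_rng(rng_seed)
    return rng.standard_normal(n_qtl)


def sample_dominance(
    a: np.ndarray, mu_delta: float, sigma_delta: float,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dominance coefficients ``delta ~ N(mu, sigma^2)`` and effects
    ``d = delta * |a|``."""
    if sigma_delta < 0:
        raise ConfigurationError("sigma_delta must be non-negative")
    rng = np.random.default_rng(rng_seed)
    delta = rng.normal(mu_delta, sigma_delta, size=a.size)
    return delta, delta * np.abs(a)


def sample_pairs(
    n_qtl: int, n_gamma: int, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Random ``n_gamma``-regular simple interaction graph on the QTL,
    returned as a (n_qtl * n_gamma / 2, 2) array of index pairs."""
    if n_gamma >= n_qtl:
        raise ConfigurationError("n_gamma must be smaller than n_qtl")
    if (n_qtl * n_gamma) % 2 != 0:
        raise ConfigurationError("n_qtl * n_gamma must be even")
    rng = np.random.default_rng(rng_seed)
    seed = int(rng.integers(2**31 - 1))
    g = nx.random_regular_graph(n_gamma, n_qtl, seed=seed)
    pairs = np.array(sorted(tuple(sorted(e)) for e in g.edges()), dtype=np.int64)
    return pairs


def sample_epistatic(
    pairs: np.ndarray, a: np.ndarray, mu_gamma: float, sigma_gamma: float,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Epistatic coefficients ``gamma ~ N(mu, sigma^2)`` per pair and
    effects ``epsilon_kl = gamma_kl * |a_k * a_l|``."""
    if sigma_gamma < 0:
        raise ConfigurationError("sigma_gamma must be non-negative")
    rng = np.random.default_rng(rng_seed)
    gamma = rng.normal(mu_gamma, sigma_gamma, size=pairs.shape[0])
    eps = gamma * np.abs(a[pairs[:, 0]] * a[pairs[:, 1]])
    return gamma, eps


# Raw two-locus interaction tables, rows = genotype at k (WW, Ww, ww),
# columns = genotype at l (YY, Yy, yy).  These are the canonical textbook
# forms of the four named configurations.
_ADD_SCORE = np.array([1.0, 0.0, -1.0])
_DOM_SCORE = np.array([-1.0, 1.0, -1.0])
_COUNT = np.array([2.0, 1.0, 0.0])

_RAW_TABLES = {
    "E_AA": np.outer(_ADD_SCORE, _ADD_SCORE),
    "E_DD": np.outer(_DOM_SCORE, _DOM_SCORE),
    "E_C": np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 0.0]]),
    "E_M": np.outer(_COUNT, _COUNT),
}


def build_contrast(model: str) -> np.ndarray:
    """9-cell epistatic contrast vector for an epistatic configuration.

    The raw table is flattened with the genotype of locus k varying
    fastest, then centered to mean 0 and scaled to (population) SD 1 over
    the 9 cells.
    """
    if model not in _RAW_TABLES:
        raise ConfigurationError(f"not an epistatic model: {model!r}")
    t = _RAW_TABLES[model].T.ravel()          # index = 3*g_l + g_k
    t = t - t.mean()
    return t / t.std()


def sample_architecture(
    config: EffectConfig, n_qtl: int, rng_seed: int | np.random.Generator = 0
) -> TraitArchitecture:
    """Sample a full trait architecture for one scenario replicate.

    The ``effect_multiplier`` scales dominance and epistatic effects
    (``d`` and ``epsilon``) after sampling, leaving additive effects
    untouched.
    """
    rng = np.random.default_rng(rng_seed)
    a = sample_additive(n_qtl, rng)
    if config.model == "D":
        delta, d = sample_dominance(a, config.mu_delta, config.sigma_delta, rng)
    else:
        delta = np.zeros(n_qtl)
        d = np.zeros(n_qtl)
    if config.model in EPISTATIC_MODELS:
        pairs = sample_pairs(n_qtl, config.n_gamma, rng)
        gamma, eps = sample_epistatic(pairs, a, config.mu_gamma,
                                      config.sigma_gamma, rng)
        contrast = build_contrast(config.model)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
        gamma = np.empty(0)
        eps = np.empty(0)
        contrast = None
    m = config.effect_multiplier
    return TraitArchitecture(a, delta, d * m, pairs, gamma, eps * m,
                             contrast, config)
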