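"""Simulator for independent diallelic sites read at low-to-high sequencing depth.

The generative model, per site:

1. The site is variable in the (ancestral) population with probability
   ``prob_variable``; variable sites receive a derived-allele frequency drawn
   from the expected neutral-diffusion site frequency spectrum, density
   proportional to 1/f on (f_min, 1) — or, as an alternative family, an
   exponential density truncated to (0, 1).  A population-expansion variant
   squares and renormalises the density, skewing it toward rare variants.
2. For structured scenarios, subpopulation frequencies follow the
   Balding–Nichols model: Beta with mean equal to the parent frequency and
   variance F_ST * p * (1 - p), arranged in a 3-population hierarchy (one deep
   split, one shallow split).
3. Diploid genotypes are drawn from HWE proportions, optionally deformed by an
   inbreeding coefficient F.
4. Read depth per individual per site is Poisson; each read reports one of the
   individual's two alleles and is miscalled with a uniform per-read error
   rate.  In the diallelic collapse of a four-base uniform error channel, a
   miscalled read lands on the alternate allele with probability 2/3 (the
   remaining third falls on off-allele bases, which carry no information and
   are dropped); a pure flip channel is available as an option.

Everything is driven by :class:`numpy.random.Generator`; identical configs and
seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "SimulationConfig",
    "StructureConfig",
    "FreqTable",
    "ReadCounts",
    "as_rng",
    "truncated_exponential",
    "neutral_diffusion_freqs",
    "draw_ancestral_freqs",
    "draw_subpop_freqs",
    "draw_genotypes",
    "simulate_reads",
]

ERROR_MODELS = ("four_base_collapsed", "flip_only")
SFS_MODELS = (
    "neutral_diffusion",      # density ∝ 1/f on (f_min, 1)
    "expansion_skewed",       # squared + renormalised: ∝ 1/f^2 on (f_min, 1)
    "neutral_exponential",    # density ∝ exp(-r f) truncated to (0, 1)
    "expansion_exponential",  # squared + renormalised: ∝ exp(-2 r f)
)

#: rate of the truncated-(0,1) exponential SFS family (a free parameter;
#: see docs/methods.md for how the SFS defaults were fixed).
DEFAULT_EXP_RATE = 5.0

#: lower frequency bound of the 1/f spectrum: one copy among 2,000
#: chromosomes, the resolution of the reference 1,000-diploid pool.
DEFAULT_F_MIN = 5e-4

RngLike = Union[None, int, np.random.Generator]


def as_rng(seed: RngLike) -> np.random.Generator:
    """Coerce ``None`` / int / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def flip_rate(error_rate: float, error_model: str = "four_base_collapsed") -> float:
    """Per-read probability of reporting the alternate allele.

    Under the four-base convention an error lands on each of the 3 other
    bases with probability ``error_rate / 3``; only one of those is the
    alternate allele of the diallelic system, hence the factor 2/3 after
    dropping off-allele bases and renormalising nothing (off-allele reads are
    simply discarded).
    """
    if error_model not in ERROR_MODELS:
        raise ValueError(f"unknown error model {error_model!r}; choose from {ERROR_MODELS}")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if error_model == "four_base_collapsed":
        return (2.0 / 3.0) * error_rate
    return error_rate


@dataclass
class SimulationConfig:
    """Parameters of a single-population sequencing simulation.

    Attributes
    ----------
    n_sites : int
        Number of independent diallelic sites.
    n_individuals : int
        Diploid sample size (the full simulated pool).
    prob_variable : float
        Probability that a site is polymorphic in the population.
    sfs_model : str
        ``"neutral_diffusion"`` (default, density ∝ 1/f) or
        ``"neutral_exponential"`` for constant population size;
        ``"expansion_skewed"`` / ``"expansion_exponential"`` square and
        renormalise the respective density.
    exp_rate : float
        Rate of the truncated exponential frequency density on (0, 1)
        (exponential family only).
    f_min : float
        Lower bound of the 1/f spectrum (1/f family only).
    inbreeding_F : float
        Per-individual inbreeding coefficient; 0 is HWE.
    mean_depth : float
        Poisson mean of per-individual per-site read depth.
    error_rate : float
        Per-read base-miscall probability.
    error_model : str
        ``"four_base_collapsed"`` (default) or ``"flip_only"``.
    seed : int or None
        Seed for the top-level generator.
    """

    n_sites: int
    n_individuals: int = 1000
    prob_variable: float = 0.1
    sfs_model: str = "neutral_diffusion"
    exp_rate: float = DEFAULT_EXP_RATE
    f_min: float = DEFAULT_F_MIN
    inbreeding_F: float = 0.0
    mean_depth: float = 1.0
    error_rate: float = 0.01
    error_model: str = "four_base_collapsed"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.prob_variable <= 1.0:
            raise ValueError("prob_variable must be in [0, 1]")
        if self.sfs_model not in SFS_MODELS:
            raise ValueError(f"unknown sfs_model {self.sfs_model!r}")
        if not self.exp_rate > 0:
            raise ValueError("exp_rate must be positive")
        if not 0.0 < self.f_min < 1.0:
            raise ValueError("f_min must be in (0, 1)")
        if not 0.0 <= self.inbreeding_F <= 1.0:
            raise ValueError("inbreeding_F must be in [0, 1]")
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be positive")
        # delegates range checks on error_rate / error_model
        flip_rate(self.error_rate, self.error_model)

    @property
    def flip_rate(self) -> float:
        return flip_rate(self.error_rate, self.error_model)

    def rng(self) -> np.random.Generator:
        return as_rng(self.seed)


@dataclass
class StructureConfig:
    """Three-population hierarchy: one deep split, then a shallow split.

    The first Balding–Nichols draw (at ``fst_deep``) is population 1; the
    second seeds populations 2 and 3 through further draws at ``fst_shallow``.
    ``n_per_pop * depth_per_sample`` is the per-population coverage budget
    held constant across the designs being compared.
    """

    fst_deep: float
    fst_shallow: float
    n_per_pop: int = 40
    depth_per_sample: float = 1.0
    n_pops: int = 3  # the hierarchy below is specific to three populations

    def __post_init__(self) -> None:
        for name in ("fst_deep", "fst_shallow"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_per_pop < 1:
            raise ValueError("n_per_pop must be positive")
        if not self.depth_per_sample > 0:
            raise ValueError("depth_per_sample must be positive")
        if self.n_pops != 3:
            raise ValueError("only the 3-population hierarchy is implemented")


@dataclass
class FreqTable:
    """Per-site true derived-allele frequencies — the simulation ground truth.

    ``freq_subpop`` (sites x populations) is present only for structured runs.
    """

    freq_ancestral: np.ndarray
    freq_subpop: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.freq_ancestral = np.asarray(self.freq_ancestral, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.freq_ancestral.shape[0]

    @property
    def is_variable_pop(self) -> np.ndarray:
        """Population-level polymorphism flag: frequency strictly in (0, 1)."""
        p = self.freq_ancestral
        return (p > 0.0) & (p < 1.0)


@dataclass
class ReadCounts:
    """Per-site per-individual read counts for the two alleles."""

    ancestral: np.ndarray
    derived: np.ndarray

    def __post_init__(self) -> None:
        self.ancestral = np.asarray(self.ancestral)
        self.derived = np.asarray(self.derived)
        if self.ancestral.shape != self.derived.shape:
            raise ValueError("ancestral/derived count shapes differ")

    @property
    def total(self) -> np.ndarray:
        return self.ancestral + self.derived

    @property
    def shape(self) -> tuple:
        return self.ancestral.shape


def truncated_exponential(
    rate: float, size: int, rng: RngLike = None
) -> np.ndarray:
    """Sample from density ∝ exp(-rate * x) truncated to (0, 1), by inverse CDF."""
    if not rate > 0:
        raise ValueError("rate must be positive")
    rng = as_rng(rng)
    u = rng.random(size)
    return -np.log1p(-u * (-np.expm1(-rate))) / rate


def neutral_diffusion_freqs(
    f_min: float, size: int, rng: RngLike = None, power: float = 1.0
) -> np.ndarray:
    """Sample from density ∝ f^-power on (f_min, 1), by inverse CDF.

    ``power=1`` is the expected neutral-diffusion spectrum; ``power=2`` is
    its squared, renormalised (expansion-skewed) variant.
    """
    if not 0.0 < f_min < 1.0:
        raise ValueError("f_min must be in (0, 1)")
    rng = as_rng(rng)
    u = rng.random(size)
    if power == 1.0:
        return f_min ** (1.0 - u)
    if power == 2.0:
        return f_min / (u + (1.0 - u) * f_min)
    raise ValueError("power must be 1 or 2")


def draw_ancestral_freqs(
    cfg: SimulationConfig, rng: RngLike = None
) -> FreqTable:
    """Draw per-site ancestral derived-allele frequencies.

    Each site is independently variable with probability ``prob_variable``;
    variable sites get a frequency from the configured SFS family; invariable
    sites are exactly 0.  The expansion variants square the density and
    renormalise, which for the exponential family doubles the rate
    (exp(-r f)^2 ∝ exp(-2 r f)) and for the 1/f family gives 1/f^2.
    """
    rng = as_rng(rng if rng is not None else cfg.seed)
    variable = rng.random(cfg.n_sites) < cfg.prob_variable
    freqs = np.zeros(cfg.n_sites)
    n_var = int(variable.sum())
    if n_var:
        if cfg.sfs_model in ("neutral_diffusion", "expansion_skewed"):
            power = 1.0 if cfg.sfs_model == "neutral_diffusion" else 2.0
            freqs[variable] = neutral_diffusion_freqs(cfg.f_min, n_var, rng, power)
        else:
            rate = cfg.exp_rate if cfg.sfs_model == "neutral_exponential" else 2.0 * cfg.exp_rate
            freqs[variable] = truncated_exponential(rate, n_var, rng)
    return FreqTable(freq_ancestral=freqs)


def _balding_nichols(
    p: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """One Beta draw per site with mean p and variance fst*p*(1-p); p in {0,1} passes through."""
    out = np.array(p, dtype=float, copy=True)
    interior = (p > 0.0) & (p < 1.0)
    if np.any(interior):
        pi = p[interior]
        scale = (1.0 - fst) / fst
        out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def draw_subpop_freqs(
    freq: FreqTable, scfg: StructureConfig, rng: RngLike = None
) -> FreqTable:
    """Derive 3 subpopulation frequency columns from the ancestral frequencies.

    Two Balding–Nichols draws at ``fst_deep``: the first becomes population
    1's frequency, the second acts as the ancestral frequency for populations
    2 and 3, each drawn at ``fst_shallow``.  Sites invariable in the ancestral
    population stay invariable everywhere.
    """
    if not 0.0 < scfg.fst_deep < 1.0 or not 0.0 < scfg.fst_shallow < 1.0:
        raise ValueError("F_ST values must be in (0, 1)")
    rng = as_rng(rng)
    p = freq.freq_ancestral
    pop1 = _balding_nichols(p, scfg.fst_deep, rng)
    anc23 = _balding_nichols(p, scfg.fst_deep, rng)
    pop2 = _balding_nichols(anc23, scfg.fst_shallow, rng)
    pop3 = _balding_nichols(anc23, scfg.fst_shallow, rng)
    return FreqTable(
        freq_ancestral=p, freq_subpop=np.column_stack([pop1, pop2, pop3])
    )


def genotype_probabilities(p: np.ndarray, inbreeding_F: float = 0.0) -> np.ndarray:
    """Per-site probabilities of carrying 0/1/2 derived alleles.

    HWE deformed by inbreeding F:
    ((1-p)^2 + F p (1-p), 2 p (1-p) (1-F), p^2 + F p (1-p)).
    """
    if not 0.0 <= inbreeding_F <= 1.0:
        raise ValueError("inbreeding_F must be in [0, 1]")
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    fpq = inbreeding_F * p * q
    probs = np.stack([q * q + fpq, 2.0 * p * q * (1.0 - inbreeding_F), p * p + fpq], axis=-1)
    return probs


def draw_genotypes(
    freqs: Union[FreqTable, np.ndarray],
    n_individuals: int,
    inbreeding_F: float = 0.0,
    rng: RngLike = None,
) -> np.ndarray:
    """Draw a (sites x individuals) genotype matrix of derived-allele counts.

    ``freqs`` may be a :class:`FreqTable` (its ancestral column is used) or a
    plain per-site frequency array.
    """
    if isinstance(freqs, FreqTable):
        p = freqs.freq_ancestral
    else:
        p = np.asarray(freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    rng = as_rng(rng)
    probs = genotype_probabilities(p, inbreeding_F)  # (sites, 3)
    u = rng.random((p.shape[0], n_individuals))
    c0 = probs[:, :1]
    c1 = c0 + probs[:, 1:2]
    g = (u >= c0).astype(np.int8) + (u >= c1).astype(np.int8)
    return g


def simulate_reads(
    g: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: RngLike = None,
    error_model: str = "four_base_collapsed",
) -> ReadCounts:
    """Simulate per-cell read counts from genotypes.

    Depth per (site, individual) is Poisson(``mean_depth``); each read samples
    one of the two parental alleles uniformly and is reported as the alternate
    allele with the channel's flip probability, so the per-read probability of
    a *derived* call is eps, 1/2, 1-eps for genotypes 0, 1, 2 (the flip
    channel is symmetric, hence exactly 1/2 for heterozygotes).
    """
    g = np.asarray(g)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be 0, 1 or 2")
    if not mean_depth > 0:
        raise ValueError("mean_depth must be positive")
    eps = flip_rate(error_rate, error_model)
    rng = as_rng(rng)
    depth = rng.poisson(mean_depth, size=g.shape)
    p_derived = np.choose(g, [eps, 0.5, 1.0 - eps])
    derived = rng.binomial(depth, p_derived)
    return ReadCounts(ancestral=depth - derived, derived=derived)
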