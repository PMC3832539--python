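"""Window-level nucleotide diversity from known genotypes and from SAF posteriors.

Two window statistics are tracked: S, the proportion of segregating sites,
and H, the mean expected heterozygosity 2 f (1 - f).  With known genotypes
both are plain sample quantities; with sequencing data they are posterior
expectations under the per-site sample-allele-frequency posterior:

    S_seq = mean over sites of P(variable)
    H_seq = mean over sites of sum_j post[j] * 2 (j/2N) (1 - j/2N)

The standardised bias of a window is (seq - known) / known, where the known
baseline is computed from the *full* pool of true genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import spearmanr

from .likelihoods import SAFPosterior

__all__ = [
    "DiversityEstimates",
    "BiasResult",
    "OutlierRecovery",
    "windows",
    "diversity_known",
    "diversity_seq",
    "diversity_from_site_stats",
    "standardized_bias",
    "outlier_recovery",
]


@dataclass
class DiversityEstimates:
    S: np.ndarray  # per-window proportion of segregating sites
    H: np.ndarray  # per-window mean expected heterozygosity
    source: str    # "known_genotypes" or "sequencing"

    @property
    def n_windows(self) -> int:
        return len(self.S)


@dataclass
class BiasResult:
    delta_S: np.ndarray
    delta_H: np.ndarray
    window_index: np.ndarray


@dataclass
class OutlierRecovery:
    top_overlap: int
    bottom_overlap: int
    spearman_rho: float
    k: int


def windows(n_sites: int, n_windows: int) -> List[slice]:
    """Contiguous, disjoint, exhaustive windows; the last absorbs any remainder."""
    if n_windows < 1:
        raise ValueError("n_windows must be positive")
    if n_windows > n_sites:
        raise ValueError("more windows than sites")
    base = n_sites // n_windows
    bounds = [i * base for i in range(n_windows)] + [n_sites]
    return [slice(bounds[i], bounds[i + 1]) for i in range(n_windows)]


def sample_frequencies(g: np.ndarray) -> np.ndarray:
    """Per-site derived-allele frequency in the sample."""
    g = np.asarray(g)
    return g.sum(axis=1) / (2.0 * g.shape[1])


def diversity_known(
    g: np.ndarray,
    window_map: Sequence[slice],
    polymorphic_rule: str = "sample_freq",
    small_sample_correction: bool = False,
) -> DiversityEstimates:
    """S and H per window from a complete genotype matrix.

    A site segregates when its sample frequency is strictly in (0, 1)
    (``polymorphic_rule="any_het"`` instead flags sites with at least one
    heterozygote, a stricter text-book indicator that misses heterozygote-free
    polymorphic configurations).  H is 2 f (1 - f) per site, optionally with
    the 2N/(2N-1) small-sample factor.
    """
    g = np.asarray(g)
    f = sample_frequencies(g)
    if polymorphic_rule == "sample_freq":
        seg = (f > 0.0) & (f < 1.0)
    elif polymorphic_rule == "any_het":
        seg = (g == 1).any(axis=1)
    else:
        raise ValueError(f"unknown polymorphic_rule {polymorphic_rule!r}")
    het = 2.0 * f * (1.0 - f)
    if small_sample_correction:
        n2 = 2 * g.shape[1]
        het = het * n2 / (n2 - 1)
    S = np.array([seg[w].mean() for w in window_map])
    H = np.array([het[w].mean() for w in window_map])
    return DiversityEstimates(S=S, H=H, source="known_genotypes")


def diversity_from_site_stats(
    p_variable: np.ndarray,
    het: np.ndarray,
    window_map: Sequence[slice],
) -> DiversityEstimates:
    """Window averages of per-site P(variable) and posterior heterozygosity."""
    p_variable = np.asarray(p_variable, dtype=float)
    het = np.asarray(het, dtype=float)
    S = np.array([p_variable[w].mean() for w in window_map])
    H = np.array([het[w].mean() for w in window_map])
    return DiversityEstimates(S=S, H=H, source="sequencing")


def diversity_seq(
    saf: SAFPosterior,
    window_map: Sequence[slice],
) -> DiversityEstimates:
    """S and H per window from full SAF posteriors (any prior)."""
    n2 = saf.n_chrom
    j = np.arange(n2 + 1)
    site_het = saf.post @ (2.0 * (j / n2) * (1.0 - j / n2))
    return diversity_from_site_stats(saf.p_variable, site_het, window_map)


def standardized_bias(
    est_seq: DiversityEstimates, est_known: DiversityEstimates
) -> BiasResult:
    """Per-window (seq - known) / known for S and H.

    Windows where a known-genotype denominator is zero are reported as NaN
    with a warning; downstream summaries should drop them.
    """
    if est_seq.n_windows != est_known.n_windows:
        raise ValueError("window counts differ")

    def _delta(seq: np.ndarray, known: np.ndarray) -> np.ndarray:
        bad = known == 0.0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} window(s) with zero known-genotype value excluded from bias",
                stacklevel=3,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (seq - known) / known
        return np.where(bad, np.nan, d)

    return BiasResult(
        delta_S=_delta(est_seq.S, est_known.S),
        delta_H=_delta(est_seq.H, est_known.H),
        window_index=np.arange(est_seq.n_windows),
    )


def outlier_recovery(
    known: np.ndarray, seq: np.ndarray, k: int
) -> OutlierRecovery:
    """Shared top-k / bottom-k windows between two per-window series.

    Ranks tie-break by window index (stable sort), so the selection is
    deterministic.  Also reports the Spearman rank correlation between the
    series.
    """
    known = np.asarray(known, dtype=float)
    seq = np.asarray(seq, dtype=float)
    if known.shape != seq.shape:
        raise ValueError("series lengths differ")
    n = known.shape[0]
    if n < 2 * k:
        raise ValueError("need at least 2k windows")
    order_known = np.argsort(known, kind="stable")
    order_seq = np.argsort(seq, kind="stable")
    bottom = len(set(order_known[:k]) & set(order_seq[:k]))
    top = len(set(order_known[-k:]) & set(order_seq[-k:]))
    rho = spearmanr(known, seq).statistic
    return OutlierRecovery(top_overlap=top, bottom_overlap=bottom, spearman_rho=float(rho), k=k)
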