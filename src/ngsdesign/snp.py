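"""SNP calling from the per-site probability of being variable, and its scoring.

A site is called polymorphic when P(variable) exceeds a threshold.  The
threshold is either fixed (0.90 / 0.95 / 0.99 are the conventional choices)
or chosen *dynamically* to minimise |#called - #truly variable| — an oracle
procedure only meaningful in simulations, where the true count is known, but
one that balances over- and under-calling.

The dynamic scan runs, by default, over the observed unique probabilities at
or above a noise floor (0.01).  The floor matters: at high depth the
probability spectrum is bimodal (detectable SNPs at ~1, everything else
within noise of 0), and an unrestricted scan would descend into the noise
cluster purely to match the count, manufacturing false positives that no
realistic caller would emit.  An unfloored scan (``min_threshold=0``) and a
fixed-step grid (``candidates="grid"``) are available as variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SNPCallResult",
    "dynamic_threshold",
    "call_and_score",
    "depth_filter",
    "maf_restrict",
]

logger = logging.getLogger(__name__)

FIXED_THRESHOLDS = (0.90, 0.95, 0.99)


@dataclass
class SNPCallResult:
    """Confusion counts and rates for one set of calls against one truth."""

    threshold: float
    calls: np.ndarray
    tp: int
    fp: int
    fn: int
    tn: int
    fp_rate: float
    fn_rate: float
    precision: float
    recall: float
    truth_level: str = "population"


def _called_counts(p_sorted: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # calls use strict inequality p > t
    return p_sorted.size - np.searchsorted(p_sorted, thresholds, side="right")


def dynamic_threshold(
    p_variable: np.ndarray,
    true_count: int,
    candidates: str = "data",
    min_threshold: float = 0.01,
    grid_step: float = 0.01,
) -> float:
    """Threshold minimising |#called - true_count|; ties go to the larger value.

    ``candidates="data"`` (default) scans the observed unique probabilities
    no smaller than ``min_threshold``, plus {min_threshold, 1};
    ``candidates="grid"`` scans min_threshold, +grid_step, ..., 1.
    """
    p = np.asarray(p_variable, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if not 0.0 <= min_threshold <= 1.0:
        raise ValueError("min_threshold must be in [0, 1]")
    if candidates == "grid":
        ts = np.arange(min_threshold, 1.0 + grid_step / 2, grid_step)
    elif candidates == "data":
        ts = np.union1d(np.unique(p[p >= min_threshold]), [min_threshold, 1.0])
    else:
        raise ValueError(f"unknown candidate set {candidates!r}")
    p_sorted = np.sort(p)
    diff = np.abs(_called_counts(p_sorted, ts) - true_count)
    best = diff.min()
    return float(ts[diff == best].max())


def call_and_score(
    p_variable: np.ndarray,
    threshold: float,
    truth: np.ndarray,
    truth_level: str = "population",
) -> SNPCallResult:
    """Call sites at ``p > threshold`` and score against boolean truth flags.

    FP rate is FP over truly-invariable sites, FN rate is FN over truly
    variable sites; precision with zero calls is reported as 1 (logged).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    p = np.asarray(p_variable, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if p.shape != truth.shape:
        raise ValueError("probability and truth shapes differ")
    calls = p > threshold
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    pos = tp + fn
    neg = fp + tn
    fp_rate = fp / neg if neg else 0.0
    fn_rate = fn / pos if pos else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision = 1.0
        logger.info("no calls at threshold %.3f; precision reported as 1", threshold)
    recall = tp / pos if pos else 0.0
    return SNPCallResult(
        threshold=float(threshold),
        calls=calls,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        fp_rate=fp_rate,
        fn_rate=fn_rate,
        precision=precision,
        recall=recall,
        truth_level=truth_level,
    )


def depth_filter(total_depth: np.ndarray, percentile: float) -> np.ndarray:
    """Mask of sites whose total depth is >= the given empirical percentile."""
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    total_depth = np.asarray(total_depth)
    cutoff = np.percentile(total_depth, percentile)
    return total_depth >= cutoff


def maf_restrict(freqs: np.ndarray, min_maf: float = 0.01) -> np.ndarray:
    """Mask of sites with minor-allele frequency strictly above ``min_maf``."""
    f = np.asarray(freqs, dtype=float)
    return np.minimum(f, 1.0 - f) > min_maf
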