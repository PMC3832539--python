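"""Genotype likelihoods and the sample-allele-frequency (SAF) machinery.

Per (site, individual) cell with `a` ancestral and `d` derived reads and a
symmetric per-read flip probability eps, the genotype log-likelihoods are

    log L(g=0) = a log(1-eps) + d log(eps)
    log L(g=1) = (a+d) log(1/2)
    log L(g=2) = a log(eps)   + d log(1-eps)

Cells with no reads carry equal likelihoods for the three genotypes.

From the per-individual likelihoods of a site, the sample allele frequency
likelihood P(D | X=j) over j = 0..2N derived chromosomes is computed by the
standard dynamic programming over individuals (a polynomial product with
combinatorial weights 1, 2, 1 for g = 0, 1, 2, divided by C(2N, j)).

With the default empirical-Bayes prior — X ~ Binomial(2N, f_ml), i.e. HWE at
the maximum-likelihood allele frequency — the SAF posterior is exactly the
distribution of a sum of *independent* per-individual posterior genotypes.
That identity gives closed forms in O(N) per site for the quantities the
pipeline needs at scale: the probability of the site being variable
(1 - post[0] - post[2N]) and the posterior expectation of the sample
heterozygosity.  The O(N^2) DP remains the general (and test-oracle) route
and supports arbitrary priors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .sim import ReadCounts, flip_rate

__all__ = [
    "GenotypeLikelihoods",
    "SAFPosterior",
    "genotype_likelihoods",
    "estimate_allele_freq_ml",
    "site_variability",
    "genotype_posteriors",
    "expected_sample_heterozygosity",
    "saf_likelihood",
    "saf_posterior",
    "point_mass_posteriors",
    "freq_init_from_counts",
    "MixtureSFS",
    "SiteStats",
    "default_f_grid",
    "component_site_stats",
    "concat_component_stats",
    "fit_sfs_mixture",
    "mixture_site_stats",
    "mixture_genotype_posteriors",
]

PRIOR_FLOOR = 1e-12  # floor on HWE prior entries to avoid 0 * inf in posteriors


def _xlogy(x: np.ndarray, y: float) -> np.ndarray:
    """x * log(y) with the convention 0 * log(0) = 0."""
    if y > 0:
        return x * np.log(y)
    out = np.full(np.shape(x), -np.inf)
    out[np.asarray(x) == 0] = 0.0
    return out


@dataclass
class GenotypeLikelihoods:
    """Log-likelihoods for derived-allele counts {0, 1, 2}, (sites, individuals, 3)."""

    logl: np.ndarray
    flip: float

    def __post_init__(self) -> None:
        self.logl = np.asarray(self.logl, dtype=float)
        if self.logl.ndim != 3 or self.logl.shape[-1] != 3:
            raise ValueError("logl must have shape (sites, individuals, 3)")

    @property
    def n_sites(self) -> int:
        return self.logl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.logl.shape[1]

    def linear(self) -> np.ndarray:
        """Linear-space likelihoods rescaled so each cell's maximum is 1."""
        return np.exp(self.logl - self.logl.max(axis=-1, keepdims=True))


@dataclass
class SAFPosterior:
    """Per-site posterior over the count of derived chromosomes in the sample."""

    post: np.ndarray  # (sites, 2N+1)
    p_variable: np.ndarray
    f_ml: np.ndarray

    def __post_init__(self) -> None:
        self.post = np.asarray(self.post, dtype=float)

    @property
    def n_chrom(self) -> int:
        return self.post.shape[1] - 1

    @property
    def mode(self) -> np.ndarray:
        # argmax takes the first maximum: ties break toward smaller j
        return self.post.argmax(axis=1)


def genotype_likelihoods(
    counts: ReadCounts,
    error_rate: float,
    error_model: str = "four_base_collapsed",
) -> GenotypeLikelihoods:
    """Compute genotype log-likelihoods from allele read counts.

    The error channel must match the one used to simulate the reads (same
    ``error_rate`` and ``error_model``).
    """
    eps = flip_rate(error_rate, error_model)
    a = np.asarray(counts.ancestral, dtype=float)
    d = np.asarray(counts.derived, dtype=float)
    l0 = _xlogy(a, 1.0 - eps) + _xlogy(d, eps)
    l1 = (a + d) * np.log(0.5)
    l2 = _xlogy(a, eps) + _xlogy(d, 1.0 - eps)
    return GenotypeLikelihoods(logl=np.stack([l0, l1, l2], axis=-1), flip=eps)


def _linear_gl(gl) -> np.ndarray:
    if isinstance(gl, GenotypeLikelihoods):
        lin = gl.linear()
    else:
        lin = np.asarray(gl, dtype=float)
    if lin.ndim == 2:
        lin = lin[None, :, :]
    if lin.ndim != 3 or lin.shape[-1] != 3:
        raise ValueError("genotype likelihoods must have shape (sites, individuals, 3)")
    return lin


def _em_step(l0, l1, l2, f):
    fa = f[:, None]
    w0 = l0 * (1.0 - fa) ** 2
    w1 = l1 * 2.0 * fa * (1.0 - fa)
    w2 = l2 * fa * fa
    dosage = (w1 + 2.0 * w2) / (w0 + w1 + w2)
    return dosage.mean(axis=1) / 2.0


def _em_allele_freq(l0, l1, l2, f0, tol, max_iter):
    # EM with Aitken extrapolation: near a boundary optimum plain EM contracts
    # arbitrarily slowly, so every third sweep the geometric fixed point is
    # jumped to and kept wherever it improves the likelihood.
    f = np.clip(np.array(f0, dtype=float, copy=True), 1e-8, 1 - 1e-8)
    active = np.arange(f.shape[0])
    sweeps = 0
    while sweeps < max_iter and active.size:
        la0, la1, la2 = l0[active], l1[active], l2[active]
        f0_, = (f[active],)
        f1_ = _em_step(la0, la1, la2, f0_)
        f2_ = _em_step(la0, la1, la2, f1_)
        f3_ = _em_step(la0, la1, la2, f2_)
        sweeps += 3
        d1 = f1_ - f0_
        d2 = f2_ - f1_
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(np.abs(d1) > 0, d2 / d1, 0.0)
            f_acc = np.where(
                (rate > 0) & (rate < 1), f1_ + d1 / (1.0 - rate), f3_
            )
        f_acc = np.clip(f_acc, 1e-10, 1 - 1e-10)
        better = _hwe_loglik(la0, la1, la2, f_acc) > _hwe_loglik(la0, la1, la2, f3_)
        f_next = np.where(better, f_acc, f3_)
        delta = np.abs(f_next - f0_)
        f[active] = f_next
        active = active[delta >= tol]
    return f


def _hwe_loglik(l0, l1, l2, f):
    fa = np.asarray(f)[:, None]
    with np.errstate(divide="ignore"):
        return np.log(
            l0 * (1.0 - fa) ** 2 + l1 * 2.0 * fa * (1.0 - fa) + l2 * fa * fa
        ).sum(axis=1)


def estimate_allele_freq_ml(
    gl,
    tol: float = 1e-6,
    max_iter: int = 100,
    init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Maximum-likelihood allele frequency per site, by EM over individuals.

    Maximises sum_i log sum_g L_i(g) HWE(g | f).  The EM update is the mean
    posterior genotype dosage: f' = (1/2N) sum_i E[g_i | f].  Iterates until
    |f' - f| < ``tol`` (at most ``max_iter`` sweeps); sites converge and drop
    out of the active set individually.  EM climbs monotonically but only
    locally, and the likelihood can peak at both boundaries, so a second
    start from the mirrored frequency guards against the wrong corner.
    Sites with no reads anywhere return 0.
    """
    lin = _linear_gl(gl)
    n_sites = lin.shape[0]
    l0, l1, l2 = lin[..., 0], lin[..., 1], lin[..., 2]
    f0 = np.full(n_sites, 0.1) if init is None else np.asarray(init, dtype=float)
    f_a = _em_allele_freq(l0, l1, l2, f0, tol, max_iter)
    f_b = _em_allele_freq(l0, l1, l2, 1.0 - f0, tol, max_iter)
    f = np.where(_hwe_loglik(l0, l1, l2, f_a) >= _hwe_loglik(l0, l1, l2, f_b), f_a, f_b)
    no_data = np.all((l0 == l1) & (l1 == l2), axis=1)
    f[no_data] = 0.0
    return np.clip(f, 0.0, 1.0)


def _per_individual_log_terms(
    lin: np.ndarray, f: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log of the monomorphic-corner contributions and of the per-individual marginal."""
    fa = f[:, None]
    w0 = lin[..., 0] * (1.0 - fa) ** 2
    w1 = lin[..., 1] * 2.0 * fa * (1.0 - fa)
    w2 = lin[..., 2] * fa * fa
    denom = w0 + w1 + w2
    with np.errstate(divide="ignore"):
        return np.log(w0), np.log(w2), np.log(denom)


def site_variability(gl, f_ml: np.ndarray) -> np.ndarray:
    """P(site variable in the sample) = 1 - post[0] - post[2N], closed form.

    Exact under the HWE-at-``f_ml`` binomial prior, for which the SAF
    posterior factorises over individuals:
    post[0] = prod_i L_i(0)(1-f)^2 / D_i and symmetrically for post[2N],
    with D_i the per-individual marginal likelihood.
    """
    lin = _linear_gl(gl)
    f = np.asarray(f_ml, dtype=float)
    out = np.zeros(lin.shape[0])
    interior = (f > 0.0) & (f < 1.0)
    if np.any(interior):
        lw0, lw2, ld = _per_individual_log_terms(lin[interior], f[interior])
        lp0 = (lw0 - ld).sum(axis=1)
        lp2n = (lw2 - ld).sum(axis=1)
        out[interior] = np.clip(1.0 - np.exp(lp0) - np.exp(lp2n), 0.0, 1.0)
    return out


def genotype_posteriors(gl, f_ml: np.ndarray, prior_floor: float = PRIOR_FLOOR) -> np.ndarray:
    """Per-cell genotype posterior P(g | D) ∝ L(g) * HWE(g | f_ml), normalised.

    The HWE prior is floored at ``prior_floor`` so that a boundary frequency
    cannot zero out a genotype that carries all the likelihood.
    """
    lin = _linear_gl(gl)
    f = np.asarray(f_ml, dtype=float)[:, None]
    prior = np.stack(
        [
            np.broadcast_to((1.0 - f) ** 2, lin.shape[:2]),
            np.broadcast_to(2.0 * f * (1.0 - f), lin.shape[:2]),
            np.broadcast_to(f * f, lin.shape[:2]),
        ],
        axis=-1,
    )
    w = lin * np.maximum(prior, prior_floor)
    return w / w.sum(axis=-1, keepdims=True)


def expected_sample_heterozygosity(gl, f_ml: np.ndarray) -> np.ndarray:
    """Posterior mean of 2 (X/2N)(1 - X/2N) per site, X = derived chromosomes.

    Uses the factorisation of the SAF posterior under the HWE prior:
    X is a sum of independent per-individual posterior genotypes, so
    E[X] and E[X^2] follow from per-individual means and variances.
    """
    lin = _linear_gl(gl)
    n2 = 2 * lin.shape[1]
    post = genotype_posteriors(gl, f_ml)
    m = post[..., 1] + 2.0 * post[..., 2]  # E[g_i]
    s = post[..., 1] + 4.0 * post[..., 2]  # E[g_i^2]
    mu = m.sum(axis=1)
    var = (s - m * m).sum(axis=1)
    ex2 = var + mu * mu
    return (2.0 / n2) * mu - (2.0 / n2**2) * ex2


def saf_likelihood(gl, return_log: bool = True) -> np.ndarray:
    """SAF log-likelihoods P(D | X=j), j = 0..2N, for every site.

    Dynamic programming over individuals: the unnormalised coefficients are
    the product of per-individual quadratics (L(0), 2 L(1), L(2)); dividing
    coefficient j by C(2N, j) yields the configuration-averaged likelihood.
    The accumulator is max-rescaled per step; output is log-space (or linear,
    normalised to max 1, with ``return_log=False``).
    """
    lin = _linear_gl(gl)
    n_sites, n_ind, _ = lin.shape
    n2 = 2 * n_ind
    q = np.zeros((n_sites, n2 + 1))
    q[:, 0] = 1.0
    logscale = np.zeros(n_sites)
    for i in range(n_ind):
        g0 = lin[:, i, 0][:, None]
        g1 = lin[:, i, 1][:, None]
        g2 = lin[:, i, 2][:, None]
        hi = 2 * i + 2
        new = np.zeros_like(q)
        new[:, :hi + 1] = g0 * q[:, :hi + 1]
        new[:, 1:hi + 1] += 2.0 * g1 * q[:, :hi]
        new[:, 2:hi + 1] += g2 * q[:, :hi - 1]
        m = new.max(axis=1)
        m[m == 0] = 1.0  # fully degenerate site; will stay -inf in log space
        q = new / m[:, None]
        logscale += np.log(m)
    j = np.arange(n2 + 1)
    log_choose = gammaln(n2 + 1) - gammaln(j + 1) - gammaln(n2 - j + 1)
    with np.errstate(divide="ignore"):
        loglik = np.log(q) - log_choose[None, :] + logscale[:, None]
    if return_log:
        return loglik
    lin_out = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    return lin_out


def point_mass_posteriors(g: np.ndarray) -> np.ndarray:
    """One-hot genotype 'posteriors' from a known (sites, individuals) genotype matrix."""
    g = np.asarray(g)
    post = np.zeros(g.shape + (3,))
    np.put_along_axis(post, g[..., None].astype(int), 1.0, axis=-1)
    return post


def freq_init_from_counts(counts: ReadCounts) -> np.ndarray:
    """Per-site derived read fraction (add-one smoothed) — a cheap EM start point."""
    d = counts.derived.sum(axis=1).astype(float)
    t = counts.total.sum(axis=1).astype(float)
    return (d + 1.0) / (t + 2.0)


def _log_prior(prior: str, n2: int, f_ml: Optional[np.ndarray], n_sites: int) -> np.ndarray:
    j = np.arange(n2 + 1)
    if prior == "uniform":
        return np.zeros((n_sites, n2 + 1))
    if prior == "neutral_1_over_j":
        w = np.ones(n2 + 1)
        w[1:] = 1.0 / j[1:]
        return np.broadcast_to(np.log(w / w.sum()), (n_sites, n2 + 1)).copy()
    if prior == "hwe_f_ml":
        if f_ml is None:
            raise ValueError("prior 'hwe_f_ml' requires f_ml")
        f = np.clip(np.asarray(f_ml, dtype=float), 0.0, 1.0)[:, None]
        log_choose = gammaln(n2 + 1) - gammaln(j + 1) - gammaln(n2 - j + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = log_choose[None, :] + j[None, :] * np.log(f) + (n2 - j)[None, :] * np.log(1.0 - f)
        # boundary frequencies: point masses at 0 / 2N
        lp = np.where(np.isnan(lp), -np.inf, lp)
        at0 = f[:, 0] == 0.0
        at1 = f[:, 0] == 1.0
        lp[at0] = -np.inf
        lp[at0, 0] = 0.0
        lp[at1] = -np.inf
        lp[at1, n2] = 0.0
        return lp
    raise ValueError(f"unknown prior {prior!r}")


@dataclass
class MixtureSFS:
    """Region-wide empirical-Bayes prior: P(invariable) = 1 - pi, and a
    weighted grid of HWE frequency components for variable sites."""

    f_grid: np.ndarray
    weights: np.ndarray  # mixture weights over f_grid, sum to 1
    pi: float            # prior probability that a site is variable


@dataclass
class SiteStats:
    """Per-site posterior summaries under the mixture prior."""

    p_variable: np.ndarray
    het: Optional[np.ndarray]  # posterior mean of 2 (X/2N)(1 - X/2N); None if skipped
    mean_freq: np.ndarray      # posterior mean of X/2N


def default_f_grid(n_points: int = 10, f_low: float = 1e-4) -> np.ndarray:
    """Log-spaced frequency grid on (f_low, 0.5], mirrored about 0.5.

    Dense near 0 and 1, where the neutral spectrum concentrates and where
    discrimination from sequencing error is hardest.
    """
    lo = np.logspace(np.log10(f_low), np.log10(0.5), n_points)
    return np.unique(np.concatenate([lo, 1.0 - lo]))


def component_site_stats(gl, f_grid: np.ndarray, moments: bool = True, dtype=None) -> dict:
    """Per-site, per-component sufficient statistics for the mixture model.

    For each grid frequency f_k (under which individuals are iid HWE), using
    the factorised SAF posterior: the site log marginal likelihood, the log
    posterior mass at X=0 and X=2N, and the mean/variance of X.  The null
    (invariable) component's log likelihood is returned separately.
    Outputs are (sites, K) arrays; rows from successive site batches may be
    concatenated before fitting.  ``moments=False`` skips the second moment
    (not needed when only P(variable) and the mean frequency are consumed);
    ``dtype`` (e.g. float32) trades per-cell precision for throughput — the
    per-site sums are always accumulated in float64.
    """
    lin = _linear_gl(gl)
    if dtype is not None:
        lin = lin.astype(dtype)
    n_sites, n_ind, _ = lin.shape
    K = len(f_grid)
    keys = ("loglik", "lp0", "lp2n", "mu") + (("var",) if moments else ())
    out = {k: np.empty((n_sites, K)) for k in keys}
    l0, l1, l2 = lin[..., 0], lin[..., 1], lin[..., 2]
    with np.errstate(divide="ignore"):
        out["ll_null"] = np.where(l0 > 0, np.log(l0), -np.inf).sum(axis=1, dtype=np.float64)
        for k, f in enumerate(f_grid):
            w0 = l0 * np.asarray((1.0 - f) ** 2, dtype=lin.dtype)
            w1 = l1 * np.asarray(2.0 * f * (1.0 - f), dtype=lin.dtype)
            w2 = l2 * np.asarray(f * f, dtype=lin.dtype)
            denom = w0 + w1 + w2
            ld = np.log(denom)
            out["loglik"][:, k] = ld.sum(axis=1, dtype=np.float64)
            out["lp0"][:, k] = (np.log(w0) - ld).sum(axis=1, dtype=np.float64)
            out["lp2n"][:, k] = (np.log(w2) - ld).sum(axis=1, dtype=np.float64)
            m = (w1 + 2.0 * w2) / denom
            out["mu"][:, k] = m.sum(axis=1, dtype=np.float64)
            if moments:
                s = (w1 + 4.0 * w2) / denom
                out["var"][:, k] = (s - m * m).sum(axis=1, dtype=np.float64)
    out["n_individuals"] = n_ind
    out["f_grid"] = np.asarray(f_grid, dtype=float)
    return out


def concat_component_stats(parts: list) -> dict:
    """Stack per-batch outputs of :func:`component_site_stats` site-wise."""
    first = parts[0]
    keys = [k for k in ("loglik", "lp0", "lp2n", "mu", "var", "ll_null") if k in first]
    out = {k: np.concatenate([p[k] for p in parts], axis=0) for k in keys}
    out["n_individuals"] = first["n_individuals"]
    out["f_grid"] = first["f_grid"]
    return out


def fit_sfs_mixture(
    comp: dict,
    pi_init: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MixtureSFS:
    """EM fit of the mixture prior (pi and grid weights) across sites."""
    ll = comp["loglik"]
    ll_null = comp["ll_null"]
    n_sites, K = ll.shape
    w = np.full(K, 1.0 / K)
    pi = float(pi_init)
    prev = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_var = ll + np.log(pi * w)[None, :]
            log_null = ll_null + np.log(1.0 - pi)
        stacked = np.column_stack([log_null, log_var])
        top = stacked.max(axis=1, keepdims=True)
        r = np.exp(stacked - top)
        norm = r.sum(axis=1, keepdims=True)
        r /= norm
        obj = float((np.log(norm[:, 0]) + top[:, 0]).sum())
        resp_var = r[:, 1:]
        pi = float(resp_var.sum() / n_sites)
        pi = min(max(pi, 1e-12), 1 - 1e-12)
        col = resp_var.sum(axis=0)
        w = col / col.sum()
        if obj - prev < tol * max(1.0, abs(obj)):
            break
        prev = obj
    return MixtureSFS(f_grid=comp["f_grid"], weights=w, pi=pi)


def mixture_site_stats(comp: dict, mix: MixtureSFS) -> SiteStats:
    """Posterior site summaries given a fitted (or fixed) mixture prior.

    Component posterior weights are combined with the within-component
    factorised SAF posteriors: the posterior mass at the monomorphic corners
    gives P(variable); the first two moments of X give the expected sample
    heterozygosity.
    """
    with np.errstate(divide="ignore"):
        log_var = comp["loglik"] + np.log(mix.pi * mix.weights)[None, :]
        log_null = comp["ll_null"] + np.log(1.0 - mix.pi)
    stacked = np.column_stack([log_null, log_var])
    top = stacked.max(axis=1, keepdims=True)
    r = np.exp(stacked - top)
    r /= r.sum(axis=1, keepdims=True)
    omega_null, omega = r[:, 0], r[:, 1:]
    p0 = omega_null + (omega * np.exp(comp["lp0"])).sum(axis=1)
    p2n = (omega * np.exp(comp["lp2n"])).sum(axis=1)
    n2 = 2 * comp["n_individuals"]
    ex = (omega * comp["mu"]).sum(axis=1)
    if "var" in comp:
        ex2 = (omega * (comp["var"] + comp["mu"] ** 2)).sum(axis=1)
        het = np.clip((2.0 / n2) * ex - (2.0 / n2**2) * ex2, 0.0, 0.5)
    else:
        het = None
    return SiteStats(
        p_variable=np.clip(1.0 - p0 - p2n, 0.0, 1.0),
        het=het,
        mean_freq=ex / n2,
    )


def mixture_genotype_posteriors(gl, comp: dict, mix: MixtureSFS) -> np.ndarray:
    """Per-cell genotype posteriors under the fitted mixture prior.

    P(g_i | D) = omega_0 [g=0] + sum_k omega_k P(g_i | D_i, f_k), with the
    component weights omega shared by all individuals at a site.  Compared
    with an HWE prior at a point frequency this shrinks cells at
    plausibly-invariable sites all the way to homozygous ancestral, and the
    per-site mean dosage equals the posterior mean frequency exactly.
    """
    lin = _linear_gl(gl)
    with np.errstate(divide="ignore"):
        log_var = comp["loglik"] + np.log(mix.pi * mix.weights)[None, :]
        log_null = comp["ll_null"] + np.log(1.0 - mix.pi)
    stacked = np.column_stack([log_null, log_var])
    top = stacked.max(axis=1, keepdims=True)
    r = np.exp(stacked - top)
    r /= r.sum(axis=1, keepdims=True)
    post = np.zeros(lin.shape)
    post[..., 0] = r[:, 0][:, None]
    for k, f in enumerate(mix.f_grid):
        w0 = lin[..., 0] * (1.0 - f) ** 2
        w1 = lin[..., 1] * 2.0 * f * (1.0 - f)
        w2 = lin[..., 2] * f * f
        denom = w0 + w1 + w2
        wk = r[:, k + 1][:, None]
        post[..., 0] += wk * w0 / denom
        post[..., 1] += wk * w1 / denom
        post[..., 2] += wk * w2 / denom
    return post


def saf_posterior(
    saf_loglik: np.ndarray,
    prior: str = "hwe_f_ml",
    f_ml: Optional[np.ndarray] = None,
) -> SAFPosterior:
    """Normalise likelihood x prior into a per-site SAF posterior.

    ``prior`` is one of ``"hwe_f_ml"`` (default: Binomial(2N, f_ml)),
    ``"uniform"`` or ``"neutral_1_over_j"``.
    """
    ll = np.asarray(saf_loglik, dtype=float)
    if ll.ndim == 1:
        ll = ll[None, :]
    n_sites, m = ll.shape
    n2 = m - 1
    lp = ll + _log_prior(prior, n2, f_ml, n_sites)
    top = lp.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(top)):
        raise ValueError("degenerate site: SAF likelihood x prior is identically zero")
    w = np.exp(lp - top)
    post = w / w.sum(axis=1, keepdims=True)
    p_var = 1.0 - post[:, 0] - post[:, -1]
    if f_ml is None:
        f_ml = post @ (np.arange(m) / n2)
    return SAFPosterior(post=post, p_variable=np.clip(p_var, 0.0, 1.0), f_ml=np.asarray(f_ml))
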