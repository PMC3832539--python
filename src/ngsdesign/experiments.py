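"""Scenario sweeps at fixed total coverage, and their summary tables.

Each experiment compares sequencing designs (per-sample depth, sample size)
whose product — the total coverage, hence the cost — is constant.  The
single-population experiments share one simulated pool of true genotypes per
scenario and subsample individuals per design; the structure experiments
simulate three populations and resample individuals per replicate.

Every run is reproducible from its spec and seed: per-design and
per-replicate generators are spawned from one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_known, windows
from .likelihoods import (
    component_site_stats,
    concat_component_stats,
    default_f_grid,
    fit_sfs_mixture,
    genotype_likelihoods,
    genotype_posteriors,
    mixture_site_stats,
    point_mass_posteriors,
)
from .sim import (
    DEFAULT_EXP_RATE,
    DEFAULT_F_MIN,
    SimulationConfig,
    StructureConfig,
    draw_ancestral_freqs,
    draw_genotypes,
    draw_subpop_freqs,
    simulate_reads,
)
from .snp import FIXED_THRESHOLDS, call_and_score, dynamic_threshold
from .structure import (
    covariance_from_posteriors,
    fit_structure_model,
    grid_compare,
    pca,
    procrustes_align,
)

__all__ = [
    "DIVERSITY_DESIGNS",
    "STRUCTURE_DESIGNS",
    "FST_LEVELS",
    "ScenarioSpec",
    "StructureSpec",
    "ScenarioResult",
    "run_scenario",
    "run_snp_experiment",
    "run_diversity_experiment",
    "run_structure_experiment",
    "rerun_structure_replicate",
    "median_replicate",
    "write_manifest",
]

#: (per-sample depth, sample size) pairs with constant product (total coverage
#: 1000X across the sample) for the diversity / SNP-calling experiments.
DIVERSITY_DESIGNS: Tuple[Tuple[float, int], ...] = (
    (1.0, 1000),
    (2.0, 500),
    (10.0, 100),
    (50.0, 20),
)

#: (per-sample depth, individuals sampled per population); total per-population
#: coverage 40X.
STRUCTURE_DESIGNS: Tuple[Tuple[float, int], ...] = (
    (1.0, 40),
    (2.0, 20),
    (10.0, 4),
    (20.0, 2),
)

#: (deep, shallow) F_ST of the 3-population hierarchy per subdivision level.
FST_LEVELS: Dict[str, Tuple[float, float]] = {
    "high": (0.4, 0.1),
    "medium": (0.3, 0.05),
    "low": (0.1, 0.02),
}


def _check_constant_product(designs: Sequence[Tuple[float, int]]) -> None:
    products = {round(d * n, 6) for d, n in designs}
    if len(products) > 1:
        raise ValueError(f"designs do not share a total coverage: {sorted(products)}")


@dataclass
class ScenarioSpec:
    """One single-population scenario: simulator settings plus the design grid."""

    designs: Tuple[Tuple[float, int], ...] = DIVERSITY_DESIGNS
    n_windows: int = 100
    sites_per_window: int = 500
    pool_size: int = 1000
    prob_variable: float = 0.1
    sfs_model: str = "neutral_diffusion"
    exp_rate: float = DEFAULT_EXP_RATE
    f_min: float = DEFAULT_F_MIN
    inbreeding_F: float = 0.0
    error_rate: float = 0.01
    error_model: str = "four_base_collapsed"
    truth_level: str = "population"
    threshold_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        _check_constant_product(self.designs)
        if max(n for _, n in self.designs) > self.pool_size:
            raise ValueError("a design asks for more individuals than the pool holds")
        if self.truth_level not in ("population", "sample"):
            raise ValueError("truth_level must be 'population' or 'sample'")

    @property
    def n_sites(self) -> int:
        return self.n_windows * self.sites_per_window


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    windows: pd.DataFrame  # one row per design x window

    def snp_summary(self, threshold: str = "dynamic") -> pd.DataFrame:
        """Mean and SD of precision / recall across windows, one row per design."""
        suffix = "" if threshold == "dynamic" else f"_fix{int(round(float(threshold) * 100))}"
        df = self.windows
        rows = []
        for (depth, n), grp in df.groupby(["depth", "n_individuals"], sort=False):
            rows.append(
                {
                    "depth": depth,
                    "n_individuals": n,
                    "precision_mean": grp[f"precision{suffix}"].mean(),
                    "precision_sd": grp[f"precision{suffix}"].std(ddof=1),
                    "recall_mean": grp[f"recall{suffix}"].mean(),
                    "recall_sd": grp[f"recall{suffix}"].std(ddof=1),
                    "fp_rate_mean": grp[f"fp_rate{suffix}"].mean(),
                    "fn_rate_mean": grp[f"fn_rate{suffix}"].mean(),
                }
            )
        return pd.DataFrame(rows)

    def bias_summary(self) -> pd.DataFrame:
        df = self.windows
        rows = []
        for (depth, n), grp in df.groupby(["depth", "n_individuals"], sort=False):
            rows.append(
                {
                    "depth": depth,
                    "n_individuals": n,
                    "delta_S_median": grp["delta_S"].median(),
                    "delta_H_median": grp["delta_H"].median(),
                    "delta_S_mean_abs": grp["delta_S"].abs().mean(),
                    "delta_H_mean_abs": grp["delta_H"].abs().mean(),
                }
            )
        return pd.DataFrame(rows)


def _simulate_pool(spec: ScenarioSpec, rng: np.random.Generator):
    cfg = SimulationConfig(
        n_sites=spec.n_sites,
        n_individuals=spec.pool_size,
        prob_variable=spec.prob_variable,
        sfs_model=spec.sfs_model,
        exp_rate=spec.exp_rate,
        f_min=spec.f_min,
        inbreeding_F=spec.inbreeding_F,
        mean_depth=1.0,  # per-design depths are applied downstream
        error_rate=spec.error_rate,
        error_model=spec.error_model,
    )
    freq = draw_ancestral_freqs(cfg, rng)
    g_pool = draw_genotypes(freq, spec.pool_size, spec.inbreeding_F, rng)
    return freq, g_pool


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Simulate one scenario and score every design on every window.

    Produces, per (design, window): diversity estimates from the full-pool
    known genotypes, from the subsampled known genotypes and from the
    sequencing data; their standardised biases; and SNP-calling scores under
    the dynamic threshold and the conventional fixed cut-offs.
    """
    ss = np.random.SeedSequence(spec.seed)
    pool_ss, *design_ss = ss.spawn(1 + len(spec.designs))
    freq, g_pool = _simulate_pool(spec, np.random.default_rng(pool_ss))
    wmap = windows(spec.n_sites, spec.n_windows)
    known_all = diversity_known(g_pool, wmap)
    f_grid = default_f_grid()

    records = []
    for (depth, n_sample), child in zip(spec.designs, design_ss):
        rng = np.random.default_rng(child)
        idx = np.sort(rng.choice(spec.pool_size, size=n_sample, replace=False))
        g_sub = g_pool[:, idx]
        known_sub = diversity_known(g_sub, wmap)
        # first pass: per-window sufficient statistics for the SFS mixture
        parts = []
        for w in wmap:
            counts = simulate_reads(g_sub[w], depth, spec.error_rate, rng, spec.error_model)
            gl = genotype_likelihoods(counts, spec.error_rate, spec.error_model)
            parts.append(component_site_stats(gl, f_grid))
        comp = concat_component_stats(parts)
        # region-wide empirical-Bayes prior, then per-site posterior summaries
        mix = fit_sfs_mixture(comp)
        stats = mixture_site_stats(comp, mix)
        for w_i, w in enumerate(wmap):
            gw = g_sub[w]
            p_var = stats.p_variable[w]
            het = stats.het[w]

            if spec.truth_level == "population":
                truth = freq.is_variable_pop[w]
            else:
                fw = gw.sum(axis=1) / (2.0 * n_sample)
                truth = (fw > 0.0) & (fw < 1.0)
            t_dyn = dynamic_threshold(
                p_var, int(truth.sum()), min_threshold=spec.threshold_floor
            )
            rec = {
                "depth": depth,
                "n_individuals": n_sample,
                "window": w_i,
                "S_known_all": known_all.S[w_i],
                "H_known_all": known_all.H[w_i],
                "S_known_sub": known_sub.S[w_i],
                "H_known_sub": known_sub.H[w_i],
                "S_seq": p_var.mean(),
                "H_seq": het.mean(),
            }
            score = call_and_score(p_var, t_dyn, truth, spec.truth_level)
            rec.update(
                threshold=score.threshold,
                tp=score.tp,
                fp=score.fp,
                fn=score.fn,
                tn=score.tn,
                fp_rate=score.fp_rate,
                fn_rate=score.fn_rate,
                precision=score.precision,
                recall=score.recall,
            )
            for t_fix in FIXED_THRESHOLDS:
                sfx = f"_fix{int(round(t_fix * 100))}"
                sc = call_and_score(p_var, t_fix, truth, spec.truth_level)
                rec.update(
                    {
                        f"fp_rate{sfx}": sc.fp_rate,
                        f"fn_rate{sfx}": sc.fn_rate,
                        f"precision{sfx}": sc.precision,
                        f"recall{sfx}": sc.recall,
                    }
                )
            records.append(rec)

    df = pd.DataFrame.from_records(records)
    # standardised bias against the full-pool known-genotype baseline
    for stat in ("S", "H"):
        known = df[f"{stat}_known_all"].to_numpy()
        seq = df[f"{stat}_seq"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (seq - known) / known
        df[f"delta_{stat}"] = np.where(known == 0.0, np.nan, delta)
    return ScenarioResult(spec=spec, windows=df)


def run_snp_experiment(spec: ScenarioSpec) -> pd.DataFrame:
    """Mean/SD of precision and recall per design (dynamic threshold)."""
    return run_scenario(spec).snp_summary()


def run_diversity_experiment(spec: ScenarioSpec) -> pd.DataFrame:
    """Per-window standardised bias table across designs."""
    df = run_scenario(spec).windows
    cols = [
        "depth",
        "n_individuals",
        "window",
        "S_known_all",
        "H_known_all",
        "S_known_sub",
        "H_known_sub",
        "S_seq",
        "H_seq",
        "delta_S",
        "delta_H",
    ]
    return df[cols]


@dataclass
class StructureSpec:
    """Three-population structure scenario across subdivision levels."""

    designs: Tuple[Tuple[float, int], ...] = STRUCTURE_DESIGNS
    fst_levels: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(FST_LEVELS)
    )
    pool_per_pop: int = 40
    n_sites: int = 100_000
    prob_variable: float = 0.1
    sfs_model: str = "neutral_diffusion"
    exp_rate: float = DEFAULT_EXP_RATE
    f_min: float = DEFAULT_F_MIN
    error_rate: float = 0.01
    error_model: str = "four_base_collapsed"
    n_replicates: int = 100
    grid_size: Tuple[int, int] = (50, 50)
    variable_only: bool = False
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    f_grid_points: int = 6    # coarser SFS grid than the diversity pipeline
    sfs_em_iter: int = 60     # capped EM sweeps; the prior shape converges fast
    n_source_pcs: int = 6     # sequencing-side PCs fed to the projection Procrustes
    seed: int = 0

    def __post_init__(self) -> None:
        budgets = {round(d * n, 6) for d, n in self.designs}
        if len(budgets) > 1:
            raise ValueError("structure designs do not share a per-population coverage")
        if max(n for _, n in self.designs) > self.pool_per_pop:
            raise ValueError("a design samples more individuals than each population holds")


def _structure_truth(spec: StructureSpec, level: str, rng: np.random.Generator):
    fst_deep, fst_shallow = spec.fst_levels[level]
    cfg = SimulationConfig(
        n_sites=spec.n_sites,
        n_individuals=spec.pool_per_pop,
        prob_variable=spec.prob_variable,
        sfs_model=spec.sfs_model,
        exp_rate=spec.exp_rate,
        f_min=spec.f_min,
        error_rate=spec.error_rate,
        error_model=spec.error_model,
    )
    freq = draw_ancestral_freqs(cfg, rng)
    scfg = StructureConfig(fst_deep=fst_deep, fst_shallow=fst_shallow, n_per_pop=spec.pool_per_pop)
    freq = draw_subpop_freqs(freq, scfg, rng)
    g_pops = [
        draw_genotypes(freq.freq_subpop[:, k], spec.pool_per_pop, 0.0, rng)
        for k in range(3)
    ]
    g_all = np.concatenate(g_pops, axis=1)
    labels = np.repeat(np.arange(1, 4), spec.pool_per_pop)
    return freq, g_all, labels


def _known_chain(g_all: np.ndarray, labels: np.ndarray, spec: StructureSpec):
    post = point_mass_posteriors(g_all)
    f_hat = g_all.sum(axis=1) / (2.0 * g_all.shape[1])
    p_var = np.ones(g_all.shape[0])
    if spec.variable_only:
        keep = (f_hat > 0) & (f_hat < 1)
        post, f_hat, p_var = post[keep], f_hat[keep], p_var[keep]
    cov = covariance_from_posteriors(post, f_hat, p_var)
    proj = pca(cov, labels=labels)
    model = fit_structure_model(proj.coords, labels, spec.svm_kernel, spec.svm_C)
    return proj, model


def run_structure_replicate(
    g_all: np.ndarray,
    labels: np.ndarray,
    proj_known,
    model_known,
    depth: float,
    n_per_pop: int,
    spec: StructureSpec,
    rng: np.random.Generator,
):
    """One resampling replicate of one design; returns (mislabel fraction, residual, grid)."""
    pool = spec.pool_per_pop
    idx = np.concatenate(
        [np.sort(rng.choice(pool, size=n_per_pop, replace=False)) + k * pool for k in range(3)]
    )
    g_sub = g_all[:, idx]
    counts = simulate_reads(g_sub, depth, spec.error_rate, rng, spec.error_model)
    gl = genotype_likelihoods(counts, spec.error_rate, spec.error_model)
    comp = component_site_stats(
        gl, default_f_grid(spec.f_grid_points), moments=False, dtype=np.float32
    )
    mix = fit_sfs_mixture(comp, max_iter=spec.sfs_em_iter)
    stats = mixture_site_stats(comp, mix)
    p_var = stats.p_variable
    f_hat = stats.mean_freq
    post = genotype_posteriors(gl, f_hat)
    if spec.variable_only:
        keep = (f_hat > 0) & (f_hat < 1)
        post, f_hat, p_var = post[keep], f_hat[keep], p_var[keep]
    cov = covariance_from_posteriors(post, f_hat, p_var)
    proj_seq = pca(cov, n_components=spec.n_source_pcs)
    fit = procrustes_align(proj_seq.coords, proj_known.coords[idx])
    model_seq = fit_structure_model(fit.aligned, labels[idx], spec.svm_kernel, spec.svm_C)
    grid = grid_compare(model_known, model_seq, proj_known.coords, spec.grid_size)
    return grid.mislabel_fraction, fit.residual, grid


def _level_setup(spec: StructureSpec, level: str):
    """Rebuild one level's truth, known chain and replicate seed children."""
    ss = np.random.SeedSequence(spec.seed)
    level_ss = ss.spawn(len(spec.fst_levels))
    lss = level_ss[list(spec.fst_levels).index(level)]
    truth_ss, reps_ss = lss.spawn(2)
    freq, g_all, labels = _structure_truth(spec, level, np.random.default_rng(truth_ss))
    proj_known, model_known = _known_chain(g_all, labels, spec)
    rep_children = reps_ss.spawn(len(spec.designs) * spec.n_replicates)
    return g_all, labels, proj_known, model_known, rep_children


def run_structure_experiment(spec: StructureSpec) -> pd.DataFrame:
    """Mislabel-fraction distributions per design per subdivision level.

    One row per (level, design, replicate); any single replicate — e.g. the
    median one, for decision-map export — can be re-run in isolation with
    :func:`rerun_structure_replicate`.
    """
    records = []
    for level in spec.fst_levels:
        g_all, labels, proj_known, model_known, rep_children = _level_setup(spec, level)
        k = 0
        for depth, n_per_pop in spec.designs:
            for rep in range(spec.n_replicates):
                child = rep_children[k]
                k += 1
                mis, resid, _ = run_structure_replicate(
                    g_all,
                    labels,
                    proj_known,
                    model_known,
                    depth,
                    n_per_pop,
                    spec,
                    np.random.default_rng(child),
                )
                records.append(
                    {
                        "level": level,
                        "fst_deep": spec.fst_levels[level][0],
                        "fst_shallow": spec.fst_levels[level][1],
                        "depth": depth,
                        "n_per_pop": n_per_pop,
                        "replicate": rep,
                        "mislabel_fraction": mis,
                        "procrustes_residual": resid,
                    }
                )
    return pd.DataFrame.from_records(records)


def rerun_structure_replicate(spec: StructureSpec, level: str, design_index: int, replicate: int):
    """Re-run one (level, design, replicate) cell of a structure experiment.

    Reconstructs the experiment's seed tree, so the returned
    (mislabel_fraction, procrustes_residual, GridPrediction) triple is
    identical to what :func:`run_structure_experiment` computed for that row
    — including the full grid decision maps, which the sweep itself discards.
    """
    if not 0 <= design_index < len(spec.designs):
        raise ValueError("design_index out of range")
    if not 0 <= replicate < spec.n_replicates:
        raise ValueError("replicate out of range")
    g_all, labels, proj_known, model_known, rep_children = _level_setup(spec, level)
    depth, n_per_pop = spec.designs[design_index]
    child = rep_children[design_index * spec.n_replicates + replicate]
    return run_structure_replicate(
        g_all,
        labels,
        proj_known,
        model_known,
        depth,
        n_per_pop,
        spec,
        np.random.default_rng(child),
    )


def median_replicate(mislabel_fractions: np.ndarray) -> int:
    """Index of the replicate whose value sits closest to the median (ties: lowest index)."""
    x = np.asarray(mislabel_fractions, dtype=float)
    return int(np.argmin(np.abs(x - np.median(x))))


def write_manifest(path, spec, extra: Optional[dict] = None) -> None:
    """JSON manifest with the spec, its hash, and the package version."""
    payload = dataclasses.asdict(spec)
    blob = json.dumps(payload, sort_keys=True, default=str)
    manifest = {
        "spec_type": type(spec).__name__,
        "spec": payload,
        "spec_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": payload.get("seed"),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
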