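"""Text I/O: BEAGLE genotype-likelihood files, truth tables, minimal VCF, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .likelihoods import GenotypeLikelihoods
from .sim import FreqTable, SimulationConfig, StructureConfig

__all__ = [
    "write_beagle",
    "read_beagle",
    "write_freq_table",
    "read_freq_table",
    "write_site_stats",
    "write_vcf",
    "save_config",
    "load_config",
]

PathLike = Union[str, Path]


def write_beagle(path: PathLike, gl: GenotypeLikelihoods, chrom: str = "sim") -> None:
    """Write linear-space genotype likelihoods in BEAGLE format.

    One row per site: marker id, the two allele codes (0 = ancestral/major,
    1 = derived/minor), then three likelihoods per individual, rescaled so the
    per-cell maximum is 1.
    """
    lin = gl.linear()
    n_sites, n_ind, _ = lin.shape
    header = ["marker", "allele1", "allele2"]
    for i in range(n_ind):
        header += [f"Ind{i}"] * 3
    flat = lin.reshape(n_sites, n_ind * 3)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s in range(n_sites):
            fields = [f"{chrom}_{s}", "0", "1"] + [f"{v:.6g}" for v in flat[s]]
            fh.write("\t".join(fields) + "\n")


def read_beagle(path: PathLike) -> Tuple[np.ndarray, GenotypeLikelihoods]:
    """Read a BEAGLE file; returns marker ids and log-space likelihoods."""
    df = pd.read_csv(path, sep="\t")
    markers = df.iloc[:, 0].to_numpy()
    lin = df.iloc[:, 3:].to_numpy(dtype=float)
    n_ind, rem = divmod(lin.shape[1], 3)
    if rem:
        raise ValueError("BEAGLE file has a column count not of the form 3 + 3*N")
    lin = lin.reshape(lin.shape[0], n_ind, 3)
    with np.errstate(divide="ignore"):
        logl = np.log(lin)
    return markers, GenotypeLikelihoods(logl=logl, flip=np.nan)


def write_freq_table(path: PathLike, freq: FreqTable) -> None:
    """TSV of per-site true frequencies and the population variability flag."""
    data = {
        "site": np.arange(freq.n_sites),
        "freq_ancestral": freq.freq_ancestral,
        "is_variable_pop": freq.is_variable_pop.astype(int),
    }
    if freq.freq_subpop is not None:
        for k in range(freq.freq_subpop.shape[1]):
            data[f"freq_pop{k + 1}"] = freq.freq_subpop[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_freq_table(path: PathLike) -> FreqTable:
    df = pd.read_csv(path, sep="\t")
    sub_cols = [c for c in df.columns if c.startswith("freq_pop")]
    sub = df[sub_cols].to_numpy() if sub_cols else None
    return FreqTable(freq_ancestral=df["freq_ancestral"].to_numpy(), freq_subpop=sub)


def write_site_stats(
    path: PathLike,
    f_ml: np.ndarray,
    p_variable: np.ndarray,
    mode: Optional[np.ndarray] = None,
) -> None:
    """Per-site TSV of the estimated frequency, P(variable) and, when a full
    allele-count posterior was computed, its mode."""
    data = {
        "site": np.arange(len(np.asarray(f_ml))),
        "f_ml": np.asarray(f_ml),
        "p_variable": np.asarray(p_variable),
    }
    if mode is not None:
        data["posterior_mode"] = np.asarray(mode)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_vcf(path: PathLike, g: np.ndarray, chrom: str = "sim") -> None:
    """Minimal diallelic VCF 4.2 of true genotypes (REF = ancestral A, ALT = derived C)."""
    g = np.asarray(g)
    n_sites, n_ind = g.shape
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom},length={n_sites}>\n")
        samples = "\t".join(f"Ind{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for s in range(n_sites):
            gts = "\t".join(gt_strings[int(v)] for v in g[s])
            fh.write(f"{chrom}\t{s + 1}\t{chrom}_{s}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def save_config(path: PathLike, cfg: Union[SimulationConfig, StructureConfig]) -> None:
    payload = {"type": type(cfg).__name__, "params": dataclasses.asdict(cfg)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path: PathLike) -> Union[SimulationConfig, StructureConfig]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kinds = {"SimulationConfig": SimulationConfig, "StructureConfig": StructureConfig}
    try:
        cls = kinds[payload["type"]]
    except KeyError as exc:
        raise ValueError(f"unknown config type in {path}") from exc
    return cls(**payload["params"])
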