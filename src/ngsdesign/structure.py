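"""Population structure from genotype posteriors: covariance, PCA, Procrustes, SVM grid.

The individual-by-individual covariance is built from posterior-mean genotypes
centred at twice the estimated allele frequency, with each site weighted by
its probability of being variable.  No per-site variance normalisation is
applied: dividing by f(1-f) over-weights rare variants, whose frequencies are
the least reliable at low depth.  The diagonal uses the full posterior second
moment E[g^2] rather than E[g]^2, since posterior means understate an
individual's self-covariance when the genotype is uncertain (the naive
variant is available behind a flag).

The first two principal components feed a multi-class RBF support-vector
classifier; decision maps from the known-genotype and sequencing-data models
are compared cell-by-cell on a grid spanning the known-genotype PC bounding
box, after Procrustes alignment of the sequencing-data coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import orthogonal_procrustes
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CovarianceMatrix",
    "PCAProjection",
    "GridPrediction",
    "ProcrustesResult",
    "covariance_from_posteriors",
    "pca",
    "procrustes_align",
    "fit_structure_model",
    "make_grid",
    "grid_compare",
]


@dataclass
class CovarianceMatrix:
    c: np.ndarray
    weights_sum: float

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if not np.isfinite(self.c).all():
            raise ValueError("covariance contains non-finite entries")


@dataclass
class PCAProjection:
    coords: np.ndarray  # (individuals, 2)
    eigenvalues: np.ndarray
    labels: Optional[np.ndarray] = None


@dataclass
class ProcrustesResult:
    aligned: np.ndarray
    residual: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray


@dataclass
class GridPrediction:
    grid_size: Tuple[int, int]
    labels_known: np.ndarray
    labels_seq: np.ndarray
    mislabel_fraction: float


def covariance_from_posteriors(
    posteriors: np.ndarray,
    f_ml: np.ndarray,
    p_variable: np.ndarray,
    diagonal: str = "second_moment",
) -> CovarianceMatrix:
    """Weighted covariance of posterior-mean genotypes.

    C[a, b] = sum_s w_s (E[g_as] - 2 f_s)(E[g_bs] - 2 f_s) / sum_s w_s with
    w_s = P(site s variable).  ``diagonal="second_moment"`` (default) replaces
    E[g]^2 with E[g^2] on the diagonal; ``"naive"`` keeps the plain outer
    product.
    """
    post = np.asarray(posteriors, dtype=float)  # (sites, individuals, 3)
    if post.ndim != 3 or post.shape[-1] != 3:
        raise ValueError("posteriors must have shape (sites, individuals, 3)")
    if diagonal not in ("second_moment", "naive"):
        raise ValueError(f"unknown diagonal mode {diagonal!r}")
    w = np.asarray(p_variable, dtype=float)
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("total site weight is zero; covariance undefined")
    f = np.asarray(f_ml, dtype=float)
    mean_g = post[..., 1] + 2.0 * post[..., 2]          # (sites, individuals)
    dev = mean_g - 2.0 * f[:, None]
    c = (dev * w[:, None]).T @ dev / wsum
    if diagonal == "second_moment":
        sec = post[..., 1] + 4.0 * post[..., 2]          # E[g^2]
        extra = sec - mean_g**2                          # per-cell posterior variance
        c[np.diag_indices_from(c)] += (w[:, None] * extra).sum(axis=0) / wsum
    return CovarianceMatrix(c=(c + c.T) / 2.0, weights_sum=wsum)


def pca(
    cov: CovarianceMatrix,
    labels: Optional[np.ndarray] = None,
    n_components: int = 2,
) -> PCAProjection:
    """Top eigenpairs; coordinates are eigenvectors scaled by sqrt(eigenvalue).

    Sign convention: each component's largest-magnitude coordinate is positive.
    """
    c = cov.c if isinstance(cov, CovarianceMatrix) else np.asarray(cov, dtype=float)
    if not np.isfinite(c).all():
        raise ValueError("non-finite covariance")
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1][: min(n_components, c.shape[0])]
    top_vals = vals[order]
    top_vecs = vecs[:, order]
    for k in range(top_vecs.shape[1]):
        imax = np.argmax(np.abs(top_vecs[:, k]))
        if top_vecs[imax, k] < 0:
            top_vecs[:, k] = -top_vecs[:, k]
    coords = top_vecs * np.sqrt(np.maximum(top_vals, 0.0))
    return PCAProjection(coords=coords, eigenvalues=top_vals, labels=labels)


def procrustes_align(coords_seq: np.ndarray, coords_known: np.ndarray) -> ProcrustesResult:
    """Similarity transform (translation, rotation/reflection, uniform scale)
    of ``coords_seq`` minimising the summed squared distance to ``coords_known``.

    Unlike a symmetric superimposition, the target configuration is left
    untouched so that downstream grids live on the known-genotype plane.  The
    source may carry more columns than the target (projection variant): an
    orthonormal-column map maximising the cross-covariance with the target
    then also projects, which recovers signal that eigen-decomposition noise
    has split across neighbouring components.  (With equal dimensions this
    objective coincides with the least-squares similarity alignment.)
    """
    x = np.asarray(coords_seq, dtype=float)
    y = np.asarray(coords_known, dtype=float)
    if x.shape[0] != y.shape[0] or x.shape[1] < y.shape[1]:
        raise ValueError(
            "source must have the same points as the target and at least as many columns"
        )
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if not np.linalg.norm(xc):
        raise ValueError("degenerate source configuration (all points identical)")
    if x.shape == y.shape:
        r, _ = orthogonal_procrustes(xc, yc)
    else:
        u, _, vt = np.linalg.svd(xc.T @ yc, full_matrices=False)
        r = u @ vt
    xr = xc @ r
    denom = float((xr**2).sum())
    if denom == 0:
        raise ValueError("source configuration is orthogonal to the target plane")
    scale = float((xr * yc).sum() / denom)
    aligned = scale * xr + y.mean(axis=0)
    residual = float(((aligned - y) ** 2).sum())
    return ProcrustesResult(
        aligned=aligned,
        residual=residual,
        rotation=r,
        scale=scale,
        translation=y.mean(axis=0) - scale * (x.mean(axis=0) @ r),
    )


def fit_structure_model(
    coords: np.ndarray,
    labels: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma=0.1,
) -> Pipeline:
    """Multi-class maximum-margin classifier on 2-D PC coordinates.

    Features are standardised on the training configuration (the SVM
    convention); with very small training sets this rescaling is itself a
    noticeable source of decision-map variability, as it should be.  The
    default kernel width (gamma 0.1 on standardised features) is deliberately
    smooth: decision maps are compared across replicates on a fixed grid, and
    wigglier boundaries mostly encode replicate noise.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two populations to fit a structure model")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel=kernel, C=C, gamma=gamma, random_state=0)),
        ]
    )
    model.fit(np.asarray(coords, dtype=float), labels)
    return model


def make_grid(coords: np.ndarray, grid_size: Tuple[int, int] = (50, 50)) -> np.ndarray:
    """Cell-centre coordinates equally partitioning the bounding box of ``coords``."""
    coords = np.asarray(coords, dtype=float)
    rows, cols = grid_size
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    xs = lo[0] + (np.arange(cols) + 0.5) * (hi[0] - lo[0]) / cols
    ys = lo[1] + (np.arange(rows) + 0.5) * (hi[1] - lo[1]) / rows
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def grid_compare(
    model_known: SVC,
    model_seq: SVC,
    coords_known: np.ndarray,
    grid_size: Tuple[int, int] = (50, 50),
) -> GridPrediction:
    """Fraction of grid cells where the two models disagree.

    The grid equally partitions the bounding box of the known-genotype PC
    coordinates and is shared by both models.
    """
    pts = make_grid(coords_known, grid_size)
    labels_known = model_known.predict(pts)
    labels_seq = model_seq.predict(pts)
    mis = float(np.mean(labels_known != labels_seq))
    return GridPrediction(
        grid_size=tuple(grid_size),
        labels_known=labels_known,
        labels_seq=labels_seq,
        mislabel_fraction=mis,
    )
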