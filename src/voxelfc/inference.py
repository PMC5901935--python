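"""Voxel-wise GLM inference with FDR and permutation cluster-level FWE.

First-level maps (one scalar per voxel per subject) are compared across
groups with a covariate-adjusted linear model, thresholded voxel-wise by
Benjamini-Hochberg FDR, grouped into 26-connected clusters split by effect
sign, and assigned family-wise-error-corrected p-values from a
Freedman-Lane permutation null of the maximum cluster extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "Cluster",
    "build_design",
    "fit_voxelwise_glm",
    "voxelwise_regression",
    "fdr_bh",
    "form_clusters",
    "cluster_fwe_permutation",
    "connectivity_strength_r2",
]

#: 26-connectivity structuring element for 3D cluster formation
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StatMap:
    """Per-voxel GLM results for one contrast."""

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    contrast: str
    df: int


@dataclass
class Cluster:
    """A 26-connected set of significant voxels with one effect direction."""

    label: int
    k: int
    peak_ijk: Tuple[int, int, int]
    peak_mm: Tuple[float, float, float]
    direction: str                      # "increase" | "decrease"
    peak_t: float
    p_fdr_voxelpeak: float
    member_voxels: np.ndarray           # (k, 3) grid indices
    p_fwe_cluster: Optional[float] = None
    mask: np.ndarray = field(default=None, repr=False)


def build_design(covariates: pd.DataFrame,
                 columns: Sequence[str] = ("age", "gender", "bdi")) -> pd.DataFrame:
    """Design matrix: intercept, patient indicator, then covariate columns.

    ``gender`` is encoded F=0 / M=1; ``group`` as patient=1 / control=0.
    """
    X = pd.DataFrame(index=covariates.index)
    X["intercept"] = 1.0
    X["group"] = (covariates["group"] == "patient").astype(float)
    for col in columns:
        if col == "gender":
            X["gender"] = (covariates["gender"] == "M").astype(float)
        else:
            X[col] = covariates[col].astype(float)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name every column whose removal restores full rank
        bad = [c for i, c in enumerate(X.columns)
               if np.linalg.matrix_rank(np.delete(A, i, axis=1)) == rank]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _glm_t(Y: np.ndarray, X: np.ndarray, c_idx: int,
           xtx_inv: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized per-voxel OLS t-test of one coefficient.

    Y is (n_subjects, n_voxels); returns (beta_c, t, p, df).
    """
    n, p = X.shape
    if xtx_inv is None:
        xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)                     # p x voxels
    resid = Y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[c_idx, c_idx], 1e-300))
    t = beta[c_idx] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return beta[c_idx], t, pvals, df


def fit_voxelwise_glm(maps: np.ndarray, design: pd.DataFrame,
                      contrast: str) -> StatMap:
    """OLS fit at every voxel; t/p for the named design column.

    ``maps`` has one row per design row (subjects) and one column per voxel.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != len(design):
        raise ValueError("maps must be (n_subjects, n_voxels) matching design rows")
    if contrast not in design.columns:
        raise ValueError(f"contrast {contrast!r} not a design column")
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    c_idx = list(design.columns).index(contrast)
    beta, t, p, df = _glm_t(maps, X, c_idx)
    _, q = fdr_bh(p)
    return StatMap(beta=beta, t=t, p=p, q=q, contrast=contrast, df=df)


def voxelwise_regression(maps: np.ndarray, outcome: np.ndarray,
                         covariates: Optional[np.ndarray] = None) -> StatMap:
    """Per-voxel model ``outcome ~ intercept + map_value (+ covariates)``.

    Uses Frisch-Waugh-Lovell partialling so the map coefficient's t/p equal
    the per-voxel full OLS fit. Returns stats for the map-value coefficient.
    """
    maps = np.asarray(maps, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, n_vox = maps.shape
    if y.shape != (n,):
        raise ValueError("outcome length must match number of subjects")
    if np.ptp(y) < 1e-12:
        raise ValueError("outcome is constant")
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([Z, C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariates are collinear with the intercept")
    # residualize outcome and maps against nuisance block
    Qz, _ = np.linalg.qr(Z)
    y_r = y - Qz @ (Qz.T @ y)
    M_r = maps - Qz @ (Qz.T @ maps)
    df = n - Z.shape[1] - 1
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    sxx = (M_r ** 2).sum(axis=0)
    ok = sxx > 1e-24
    beta = np.zeros(n_vox)
    tvals = np.zeros(n_vox)
    sxy = M_r.T @ y_r
    beta[ok] = sxy[ok] / sxx[ok]
    resid2 = (y_r ** 2).sum() - beta * sxy
    sigma2 = np.maximum(resid2, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / np.where(ok, sxx, np.inf))
        tvals[ok] = beta[ok] / np.maximum(se[ok], 1e-300)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals[~ok] = 1.0
    _, q = fdr_bh(pvals)
    return StatMap(beta=beta, t=tvals, p=pvals, q=q, contrast="map_value", df=df)


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def form_clusters(sig_mask: np.ndarray, t_map: np.ndarray,
                  affine: np.ndarray,
                  q_map: Optional[np.ndarray] = None) -> List["Cluster"]:
    """26-connected components of a significance mask, split by t sign.

    ``sig_mask`` and ``t_map`` are 3D volumes on the same grid; peak is the
    voxel of maximum |t|, reported in mm via the affine.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    t_map = np.asarray(t_map, dtype=float)
    if sig_mask.shape != t_map.shape:
        raise ValueError("sig_mask and t_map grids differ")
    clusters: List[Cluster] = []
    next_label = 1
    for direction, part in (("increase", sig_mask & (t_map > 0)),
                            ("decrease", sig_mask & (t_map < 0))):
        labels, n_comp = ndimage.label(part, structure=_STRUCT26)
        for comp in range(1, n_comp + 1):
            members = np.array(np.nonzero(labels == comp)).T
            tvals = t_map[tuple(members.T)]
            peak_row = int(np.argmax(np.abs(tvals)))
            peak_ijk = tuple(int(v) for v in members[peak_row])
            peak_mm = tuple((np.asarray(affine) @ np.append(members[peak_row], 1.0))[:3])
            q_peak = float(q_map[peak_ijk]) if q_map is not None else np.nan
            cmask = labels == comp
            clusters.append(Cluster(
                label=next_label,
                k=members.shape[0],
                peak_ijk=peak_ijk,
                peak_mm=tuple(float(v) for v in peak_mm),
                direction=direction,
                peak_t=float(tvals[peak_row]),
                p_fdr_voxelpeak=q_peak,
                member_voxels=members,
                mask=cmask,
            ))
            next_label += 1
    clusters.sort(key=lambda c: (-c.k, c.peak_mm[0]))
    for i, c in enumerate(clusters, start=1):
        c.label = i
    return clusters


def _embed(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vol = np.zeros(mask.shape, dtype=values.dtype)
    vol[mask] = values
    return vol


def _max_cluster_size(reject: np.ndarray, t: np.ndarray, mask: np.ndarray) -> int:
    """Largest 26-connected cluster extent over both effect directions."""
    if not reject.any():
        return 0
    sig3d = _embed(reject, mask)
    t3d = _embed(t, mask)
    best = 0
    for part in (sig3d & (t3d > 0), sig3d & (t3d < 0)):
        if not part.any():
            continue
        labels, n_comp = ndimage.label(part, structure=_STRUCT26)
        if n_comp:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def cluster_fwe_permutation(maps: np.ndarray, design: pd.DataFrame,
                            contrast: str, n_perm: int,
                            cluster_forming_alpha: float = 0.05,
                            mask: Optional[np.ndarray] = None,
                            affine: Optional[np.ndarray] = None,
                            rng: Optional[np.random.Generator] = None,
                            ) -> Tuple[List[Cluster], StatMap]:
    """Observed FDR clusters with Freedman-Lane permutation cluster FWE.

    Observed clusters are formed from the BH-significant voxels at
    ``cluster_forming_alpha``.  The null distribution of the maximum cluster
    extent is built by permuting reduced-model residuals, refitting the full
    model and re-forming clusters; ``p_fwe = (1 + #{null max-k >= k}) /
    (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable tail")
    maps = np.asarray(maps, dtype=float)
    if mask is None:
        raise ValueError("a 3D mask is required to form clusters")
    if affine is None:
        affine = np.eye(4)
    if rng is None:
        rng = np.random.default_rng(0)

    stat = fit_voxelwise_glm(maps, design, contrast)
    reject, q = fdr_bh(stat.p, alpha=cluster_forming_alpha)
    clusters = form_clusters(_embed(reject, mask), _embed(stat.t, mask),
                             affine, q_map=_embed(q, mask))

    # Freedman-Lane: permute residuals of the reduced (nuisance-only) model
    X = design.to_numpy(dtype=float)
    c_idx = list(design.columns).index(contrast)
    Xr = np.delete(X, c_idx, axis=1)
    Qr, _ = np.linalg.qr(Xr)
    fitted = Qr @ (Qr.T @ maps)
    resid = maps - fitted
    xtx_inv = np.linalg.inv(X.T @ X)
    n = maps.shape[0]

    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = fitted + resid[perm]
        _, tb, pb, _ = _glm_t(Yb, X, c_idx, xtx_inv=xtx_inv)
        rej_b, _ = fdr_bh(pb, alpha=cluster_forming_alpha)
        null_max[b] = _max_cluster_size(rej_b, tb, mask)

    for c in clusters:
        c.p_fwe_cluster = float((1 + np.sum(null_max >= c.k)) / (1 + n_perm))
    return clusters, stat


def connectivity_strength_r2(strengths: np.ndarray,
                             outcome: np.ndarray) -> Tuple[float, float, np.ndarray]:
    """Simple regression of per-subject connectivity strength on an outcome.

    Returns ``(r_squared, slope, strengths)`` where r_squared is the squared
    Pearson correlation and slope is d(strength)/d(outcome).
    """
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s.size != y.size or s.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(s) < 1e-12 or np.ptp(y) < 1e-12:
        raise ValueError("constant input")
    res = stats.linregress(y, s)
    return float(res.rvalue ** 2), float(res.slope), s
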