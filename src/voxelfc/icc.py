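"""Intrinsic connectivity contrast (ICC): voxel-to-brain connectivity maps.

For every masked voxel *i* the raw statistic is the mean, over all other
masked voxels *j*, of ``r_ij**2 * u(r_ij)`` where ``r_ij`` is the Pearson
correlation of the two time series and ``u`` is the unit step keeping only
positive correlations.  No correlation threshold is applied.  Maps are
z-normalized over the brain mask for group statistics.

The computation streams over row chunks of the standardized data matrix and
never materializes the full voxel-by-voxel correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BoldSeries

__all__ = ["IccMap", "compute_icc", "normalize_icc", "icc_map"]


@dataclass
class IccMap:
    """Raw and z-normalized voxel-to-brain connectivity of one subject."""

    raw: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    affine: np.ndarray


def _standardize_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit L2 norm; zero-variance rows zeroed.

    With this scaling ``X @ X.T`` is the Pearson correlation matrix, and a
    zero-variance voxel contributes r = 0 to every pair.
    """
    X = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 1e-12
    X[ok] /= norms[ok, None]
    X[~ok] = 0.0
    return X, ok


def compute_icc(series: BoldSeries, chunk_size: int = 256) -> np.ndarray:
    """Raw ICC per masked voxel: mean of squared positive correlations.

    ``raw_i = (1/(N-1)) * sum_{j != i} r_ij^2 * [r_ij > 0]`` with N the
    number of masked voxels.  Zero-variance voxels receive 0 and contribute
    r = 0 to all pairs.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    X, ok = _standardize_rows(series.data)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 masked voxels")
    if not ok.any():
        warnings.warn("all voxels are constant; ICC map is all zero")
        return np.zeros(n)
    raw = np.zeros(n)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        R = X[start:stop] @ X.T                      # chunk x N correlations
        np.clip(R, -1.0, 1.0, out=R)
        contrib = np.where(R > 0, R * R, 0.0)
        # remove the self term r_ii = 1 (only defined for non-constant rows)
        idx = np.arange(start, stop)
        contrib[np.arange(stop - start), idx] = 0.0
        raw[start:stop] = contrib.sum(axis=1)
    raw /= (n - 1)
    raw[~ok] = 0.0
    return raw


def normalize_icc(raw: np.ndarray, mask_values: np.ndarray | None = None) -> np.ndarray:
    """Z-score a raw map over the brain mask (zero mean, unit variance).

    ``mask_values`` may restrict the statistics to a boolean subset of
    entries; by default all entries (the masked voxels) are used.
    """
    raw = np.asarray(raw, dtype=float)
    sel = np.ones(raw.shape, dtype=bool) if mask_values is None else np.asarray(mask_values, dtype=bool)
    vals = raw[sel]
    if vals.size < 2:
        raise ValueError("need at least 2 masked voxels to normalize")
    mu = vals.mean()
    sd = vals.std()
    if sd < 1e-15:
        raise ValueError("degenerate ICC map: zero variance over mask")
    return (raw - mu) / sd


def icc_map(series: BoldSeries, chunk_size: int = 256) -> IccMap:
    """Convenience wrapper: raw + z-normalized map with grid metadata."""
    raw = compute_icc(series, chunk_size=chunk_size)
    return IccMap(raw=raw, z=normalize_icc(raw), mask=series.mask,
                  affine=series.affine)
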