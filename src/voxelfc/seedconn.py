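"""Seed-based connectivity: Fisher-z correlation maps from cluster seeds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoldSeries

__all__ = ["SeedMap", "extract_seed_timeseries", "seed_correlation_map"]

#: correlations are clipped to this magnitude before atanh to keep maps finite
R_CLIP = 1.0 - 1e-7


@dataclass
class SeedMap:
    """Per-voxel Fisher-z map of correlation with a seed's mean time series."""

    z: np.ndarray
    seed_mask: np.ndarray
    subject_id: str


def extract_seed_timeseries(series: BoldSeries, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over the seed's masked voxels."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != series.mask.shape:
        raise ValueError("seed_mask grid does not match series mask")
    rows = np.nonzero(seed_mask[tuple(series.voxel_coords.T)])[0]
    if rows.size == 0:
        raise ValueError("seed mask selects no voxels inside the brain mask")
    return series.data[rows, :].mean(axis=0)


def seed_correlation_map(series: BoldSeries, seed_ts: np.ndarray,
                         seed_mask: np.ndarray | None = None,
                         subject_id: str = "?") -> SeedMap:
    """Fisher-z of the Pearson correlation between every voxel and the seed.

    Zero-variance voxels get z = 0; |r| is clipped at ``R_CLIP`` before the
    atanh transform. Seed voxels are retained in the map.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.shape != (series.n_timepoints,):
        raise ValueError("seed_ts length must equal n_timepoints")
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm < 1e-12:
        raise ValueError("seed time series is constant")
    s /= s_norm
    X = series.data - series.data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 1e-12
    r = np.zeros(series.n_voxels)
    r[ok] = (X[ok] @ s) / norms[ok]
    np.clip(r, -R_CLIP, R_CLIP, out=r)
    z = np.arctanh(r)
    z[~ok] = 0.0
    if seed_mask is None:
        seed_mask = np.zeros(series.mask.shape, dtype=bool)
    return SeedMap(z=z, seed_mask=np.asarray(seed_mask, dtype=bool),
                   subject_id=subject_id)
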