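"""Per-subject temporal preprocessing and the motion-exclusion gate.

Stage order is fixed: motion QC (excluded subjects yield an
:class:`ExclusionRecord`, not data) -> initial volume discard -> linear
detrend -> zero-phase band-pass -> PCA-based nuisance regression of a noise
ROI (CompCor-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import signal

from .core import BoldSeries

__all__ = [
    "PreprocConfig",
    "ExclusionRecord",
    "discard_initial_volumes",
    "motion_qc",
    "detrend_linear",
    "bandpass",
    "compcor",
    "run_preprocess",
]


@dataclass
class PreprocConfig:
    """Temporal preprocessing parameters.

    Motion limits are strict bounds: a run is excluded only when a parameter
    *exceeds* the limit. Band edges must satisfy 0 <= low < high < Nyquist.
    """

    n_discard: int = 3
    band_low: float = 0.01
    band_high: float = 0.08
    motion_trans_limit: float = 1.0   # mm
    motion_rot_limit: float = 1.0     # degrees
    n_compcor: int = 5

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if not 0 <= self.band_low < self.band_high:
            raise ValueError("need 0 <= band_low < band_high")
        if self.motion_trans_limit <= 0 or self.motion_rot_limit <= 0:
            raise ValueError("motion limits must be positive")
        if self.n_compcor < 0:
            raise ValueError("n_compcor must be >= 0")


@dataclass
class ExclusionRecord:
    """Outcome of a failed motion QC gate."""

    subject_id: str
    reason: str
    volume_index: int


def discard_initial_volumes(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` timepoints (steady-state magnetization)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_timepoints} timepoints")
    if n_discard == 0:
        return series.with_data(series.data.copy())
    return series.with_data(series.data[:, n_discard:])


def motion_qc(motion: np.ndarray, trans_limit: float = 1.0,
              rot_limit: float = 1.0) -> Tuple[bool, Optional[int]]:
    """Check a 6-parameter motion trace against exclusion limits.

    Returns ``(passed, offending_volume)``. A volume fails when any
    translation magnitude strictly exceeds ``trans_limit`` (mm) or any
    rotation magnitude strictly exceeds ``rot_limit`` (degrees); values at
    the boundary pass.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] == 0:
        raise ValueError("motion trace must be a nonempty (n_volumes, 6) array")
    if np.isnan(motion).any():
        raise ValueError("motion trace contains NaN")
    bad = (np.abs(motion[:, :3]) > trans_limit).any(axis=1) | \
          (np.abs(motion[:, 3:]) > rot_limit).any(axis=1)
    if bad.any():
        return False, int(np.argmax(bad))
    return True, None


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Subtract each voxel's least-squares line over the time index."""
    if series.n_timepoints < 3:
        raise ValueError("detrend needs at least 3 timepoints")
    out = signal.detrend(series.data, axis=1, type="linear")
    return series.with_data(out)


def bandpass(series: BoldSeries, low: float, high: float) -> BoldSeries:
    """Zero-phase 2nd-order Butterworth band-pass along time.

    Each voxel is demeaned first (DC is below any admissible band) and the
    forward-backward pass uses Gustafsson initial conditions, which keeps
    edge transients from leaking stop-band power on short runs.
    """
    nyq = 0.5 / series.tr
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"band_high {high} Hz must be below Nyquist {nyq} Hz")
    b, a = signal.butter(2, [low / nyq, high / nyq], btype="bandpass")
    demeaned = series.data - series.data.mean(axis=1, keepdims=True)
    out = signal.filtfilt(b, a, demeaned, axis=1, method="gust")
    return series.with_data(out)


def compcor(series: BoldSeries, noise_mask: np.ndarray,
            n_components: int) -> BoldSeries:
    """Regress principal components of a noise ROI out of every voxel.

    Components are the top left singular vectors of the time x noise-voxel
    matrix after per-voxel standardization; they are removed (together with
    an intercept) from all series by OLS. ``n_components == 0`` is the
    identity.
    """
    if n_components == 0:
        return series.with_data(series.data.copy())
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if noise_mask.shape != series.mask.shape:
        raise ValueError("noise_mask grid does not match series mask")
    if not noise_mask.any():
        raise ValueError("noise_mask is empty")
    if not noise_mask[series.mask].any() and not (noise_mask & series.mask).any():
        raise ValueError("noise_mask lies outside the brain mask")

    rows = np.nonzero(noise_mask[tuple(series.voxel_coords.T)])[0]
    if rows.size == 0:
        raise ValueError("noise_mask selects no masked voxels")
    noise = series.data[rows, :].T.copy()           # time x voxels
    noise -= noise.mean(axis=0)
    sd = noise.std(axis=0)
    keep = sd > 1e-12
    noise = noise[:, keep] / sd[keep]
    if noise.shape[1] == 0:
        raise ValueError("noise ROI has no non-constant voxels")
    rank = np.linalg.matrix_rank(noise)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds noise-matrix rank {rank}")
    u, _, _ = np.linalg.svd(noise, full_matrices=False)
    comps = u[:, :n_components]                     # time x k, orthonormal

    X = np.column_stack([np.ones(series.n_timepoints), comps])
    Y = series.data.T                               # time x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return series.with_data(resid.T)


def run_preprocess(series: BoldSeries, motion: np.ndarray,
                   config: PreprocConfig,
                   noise_mask: Optional[np.ndarray] = None,
                   subject_id: str = "?") -> Union[BoldSeries, ExclusionRecord]:
    """Full temporal chain with the motion gate in front.

    Excluded subjects produce an :class:`ExclusionRecord`; included subjects
    pass through discard -> detrend -> band-pass -> CompCor (the last only
    when a ``noise_mask`` is supplied and ``config.n_compcor > 0``).
    """
    nyq = 0.5 / series.tr
    if config.band_high >= nyq:
        raise ValueError("band_high must be below Nyquist for this tr")
    passed, vol = motion_qc(motion, config.motion_trans_limit,
                            config.motion_rot_limit)
    if not passed:
        return ExclusionRecord(
            subject_id=subject_id,
            reason="motion limit exceeded",
            volume_index=vol,
        )
    out = discard_initial_volumes(series, config.n_discard)
    out = detrend_linear(out)
    out = bandpass(out, config.band_low, config.band_high)
    if noise_mask is not None and config.n_compcor > 0:
        out = compcor(out, noise_mask, config.n_compcor)
    return out
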