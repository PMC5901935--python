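"""Synthetic BOLD cohort generator.

Builds cohorts of subjects (covariate records plus masked 4D BOLD data) with
planted network structure on a small common grid:

* a set of deterministic geometric network templates (DMN, SMA, bilateral
  VISUAL and TEMPORAL blocks, plus a physiological NOISE_ROI);
* band-limited latent time courses per network, with the DMN and SMA latents
  mixed to an exact empirical correlation that is an affine function of each
  patient's age of onset (controls sit at the baseline coupling);
* an occipital gain multiplier boosting the shared VISUAL signal in patients;
* linear drift, a high-frequency sinusoidal physiological confound
  concentrated in the NOISE_ROI, and white noise.

Everything is seeded; per-subject random streams are derived from
``(rng_seed, subject_id)`` so cohorts are reproducible and subjects are
statistically independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .core import BoldSeries, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkTemplate",
    "SimConfig",
    "make_brain_mask",
    "make_network_templates",
    "simulate_cohort",
    "simulate_subject",
    "simulate_motion_trace",
    "cohort_to_frame",
    "write_cohort_csv",
    "ONSET_REF",
]

#: Reference age of onset (upper end of the 18-45 recruitment window); a
#: younger onset moves the planted DMN-SMA coupling further above baseline.
ONSET_REF = 45.0

_SIGNAL_NETWORKS = ("DMN", "SMA", "VISUAL", "TEMPORAL")

# Fractional (lo, hi) bounds per axis; each template is a union of axis-aligned
# blocks intersected with the brain mask.  y runs posterior -> anterior,
# z inferior -> superior.
_TEMPLATE_BLOCKS: Dict[str, List[Tuple[Tuple[float, float], ...]]] = {
    "VISUAL": [
        ((0.08, 0.40), (0.03, 0.22), (0.30, 0.70)),
        ((0.60, 0.92), (0.03, 0.22), (0.30, 0.70)),
    ],
    "TEMPORAL": [
        ((0.03, 0.28), (0.30, 0.55), (0.05, 0.32)),
        ((0.72, 0.97), (0.30, 0.55), (0.05, 0.32)),
    ],
    "DMN": [
        ((0.38, 0.62), (0.72, 0.95), (0.35, 0.65)),   # medial prefrontal
        ((0.38, 0.62), (0.26, 0.44), (0.58, 0.85)),   # precuneus-like
    ],
    "SMA": [
        ((0.38, 0.62), (0.48, 0.68), (0.72, 0.95)),
    ],
    "NOISE_ROI": [
        ((0.40, 0.60), (0.46, 0.60), (0.06, 0.34)),
    ],
}

_MIN_TEMPLATE_VOXELS = {"NOISE_ROI": 12}
_MIN_SIGNAL_VOXELS = 8


@dataclass
class NetworkTemplate:
    """A named set of voxels carrying one latent network signal."""

    name: str
    mask: np.ndarray
    amplitude: float = 1.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    rng_seed: int
    grid_shape: Tuple[int, int, int] = (18, 18, 12)
    n_patients: int = 17
    n_controls: int = 17
    n_timepoints: int = 178
    tr: float = 2.5
    baseline_coupling: float = -0.4
    coupling_slope: float = 0.0045
    occipital_gain: float = 2.0
    noise_sd: float = 1.0
    drift_amp: float = 0.5
    physio_amp: float = 0.6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("n_patients and n_controls must be positive")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not -1.0 < self.baseline_coupling < 1.0:
            raise ValueError("baseline_coupling must lie in (-1, 1)")
        for name in ("noise_sd", "drift_amp", "physio_amp", "amplitude",
                     "occipital_gain", "coupling_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def make_brain_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Deterministic superellipsoid brain mask inscribed in the grid."""
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 3:
        raise ValueError("grid_shape must be 3 integers, each >= 3")
    idx = np.indices(grid_shape, dtype=float)
    centers = [(s - 1) / 2.0 for s in grid_shape]
    semi = [(s - 1) / 2.0 for s in grid_shape]
    r = sum((np.abs(idx[a] - centers[a]) / semi[a]) ** 4 for a in range(3))
    return r <= 1.0


def _block_mask(grid_shape: Tuple[int, int, int],
                bounds: Tuple[Tuple[float, float], ...]) -> np.ndarray:
    mask = np.zeros(grid_shape, dtype=bool)
    slices = []
    for size, (lo, hi) in zip(grid_shape, bounds):
        a = int(np.floor(lo * size))
        b = int(np.ceil(hi * size))
        slices.append(slice(max(a, 0), min(b, size)))
    mask[tuple(slices)] = True
    return mask


def make_network_templates(grid_shape: Sequence[int],
                           amplitude: float = 1.0) -> List[NetworkTemplate]:
    """Deterministic geometric network templates inside the brain mask.

    Returns the five templates (DMN, SMA, VISUAL, TEMPORAL, NOISE_ROI).
    Signal templates are pairwise disjoint and the NOISE_ROI is disjoint
    from all of them.  Raises ``ValueError`` naming the first template the
    grid is too small for.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    first = next(iter(_TEMPLATE_BLOCKS))
    if len(grid_shape) != 3 or min(grid_shape) < 3:
        raise ValueError(
            f"grid {grid_shape} too small for template {first}: "
            "need 3 dimensions, each >= 3")
    brain = make_brain_mask(grid_shape)
    templates: List[NetworkTemplate] = []
    for name, blocks in _TEMPLATE_BLOCKS.items():
        mask = np.zeros(grid_shape, dtype=bool)
        for bounds in blocks:
            mask |= _block_mask(grid_shape, bounds)
        mask &= brain
        needed = _MIN_TEMPLATE_VOXELS.get(name, _MIN_SIGNAL_VOXELS)
        if mask.sum() < needed:
            raise ValueError(
                f"grid {grid_shape} too small for template {name}: "
                f"{int(mask.sum())} voxels < {needed}"
            )
        templates.append(NetworkTemplate(name=name, mask=mask, amplitude=amplitude))
    # construction invariant: no voxel belongs to two templates
    total = np.zeros(grid_shape, dtype=int)
    for t in templates:
        total += t.mask
    if (total > 1).any():
        raise AssertionError("template masks overlap")
    return templates


def simulate_motion_trace(rng: np.random.Generator, n_volumes: int,
                          scale: float = 0.02, bound: float = 0.6) -> np.ndarray:
    """Bounded random-walk motion trace (3 translations mm, 3 rotations deg)."""
    steps = rng.normal(0.0, scale, size=(n_volumes, 6))
    trace = np.cumsum(steps, axis=0)
    return np.clip(trace, -bound, bound)


def _draw_scale(rng: np.random.Generator, mean: float, sd: float,
                lo: int, hi: int, size: int) -> np.ndarray:
    vals = np.rint(rng.normal(mean, sd, size=size))
    return np.clip(vals, lo, hi).astype(int)


def simulate_cohort(config: SimConfig) -> List[SubjectRecord]:
    """Draw per-subject covariate records for a patients+controls cohort.

    Patient scale scores are drawn from normal distributions (onset
    28.82/10.15, PSQI 15/2.35, ISI 18.45/5.16, BDI 8/4.52; control BDI
    6/3.86), rounded and clipped to each instrument's legal range.  Ages are
    invented (the source cohort reported neither per-group age nor gender
    composition); gender alternates within group so small designs stay
    full rank.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    records: List[SubjectRecord] = []

    n_p, n_c = config.n_patients, config.n_controls
    p_age = np.clip(rng.normal(36.0, 5.0, n_p), 20.0, 45.0)
    p_onset = np.clip(rng.normal(28.82, 10.15, n_p), 12.0, p_age)
    p_psqi = _draw_scale(rng, 15.0, 2.35, 0, 21, n_p)
    p_isi = _draw_scale(rng, 18.45, 5.16, 0, 28, n_p)
    p_bdi = _draw_scale(rng, 8.0, 4.52, 0, 63, n_p)
    for i in range(n_p):
        records.append(SubjectRecord(
            subject_id=f"pat{i + 1:03d}",
            group="patient",
            age=round(float(p_age[i]), 2),
            gender="F" if i % 2 == 0 else "M",
            bdi=int(p_bdi[i]),
            psqi=int(p_psqi[i]),
            isi=int(p_isi[i]),
            age_of_onset=round(float(p_onset[i]), 2),
            duration=round(float(p_age[i]), 2) - round(float(p_onset[i]), 2),
            motion=simulate_motion_trace(rng, config.n_timepoints),
        ))

    c_age = np.clip(rng.normal(36.0, 5.0, n_c), 20.0, 45.0)
    c_psqi = _draw_scale(rng, 3.0, 1.5, 0, 5, n_c)
    c_isi = _draw_scale(rng, 3.0, 2.0, 0, 7, n_c)
    c_bdi = _draw_scale(rng, 6.0, 3.86, 0, 63, n_c)
    for i in range(n_c):
        records.append(SubjectRecord(
            subject_id=f"ctl{i + 1:03d}",
            group="control",
            age=round(float(c_age[i]), 2),
            gender="F" if i % 2 == 0 else "M",
            bdi=int(c_bdi[i]),
            psqi=int(c_psqi[i]),
            isi=int(c_isi[i]),
            motion=simulate_motion_trace(rng, config.n_timepoints),
        ))
    return records


def _subject_rng(rng_seed: int, subject_id: str) -> np.random.Generator:
    """Independent stream per (seed, subject_id)."""
    key = [rng_seed] + list(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(key))


def _bandlimited_noise(rng: np.random.Generator, n: int, tr: float,
                       low: float = 0.02, high: float = 0.06) -> np.ndarray:
    """Unit-variance, zero-mean band-limited Gaussian time course.

    The band sits strictly inside the default 0.01-0.08 Hz preprocessing
    pass-band so the temporal chain is close to the identity on latents.
    """
    x = rng.standard_normal(n)
    nyq = 0.5 / tr
    b, a = signal.butter(2, [low / nyq, high / nyq], btype="bandpass")
    y = signal.filtfilt(b, a, x)
    y = y - y.mean()
    sd = y.std()
    if sd < 1e-12:  # pragma: no cover - n would have to be tiny
        raise ValueError("degenerate band-limited draw")
    return y / sd


def planted_coupling(record: SubjectRecord, config: SimConfig) -> float:
    """Target DMN-SMA latent correlation for one subject (clipped)."""
    if record.group == "patient":
        if record.age_of_onset is None:
            raise ValueError(f"{record.subject_id}: patient without age_of_onset")
        rho = config.baseline_coupling + config.coupling_slope * (
            ONSET_REF - record.age_of_onset)
    else:
        rho = config.baseline_coupling
    if not -1.0 < rho < 1.0:
        logger.warning(
            "subject %s: requested latent coupling %.3f outside (-1, 1); clipping",
            record.subject_id, rho)
    return float(np.clip(rho, -0.95, 0.95))


def simulate_subject(record: SubjectRecord,
                     templates: Sequence[NetworkTemplate],
                     config: SimConfig,
                     brain_mask: Optional[np.ndarray] = None) -> BoldSeries:
    """Generate one subject's masked BOLD series with planted structure.

    The DMN and SMA latents are mixed by Gram-Schmidt so their *empirical*
    correlation equals the planted coupling exactly; the coupling is stored
    (with all latents) in ``series.latents``.
    """
    by_name = {t.name: t for t in templates}
    for required in (*_SIGNAL_NETWORKS, "NOISE_ROI"):
        if required not in by_name:
            raise ValueError(f"missing template {required}")
    grid_shape = by_name["DMN"].mask.shape
    if brain_mask is None:
        brain_mask = make_brain_mask(grid_shape)
    rng = _subject_rng(config.rng_seed, record.subject_id)
    T = config.n_timepoints

    # latent time courses; DMN/SMA mixed to an exact empirical correlation
    dmn = _bandlimited_noise(rng, T, config.tr)
    raw2 = _bandlimited_noise(rng, T, config.tr)
    rho = planted_coupling(record, config)
    d_unit = dmn / np.linalg.norm(dmn)
    resid = raw2 - (raw2 @ d_unit) * d_unit
    resid -= resid.mean()
    resid /= np.linalg.norm(resid)
    sma = rho * d_unit + np.sqrt(1.0 - rho ** 2) * resid
    sma = (sma - sma.mean()) / sma.std()
    latents = {
        "DMN": dmn,
        "SMA": sma,
        "VISUAL": _bandlimited_noise(rng, T, config.tr),
        "TEMPORAL": _bandlimited_noise(rng, T, config.tr),
        "coupling": rho,
    }

    coords = np.array(np.nonzero(brain_mask)).T
    n_vox = coords.shape[0]
    data = np.zeros((n_vox, T))
    flat_rows = np.full(brain_mask.shape, -1, dtype=int)
    flat_rows[brain_mask] = np.arange(n_vox)

    for name in _SIGNAL_NETWORKS:
        tpl = by_name[name]
        rows = flat_rows[tpl.mask & brain_mask]
        rows = rows[rows >= 0]
        gain = tpl.amplitude
        if name == "VISUAL" and record.group == "patient":
            gain *= np.sqrt(config.occipital_gain)
        data[rows] += gain * latents[name]

    # linear drift with a random per-voxel slope
    if config.drift_amp > 0:
        t_lin = np.linspace(-0.5, 0.5, T)
        slopes = rng.normal(0.0, config.drift_amp, size=n_vox)
        data += slopes[:, None] * t_lin[None, :]

    # high-frequency physiological confound: strong in the NOISE_ROI,
    # leaking weakly into the rest of the brain
    if config.physio_amp > 0:
        t_sec = np.arange(T) * config.tr
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        c1 = np.sin(2 * np.pi * 0.15 * t_sec + phase1)
        c2 = np.sin(2 * np.pi * 0.12 * t_sec + phase2)
        noise_rows = flat_rows[by_name["NOISE_ROI"].mask & brain_mask]
        noise_rows = noise_rows[noise_rows >= 0]
        load1 = rng.uniform(0.15, 0.45, size=n_vox)
        load2 = rng.uniform(0.15, 0.45, size=n_vox)
        load1[noise_rows] = rng.uniform(0.8, 1.2, size=noise_rows.size)
        load2[noise_rows] = rng.uniform(0.8, 1.2, size=noise_rows.size)
        data += config.physio_amp * (np.outer(load1, c1) + np.outer(load2, c2))

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = -1.5 * (np.array(grid_shape) - 1)
    return BoldSeries(
        data=data,
        tr=config.tr,
        mask=brain_mask,
        affine=affine,
        voxel_coords=coords,
        latents=latents,
    )


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Covariate table with one row per subject."""
    return pd.DataFrame([
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "gender": r.gender,
            "bdi": r.bdi,
            "psqi": r.psqi,
            "isi": r.isi,
            "age_of_onset": r.age_of_onset,
            "duration": r.duration,
        }
        for r in records
    ])


def write_cohort_csv(records: Sequence[SubjectRecord], path: str) -> None:
    cohort_to_frame(records).to_csv(path, index=False)
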