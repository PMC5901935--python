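"""End-to-end two-step connectivity analysis.

Step one compares voxel-to-brain connectivity (ICC z-maps) across groups
and regresses them on clinical scores, with FDR voxel thresholding and
permutation cluster-level FWE.  Step two turns every surviving cluster into
a seed, builds per-subject seed correlation maps, and re-runs the same
model at the same thresholds.  A cohort can be fully synthetic (generated
in-process) or loaded from NIfTI files born in a common space.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import BoldSeries, SubjectRecord
from .icc import compute_icc, normalize_icc
from .inference import (Cluster, build_design, cluster_fwe_permutation,
                        connectivity_strength_r2)
from .preprocess import ExclusionRecord, PreprocConfig, run_preprocess
from .seedconn import extract_seed_timeseries, seed_correlation_map
from .synthetic import (NetworkTemplate, SimConfig, make_brain_mask,
                        make_network_templates, simulate_cohort,
                        simulate_subject)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_two_step",
    "write_cluster_table",
    "clusters_to_frame",
    "load_pipeline_config",
]

_REGRESSION_OUTCOMES = ("age_of_onset", "duration", "isi")


@dataclass
class PipelineConfig:
    """Configuration for a full two-step run."""

    rng_seed: int
    sim: SimConfig = None
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    alpha: float = 0.05
    n_perm: int = 300
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sim is None:
            self.sim = SimConfig(rng_seed=self.rng_seed)

    def canonical_dict(self) -> dict:
        d = {
            "rng_seed": self.rng_seed,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "sim": asdict(self.sim),
            "preproc": asdict(self.preproc),
        }
        d["sim"]["grid_shape"] = list(d["sim"]["grid_shape"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All tables produced by one two-step run."""

    group_clusters: List[Cluster]
    regression_clusters: Dict[str, List[Cluster]]
    seed_tables: Dict[str, pd.DataFrame]
    strength: pd.DataFrame
    exclusions: List[ExclusionRecord]
    provenance: dict

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_cluster_table(self.group_clusters,
                            os.path.join(out_dir, "group_clusters.csv"))
        for outcome, clusters in self.regression_clusters.items():
            write_cluster_table(clusters,
                                os.path.join(out_dir, f"{outcome}_clusters.csv"))
        for name, table in self.seed_tables.items():
            table.to_csv(os.path.join(out_dir, f"seed_{name}_clusters.csv"),
                         index=False)
        self.strength.to_csv(os.path.join(out_dir, "strength.csv"), index=False)
        pd.DataFrame([asdict(e) for e in self.exclusions],
                     columns=["subject_id", "reason", "volume_index"]).to_csv(
            os.path.join(out_dir, "exclusions.csv"), index=False)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, sort_keys=True, indent=2)


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = [{
        "x": c.peak_mm[0], "y": c.peak_mm[1], "z": c.peak_mm[2],
        "k": c.k,
        "p_fdr": c.p_fdr_voxelpeak,
        "p_fwe": c.p_fwe_cluster,
        "direction": c.direction,
    } for c in clusters]
    df = pd.DataFrame(rows, columns=["x", "y", "z", "k", "p_fdr", "p_fwe",
                                     "direction"])
    if len(df):
        df = df.sort_values(["k", "x"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return df


def write_cluster_table(clusters: Sequence[Cluster], path: str) -> None:
    """CSV cluster table (x, y, z in mm; descending k, then x)."""
    clusters_to_frame(clusters).to_csv(path, index=False)


def _surviving(clusters: Sequence[Cluster], alpha: float) -> List[Cluster]:
    return [c for c in clusters
            if c.p_fwe_cluster is not None and c.p_fwe_cluster < alpha]


def _seed_second_level(seed_name: str, clusters: List[Cluster],
                       series_by_id: Dict[str, BoldSeries],
                       design_frame: pd.DataFrame, contrast_design,
                       contrast: str, cfg: PipelineConfig,
                       mask: np.ndarray, affine: np.ndarray,
                       rng: np.random.Generator,
                       subject_ids: Sequence[str]) -> pd.DataFrame:
    """Seed maps for one cluster seed, modelled at the same thresholds."""
    seed_mask = clusters[0].mask if clusters else None
    maps = []
    for sid in subject_ids:
        series = series_by_id[sid]
        ts = extract_seed_timeseries(series, seed_mask)
        maps.append(seed_correlation_map(series, ts, seed_mask, sid).z)
    maps = np.asarray(maps)
    cl, _ = cluster_fwe_permutation(maps, contrast_design, contrast,
                                    n_perm=cfg.n_perm,
                                    cluster_forming_alpha=cfg.alpha,
                                    mask=mask, affine=affine, rng=rng)
    return clusters_to_frame(_surviving(cl, cfg.alpha))


def run_two_step(config: PipelineConfig,
                 records: Optional[List[SubjectRecord]] = None,
                 series_by_id: Optional[Dict[str, BoldSeries]] = None,
                 ) -> AnalysisReport:
    """Run the full pipeline and return the report.

    Without ``records``/``series_by_id`` a synthetic cohort is generated
    from ``config.sim``.  Supplied series must already be in a common space.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    sim = config.sim
    templates = make_network_templates(sim.grid_shape, amplitude=sim.amplitude)
    by_name = {t.name: t for t in templates}
    brain_mask = make_brain_mask(sim.grid_shape)

    if records is None:
        records = simulate_cohort(sim)
    if series_by_id is None:
        series_by_id = {
            r.subject_id: simulate_subject(r, templates, sim, brain_mask)
            for r in records
        }

    # --- preprocessing with the motion-exclusion gate -----------------
    exclusions: List[ExclusionRecord] = []
    prepped: Dict[str, BoldSeries] = {}
    for r in records:
        motion = r.motion if r.motion is not None else np.zeros((sim.n_timepoints, 6))
        out = run_preprocess(series_by_id[r.subject_id], motion, config.preproc,
                             noise_mask=by_name["NOISE_ROI"].mask,
                             subject_id=r.subject_id)
        if isinstance(out, ExclusionRecord):
            logger.info("excluding %s (volume %d)", r.subject_id, out.volume_index)
            exclusions.append(out)
        else:
            prepped[r.subject_id] = out

    included = [r for r in records if r.subject_id in prepped]
    n_pat = sum(r.group == "patient" for r in included)
    n_ctl = sum(r.group == "control" for r in included)
    if n_pat < 2 or n_ctl < 2:
        raise RuntimeError(
            f"too few subjects after motion QC (patients={n_pat}, "
            f"controls={n_ctl}); excluded: "
            f"{[e.subject_id for e in exclusions]}")

    cov = pd.DataFrame([{
        "subject_id": r.subject_id, "group": r.group, "age": r.age,
        "gender": r.gender, "bdi": r.bdi, "psqi": r.psqi, "isi": r.isi,
        "age_of_onset": r.age_of_onset, "duration": r.duration,
    } for r in included])

    # --- first level: ICC z-maps --------------------------------------
    logger.info("computing ICC maps for %d subjects", len(included))
    icc_z = np.asarray([
        normalize_icc(compute_icc(prepped[r.subject_id])) for r in included
    ])
    affine = next(iter(prepped.values())).affine

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0xFC]))

    design = build_design(cov)
    group_cl, _ = cluster_fwe_permutation(icc_z, design, "group",
                                          n_perm=config.n_perm,
                                          cluster_forming_alpha=config.alpha,
                                          mask=brain_mask, affine=affine,
                                          rng=rng)
    group_sig = _surviving(group_cl, config.alpha)
    logger.info("group contrast: %d surviving clusters", len(group_sig))

    # --- clinical regressions (patients only) -------------------------
    pat_ids = [r.subject_id for r in included if r.group == "patient"]
    pat_rows = cov["group"] == "patient"
    pat_maps = icc_z[pat_rows.to_numpy()]
    regression_clusters: Dict[str, List[Cluster]] = {}
    reg_designs: Dict[str, pd.DataFrame] = {}
    for outcome in _REGRESSION_OUTCOMES:
        y = cov.loc[pat_rows, outcome].astype(float)
        X = pd.DataFrame({"intercept": 1.0, outcome: y})
        reg_designs[outcome] = X
        cl, _ = cluster_fwe_permutation(pat_maps, X, outcome,
                                        n_perm=config.n_perm,
                                        cluster_forming_alpha=config.alpha,
                                        mask=brain_mask, affine=affine, rng=rng)
        regression_clusters[outcome] = _surviving(cl, config.alpha)
        logger.info("regression on %s: %d surviving clusters",
                    outcome, len(regression_clusters[outcome]))

    # --- second level: every surviving cluster becomes a seed ---------
    all_ids = [r.subject_id for r in included]
    seed_tables: Dict[str, pd.DataFrame] = {}
    for i, c in enumerate(group_sig, start=1):
        seed_tables[f"group_{i}"] = _seed_second_level(
            f"group_{i}", [c], prepped, cov, design, "group", config,
            brain_mask, affine, rng, all_ids)
    for outcome, clusters in regression_clusters.items():
        for i, c in enumerate(clusters, start=1):
            seed_tables[f"{outcome}_{i}"] = _seed_second_level(
                f"{outcome}_{i}", [c], prepped, cov, reg_designs[outcome],
                outcome, config, brain_mask, affine, rng, pat_ids)

    # --- DMN<->SMA-analog strength vs onset/duration ------------------
    onset_sig = regression_clusters.get("age_of_onset", [])
    if onset_sig:
        seed_mask = onset_sig[0].mask
        seed_source = "first-level age_of_onset cluster 1"
    else:
        seed_mask = by_name["DMN"].mask
        seed_source = "DMN template (no surviving onset cluster)"
    target_mask = by_name["SMA"].mask
    strengths = []
    for sid in pat_ids:
        series = prepped[sid]
        ts = extract_seed_timeseries(series, seed_mask)
        zmap = seed_correlation_map(series, ts, seed_mask, sid).z
        rows = np.nonzero(target_mask[tuple(series.voxel_coords.T)])[0]
        strengths.append(float(zmap[rows].mean()))
    strengths = np.asarray(strengths)
    strength_rows = []
    for outcome in ("age_of_onset", "duration"):
        y = cov.loc[pat_rows, outcome].astype(float).to_numpy()
        r2, slope, _ = connectivity_strength_r2(strengths, y)
        strength_rows.append({"outcome": outcome, "r_squared": r2,
                              "slope": slope, "n": len(strengths),
                              "seed": seed_source})
    strength = pd.DataFrame(strength_rows)
    strength_subjects = pd.DataFrame({
        "subject_id": pat_ids, "strength": strengths,
        "age_of_onset": cov.loc[pat_rows, "age_of_onset"].to_numpy(),
        "duration": cov.loc[pat_rows, "duration"].to_numpy(),
    })

    provenance = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "version": __version__,
        "n_included": len(included),
        "n_excluded": len(exclusions),
        "strength_seed": seed_source,
    }
    report = AnalysisReport(
        group_clusters=group_sig,
        regression_clusters=regression_clusters,
        seed_tables=seed_tables,
        strength=strength,
        exclusions=exclusions,
        provenance=provenance,
    )
    report.strength_subjects = strength_subjects
    if config.out_dir:
        report.save(config.out_dir)
        strength_subjects.to_csv(
            os.path.join(config.out_dir, "strength_subjects.csv"), index=False)
    return report


def load_pipeline_config(path: str, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON mapping file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "rng_seed" not in raw:
        raise ValueError("config must provide rng_seed")
    sim_kwargs = raw.get("sim", {}) or {}
    sim_kwargs.setdefault("rng_seed", raw["rng_seed"])
    if "grid_shape" in sim_kwargs:
        sim_kwargs["grid_shape"] = tuple(sim_kwargs["grid_shape"])
    preproc_kwargs = raw.get("preproc", {}) or {}
    return PipelineConfig(
        rng_seed=int(raw["rng_seed"]),
        sim=SimConfig(**sim_kwargs),
        preproc=PreprocConfig(**preproc_kwargs),
        alpha=float(raw.get("alpha", 0.05)),
        n_perm=int(raw.get("n_perm", 300)),
        out_dir=raw.get("out_dir"),
        log_level=str(raw.get("log_level", "INFO")),
    )
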