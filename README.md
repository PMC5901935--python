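# voxelfc

Voxel-wise resting-state fMRI functional connectivity pipeline with a
synthetic BOLD cohort generator.

The package implements a two-step connectivity analysis for a
patients-vs-controls resting-state study:

1. **Synthetic cohort** (`voxelfc.synthetic`) — seeded generation of subject
   covariate records (group, age, gender, BDI/PSQI/ISI, age of onset,
   disease duration, motion traces) and masked 4D BOLD volumes on a small
   common grid, with planted structure: band-limited latent time courses per
   network template (DMN, SMA, bilateral visual and temporal blocks), an
   exact DMN–SMA latent correlation that varies affinely with each patient's
   age of onset, an occipital gain multiplier for patients, linear drift, a
   high-frequency physiological confound concentrated in a noise ROI, and
   white noise.
2. **Temporal preprocessing** (`voxelfc.preprocess`) — motion-based
   exclusion gate (strict >1.0 mm / >1.0° limits), initial volume discard,
   per-voxel linear detrend, zero-phase 0.01–0.08 Hz Butterworth band-pass,
   and CompCor-style nuisance regression of noise-ROI principal components.
3. **Intrinsic connectivity contrast** (`voxelfc.icc`) — per-voxel mean of
   squared positive Pearson correlations with every other brain voxel,
   computed in row chunks without materializing the correlation matrix, then
   z-normalized over the brain mask.
4. **Seed-based connectivity** (`voxelfc.seedconn`) — Fisher-z correlation
   maps between a cluster seed's mean time series and every voxel.
5. **Inference** (`voxelfc.inference`) — vectorized voxel-wise GLM
   (covariate-adjusted group contrast and clinical-score regressions),
   Benjamini–Hochberg FDR, 26-connected cluster formation split by effect
   sign, Freedman–Lane permutation null of the maximum cluster extent for
   cluster-level FWE, and strength-vs-outcome R².
6. **Clinical scales** (`voxelfc.clinical`) — PSQI/ISI/BDI range checks and
   severity bands, plus pooled two-sample t statistics from per-group
   summary statistics.
7. **Pipeline & CLI** (`voxelfc.pipeline`, `voxelfc.cli`) — orchestration:
   cohort → preprocessing → ICC maps → FDR+FWE inference → each surviving
   cluster becomes a seed for a second-level analysis at the same
   thresholds → cluster tables and a DMN↔SMA strength report. Fully
   deterministic given a config and seed.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (summary-statistic t
tests, ICC oracle equivalence, normalization contract, FDR/FWE Monte-Carlo
calibration, planted-effect parameter recovery, preprocessing contracts,
end-to-end determinism). The full suite takes a few minutes on one CPU.

## CLI

```bash
voxelfc simulate --seed 1 --out data/               # cohort: NIfTI + CSV
voxelfc preprocess --data data/ --out prep/         # motion gate + temporal chain
voxelfc icc --data prep/ --mask data/brain_mask.nii.gz --out iccmaps/
voxelfc analyze --seed 1 --n-perm 300 --out analysis/   # full two-step run
voxelfc report --analysis analysis/                 # print saved tables
```

All subcommands accept `--config cfg.yaml`, a mapping with optional `sim`,
`preproc`, `alpha`, `n_perm` sections, e.g.

```yaml
rng_seed: 1
n_perm: 300
sim:
  n_patients: 17
  n_controls: 17
  n_timepoints: 178
preproc:
  n_discard: 3
```

Cluster tables are CSVs with columns `x,y,z,k,p_fdr,p_fwe,direction`
(peak mm coordinates, cluster extent, corrected p-values), sorted by
descending extent. Every reported cluster passes both correction stages.

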