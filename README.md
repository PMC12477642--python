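# crossmodal

Cross-modal spatial analysis of volumetric brain maps. The package relates
two sets of whole-brain images (a coarse dynamic "HP" block and a finer
"PET"-like block) through a reproducible pipeline:

- **Sum images** — temporal integration of dynamic series over configurable
  windows (all frames, fixed windows, last-N-minutes, uptake detection).
- **Normalization** — whole-brain mean-1 scaling and voxelwise group medians.
- **Derived maps** — spatial-regression residual maps (glycolytic index and
  metabolite residuals), vascular-signal removal, and a floor-guarded
  oxygen-extraction ratio map.
- **Smoothing** — mask-renormalized 3D Gaussian smoothing with empirical
  FWHM selection by rank correlation.
- **Parcellation** — integer label volumes with unit-sphere centroids;
  regional medians; a synthetic Fibonacci-lattice spherical parcellation.
- **Statistics** — Spearman correlations, spin-permutation inference
  (random spherical rotations of parcel data, preserving spatial
  autocorrelation), and Benjamini–Hochberg FDR control.
- **PLS** — two-block canonical-mode partial least squares (NIPALS) with
  deterministic signs and score-map normalization.
- **Synthetic data** — multi-subject paired datasets built from known
  latent spatial fields and mixing matrices, so every stage can be tested
  against planted ground truth.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the
normalization/residual/PLS invariants, and `tests/test_acceptance.py`
covering the acceptance contracts (the spin-test calibration check runs
~500 simulated null pairs and takes a couple of minutes).

## CLI

```sh
crossmodal simulate --seed 1 --n-subjects 10 --out-dir data/        # synthetic dataset
crossmodal sum data/sub-01_pyruvate.nii.gz --out sum.nii.gz
crossmodal normalize sum.nii.gz --mask data/mask.nii.gz --out norm.nii.gz
crossmodal smooth norm.nii.gz --mask data/mask.nii.gz --fwhm 14 --out smooth.nii.gz
crossmodal derive --kind gi --dependent cmrglc.nii.gz --independent cmro2.nii.gz \
    --mask data/mask.nii.gz --out gi.nii.gz
crossmodal correlate --map a=a.nii.gz --map b=b.nii.gz --mask data/mask.nii.gz \
    --parcellation data/parcellation.nii.gz --centroids data/parcel_centroids.csv \
    --n-perm 10000 --out correlations.csv
crossmodal run --config config.yaml --out-dir results/              # full pipeline
```

`crossmodal run` executes the whole study: simulate (or load) subjects,
sum + normalize, derived maps, group medians, smoothing, correlation
matrices with spin p-values and FDR flags, PLS, and a provenance record.
Outputs: `correlations.csv`, `pls_weights.csv`,
`pls_score_correlations.csv`, `scores_*.nii.gz`, `provenance.json`.
Runs are pure functions of (config, seed): repeated runs produce
byte-identical CSVs.

Example YAML config:

```yaml
n_subjects: 35
grid_shape: [32, 32, 32]
n_parcels: 200
fwhm_mm: 14.0
n_perm: 10000
alpha: 0.05
seed: 0
```

## Python API

```python
from crossmodal import RunConfig, run_study

result = run_study(RunConfig(out_dir="results", seed=0, n_perm=10_000))
result.correlations          # long-format pair table with spin p and FDR flags
result.pls.weights_x         # per-component channel weights
```
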