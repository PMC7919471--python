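# gdr — gated delta-radiomics

`gdr` identifies treatment-induced changes in PET radiomic features that
exceed a *patient-individualized* noise floor. The key idea: the spread of a
feature across the K respiratory phases of a pre-treatment 4D (gated) PET
scan measures that feature's intrinsic variability (noise, resolution,
breathing motion) in that patient. A change during therapy is expressed in
units of that noise floor,

```
delta = delta_r / sigma_4d
delta_r  = 100 * (post - pre) / |pre|          # relative change, %
sigma_4d = 100 * SD(phases) / |mean(phases)|   # relative phase spread, %
```

and only features that earn the right to this normalization are used: they
must be (1) normally distributed across the gated phases in > 70% of
patients (Shapiro–Wilk) and (2) comparable between the static 3D scan and
the 4D phase summary (BH-adjusted Wilcoxon signed-rank, confirmed by the
Bland–Altman percentage CI). The resulting deltas feed a logistic
local-recurrence model evaluated by stratified bootstrap with out-of-bag
ROC/AUC.

Because no clinical scans ship with this package, a synthetic 4D-PET
phantom generator stands in for the data: a textured ellipsoidal lesion,
PSF blur (default FWHM 4.8 mm), multiplicative noise, periodic per-phase
displacement, and a follow-up scan whose lesion *homogenization* is planted
per outcome group.

## Modules

| module | contents |
|---|---|
| `gdr.phantom_io` | image/mask/phase-series data model, NIfTI + manifest I/O, phantom & cohort simulation |
| `gdr.segmentation` | contrast-oriented threshold segmentation (COA), manual-mask ingestion |
| `gdr.feature_bank` | first-order, GLCM, GLRLM, GLSZM, NGTDM features; raw / wavelet-band-pass (`WF-`) / equal-probability-quantized (`Q-`) variants |
| `gdr.wavelet` | self-contained periodized Coiflet-1 3D transform with 2:1 sub-band weighting |
| `gdr.robustness_screen` | phase-normality screen, 3D-vs-4D comparability screen, BH adjustment |
| `gdr.delta_outcome` | delta computation, Mann–Whitney group tests, bootstrap logistic model, ROC |
| `gdr.cli_pipeline` | YAML-configured end-to-end pipeline and the `gdr` CLI |

## CLI

```bash
gdr run --config run.yaml --out out/      # full pipeline
gdr simulate --n 10 --seed 1 --out cohort/
gdr coa --in vol.nii.gz --roi box.json --a 0.5 --b 0.5 --out mask.nii.gz --report coa.json
gdr extract --vol vol.nii.gz --mask mask.nii.gz --out features.csv
gdr screen --features features.csv --out screen_report.json
gdr delta --features features.csv --eligible screen_report.json --out deltas.csv
gdr model --deltas deltas.csv --outcome manifest.csv --label LR --out model.json
```

A minimal `run.yaml` needs only a seed; all other keys default sensibly and
unknown keys are rejected:

```yaml
seed: 7
cohort: {n: 30, lr_fraction: 0.4, K: 8, homogenization_lr: 0.75}
segmentation: manual        # or: coa
screen: {alpha: 0.05, patient_fraction: 0.70}
model: {endpoint: LR, features: [AUC_CSH], bootstrap: 1000}
```

Every run writes `features.csv`, `screen_report.json`, `deltas.csv`,
`model.json` and a `report.json` with per-stage status, output digests and
the fully resolved configuration; identical configs reproduce identical
digests.

## Conventions and defaults worth knowing

- Texture matrices are merged over the 13 unique 3D directions (one
  matrix, not per-direction averages); fixed bin width W = 0.01 SUV,
  anchored at the mask minimum; equal-probability quantization uses 64
  levels.
- COA threshold = `a*mSUV70 + b*background` with defaults a = b = 0.5 and a
  shell-based background estimate; report files always carry the
  coefficients used.
- Phase count defaults to K = 8 (configurable, reported with results);
  breathing pattern is a cos² displacement weighting with an optional
  per-phase jitter for irregular breathing.
- Undefined features (e.g. neighborhood statistics on one-voxel masks)
  become NaN sentinels and are excluded from screening and deltas rather
  than imputed; sigma below 0.1% excludes a delta record with a reason
  code instead of producing an unbounded value.
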