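# nircal

NIR-chemometric calibration and validation pipeline for assaying an active
ingredient (meloxicam) directly in pharmaceutical powder blends for
tableting. The package covers the full workflow:

- **protocol** — formulation design (120 mg tablet, isomalt-compensated
  blends at 80–120 % of the 12.50 % w/w target) and the calibration /
  validation experimental matrix (3 series × 5 levels calibration; 4
  replicates × 3 series at levels 1/3/5 for validation).
- **synth** — synthetic NIR reflectance spectra (11000→4000 cm⁻¹ at
  8 cm⁻¹) with linear mixing in absorbance, baseline drift, multiplicative
  scatter, between-series random effects and additive noise, so every
  downstream stage is testable without instrument data.
- **preprocess** — region selection (default 7500–4000 cm⁻¹) plus nine
  pre-treatments: none, moving-average and Savitzky–Golay smoothing
  (11 points, 2nd-order polynomial), unit-vector and min/max normalization,
  SNV, Norris gap first/second derivatives, and resolution reduction
  ("deresolve").
- **chemometrics** — PLS1 (NIPALS) and PCR with factor-wise prediction
  vectors and portable JSON model files.
- **model_selection** — leave-one-out / leave-group-out cross-validation,
  RMSECV/RMSEC/RMSEP/bias/R², MSE-ratio (or F-test) factor selection, and
  the 9 × 2 pre-treatment × method grid search ranked by RMSECV.
- **validation** — accuracy profiles: recovery/relative bias, one-way
  random-effects variance components (repeatability and intermediate
  precision), β-expectation tolerance intervals (Satterthwaite degrees of
  freedom), compliance against relative acceptance limits, and a linearity
  profile.

## CLI

```bash
nircal simulate  -o out/                       # protocol datasets (CSV)
nircal gridsearch --cal out/calibration.csv --val out/validation.csv -o grid.csv
nircal calibrate --cal out/calibration.csv --method pls \
                 --pretreatment smoothing_savitzky_golay -o model.json
nircal validate  --model model.json --val out/validation.csv -o valout/
nircal report    --gridsearch grid.csv --validation valout/ -o report.txt
```

All commands take `--config config.yaml` (see `nircal.config.RunConfig`)
and are deterministic given config + seed: identical inputs produce
byte-identical output files.

Spectrum sets are wide CSVs: a `#` header comment (tool version, config
hash, seed), five metadata columns (`sample_id, role, series, level_index,
nominal_pct_ww`) and one column per wavenumber, stored in descending
instrument order (ascending files are accepted and normalized).

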