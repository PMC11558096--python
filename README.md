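# sonolfa

Simulation and analysis toolkit for ultrasound-enriched colorimetric
lateral-flow assays (LFA). It covers the full workflow of an
acoustofluidically enhanced strip test:

- **`sonolfa.acoustics`** — 1D standing-wave acoustophoresis: acoustic
  contrast factor, primary radiation force, pressure-node structure of a
  resonant cavity, and an overdamped (Stokes-drag, optional Brownian)
  particle-migration simulator with convergence and enrichment metrics.
- **`sonolfa.synthetic`** — synthetic strip datasets and rendered strip
  images: a saturating dose-response with a configurable linear range,
  concentration-domain blank noise, an enrichment signal gain, and a
  geometric strip renderer (control/test bands 7 mm apart on a 4 mm
  strip).
- **`sonolfa.extraction`** — band detection on strip photographs,
  test-line ROI extraction, and the control-line QC filter.
- **`sonolfa.models`** — a KNN classifier (Euclidean RGB distance,
  documented tie-breaking) and a Gaussian-process regressor (RBF kernel,
  marginal-likelihood hyperparameter optimization), with stratified
  k-fold cross-validation.
- **`sonolfa.calibration`** — confusion matrix/accuracy, R², Bland-Altman
  limits of agreement, linear calibration with a blank+3·SD detection
  limit, single-feature baseline fits, Welch's t-test, clinical interval
  calls, and the end-to-end JSON report.

## CLI

The `sonolfa` entry point exposes the pipeline stages:

```bash
sonolfa generate --matrix PBS --n-per-level 15 --seed 1 --out records.csv
sonolfa render   --data records.csv --out-dir strips/
sonolfa extract  --images strips/ --out extracted.csv
sonolfa calibrate --data records.csv --model gpr --seed 7 --out gpr.json
sonolfa calibrate --data records.csv --model knn --k 5 --out knn.json
sonolfa report   --config assay.cfg --seed 1 --out report.json
sonolfa simulate-acoustics --config sim.cfg --n-particles 100
```

Configs are flat `key = value` files (JSON-typed values), e.g.:

```
field.frequency_hz = 700000
field.pressure_amplitude_pa = 1e5
sim.dt_s = 1e-4
clinical.threshold_ng_ml = 0.3
```

## Notes

- The blank background statistics (0.0022 ± 0.0021 ng/mL in buffer,
  0.0025 ± 0.0026 ng/mL in serum) are injected in the concentration
  domain, so back-calculated blank statistics reproduce them by
  construction.
- A single ~40 nm particle's radiation force is far too weak to migrate
  on laboratory time scales; use `effective_cluster_radius` and
  `force_scale` to simulate aggregate-scale dynamics. Collective
  acoustofluidic effects are out of scope.
- The clinical decision threshold is deliberately unconfigured; set
  `clinical.threshold_ng_ml` explicitly.
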