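# naquant

Multivariate quantification and CHO characterization of naphthenic acids
(NAs) in produced water from direct-infusion ESI(−) high-resolution mass
spectra.

The package covers the full workflow:

- **Spectrum I/O and alignment** (`naquant.spectra_io`): centroided spectra
  from mzML or two-column peak-list CSV, aligned onto a fixed-width m/z grid
  (default 0.001 Th over m/z 100–400, half-open bins); only occupied bins
  become columns of the sample × bin intensity matrix X.
- **Synthetic data** (`naquant.synthetic_data`): a seeded simulator for
  mixtures of the ten carboxylic-acid calibration standards (12 levels ×
  3 replicates, 0.5–40 mg·L⁻¹ by default) with configurable mass error,
  intensity noise, chemical baseline and real-sample interferents.
- **Preprocessing** (`naquant.preprocess`): row normalization (sum / max /
  vector) and calibration-fitted column scaling (mean centering or
  autoscaling, sample SD).
- **PLS core** (`naquant.pls_core`): PLS1 via NIPALS, RMSE and Pearson-r
  metrics, Monte-Carlo cross-validation with random removal of three
  samples (exhaustive leave-one-out when `leave_out=1, n_splits=n`).
- **OPS variable selection** (`naquant.ops_selection`): ordered predictor
  selection — rank variables by an informative vector (|b|, |corr| or their
  product), evaluate growing prefixes (window 20, increment 5, 100 % tested
  by default) under shared CV splits, keep the RMSECV-best subset.
- **Characterization** (`naquant.characterize`): CHO formula assignment for
  [M−H]⁻ peaks (electron mass included), Ox class distributions and
  DBE × carbon-number matrices.
- **Pipeline + CLI** (`naquant.pipeline`, `naquant.cli`): stratified 24/12
  calibration/prediction splits, end-to-end calibration reports
  (RMSEC/Rc, RMSECV/Rcv, RMSEP/Rp), dilution-corrected prediction of
  unknowns, model serialization to JSON.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit and property tests per module plus
`tests/test_acceptance.py`, which checks the headline contracts (dilution
arithmetic on the bundled 12-sample reference table, exact-mass engine,
oracle equivalence of the PLS core against scikit-learn/OLS/brute-force
LOO, noiseless parameter recovery, and the full pipeline on the synthetic
36-sample set reaching Rc, Rp ≥ 0.95).

## CLI

```bash
# simulate 36 standard-mixture spectra + manifest
naquant simulate --out-dir data/ --seed 42

# align manifest spectra into a wide CSV matrix
naquant align --manifest data/manifest.csv --out X.csv

# calibrate OPS-PLS and write report.json / model.json / ops_trace.csv
naquant fit --manifest data/manifest.csv --out-dir results/ --seed 42

# predict unknowns with dilution correction
naquant predict --model results/model.json --manifest unknowns.csv \
    --dilution-factor 20 --out predictions.json

# CHO formula assignment + class / DBE summaries for one peak list
naquant characterize --input sample.csv --out-dir characterization/
```

All stages accept `--config config.yaml` (see `naquant.pipeline.PipelineConfig`
for the keys) and a single `--seed` that fixes every source of randomness
(split, CV, OPS, simulation).

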