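# nirfusion

Chemometrics pipeline for FT-NIR fruit-quality phenotyping. The package
simulates lab quality panels (soluble solids, titratable acidity,
vitamin C, anthocyanins, phenolic acids) and linked FT-NIR absorbance
spectra for four strawberry cultivars, then runs the full analysis
chain:

* **synth** — cultivar-profile generator: zero-truncated multivariate
  normal lab panels, Gaussian-band spectra with composition-linked
  amplitudes, multiplicative/additive scatter, instrument noise and
  missing-at-random lab records (default cohort: 4 cultivars x 54
  fruits x 2 replicate spectra = 432 observations x 1557 wavenumbers on
  a 10,000–4,000 cm⁻¹ grid).
* **preprocess** — range trimming, SNV, MSC, Savitzky–Golay
  smoothing/derivatives, mean centering, autoscaling, block scaling and
  replicate averaging, with train-fitted statistics for test data.
* **pca** — SVD-based PCA with deterministic sign convention, score
  projection and per-group confidence-ellipse summaries.
* **fusion** — low-level (variable concatenation + block scaling) and
  mid-level (per-block PCA scores + autoscaling) multiblock fusion,
  including back-reconstruction of original-variable contributions
  (O = PᵀF).
* **model_selection** — duplex train/test partitioning, venetian-blinds
  cross-validation folds, 1-SE latent-variable selection.
* **plsda** — NIPALS-style PLS1/PLS2 discriminant analysis with dummy
  coding, ROC analysis, CV-based threshold choice, TPR/TNR/error
  reporting, the three binary cultivar-group models and a multiclass
  variant.
* **anova** — one-way ANOVA with Tukey HSD post hoc and compact-letter
  display.
* **io / pipeline / cli** — CSV readers/writers, complete-case joining,
  YAML/JSON configuration and the end-to-end orchestrator.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (dataset
counts, generator mean recovery, Tukey letter-pattern recovery over 200
seeds, zero-error classification under strong class separation, oracle
equivalences and the permutation null).

## CLI

```sh
nirfusion simulate  --seed 1 --outdir out          # panel.csv + spectra.csv
nirfusion preprocess out/spectra.csv --outdir out  # trim + 1st derivative + centering
nirfusion pca out/spectra-preprocessed.csv --outdir out
nirfusion fuse out/panel.csv out/spectra-preprocessed.csv --level mid --outdir out
nirfusion anova out/panel.csv --outdir out
nirfusion classify out/spectra.csv out/panel.csv --mode mode1 --features nir
nirfusion run-all --seed 1 --outdir out            # everything, one report bundle
```

All commands accept `--config PATH` (YAML or JSON with a `seed` field);
`run-all` writes CSV/JSON outputs tagged with the config hash and seed
and is byte-reproducible from (config, seed).

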