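# lesionrad

Multi-sequence MRI lesion radiomics for two-class lesion discrimination,
driven entirely by synthetic lesion phantoms:

* **Synthetic cohorts** — reproducible two-class lesion phantoms over four
  MR sequences (in-phase, out-phase, T2WI, DWI) with controllable
  class-separating mean shifts and heterogeneity texture, written as NIfTI
  volumes/masks plus a CSV manifest.
* **Feature bank** — 1029 named features per volume/mask pair: 93
  original-image features (19 first-order, 15 shape, 27 GLCM, 16 GLRLM,
  16 GLSZM) plus 936 higher-order features (the 78 intensity-dependent
  features recomputed on 12 filtered variants: exponential, square,
  square-root, logarithm, and 8 single-level 3-D wavelet bands).
* **Selection cascade** — variance threshold (0.8) → per-feature
  Mann-Whitney filter (p ≤ 0.05) → linear LASSO with subject-grouped
  cross-validated alpha, per sequence.
* **Evaluation grid** — four classifiers (decision tree, random forest,
  KNN, logistic regression) × four sequences plus a combined model, with
  subject-grouped stratified 80/20 splits, ROC/AUC, Youden operating
  points, and DeLong AUC comparisons.

## CLI

```bash
lesionrad simulate --config config.yaml --out cohort/       # phantoms + manifest
lesionrad extract  --manifest cohort/manifest.csv --out features.csv
lesionrad select   --features features.csv --out selection.json --plots plots/
lesionrad evaluate --features features.csv --out report.json
lesionrad run-all  --config config.yaml --out run/          # all of the above
lesionrad report   --out registry.json                      # feature registry
```

The YAML config is schema-validated (unknown keys are rejected) and is
serialized into every output for provenance. An empty config uses the
defaults shown in `lesionrad.config`.

## Conventions worth knowing

* Intensity normalization is the z-score map `f(x) = s(x - mean)/sd` over
  the **whole image**, using the **population** SD; it is applied to every
  sequence volume before both original and filtered feature extraction,
  so downstream features are invariant to intensity gain/offset.
* Discretization uses a fixed bin **count** (default 32 equal-width bins
  over the in-mask range) rather than a fixed bin width, since absolute
  widths are meaningless after normalization.
* GLCM/GLRLM features are averaged over the 13 unique 3-D directions at
  distance 1; directions with no voxel pairs are excluded from the GLCM
  average. GLSZM zones use 26-connectivity.
* Two GLCM registry names carry nonstandard labels; they are mapped
  interpretively (`AverageIntensity` → joint average, `GrayLevelIntensity`
  → joint grey-level variance) and flagged in the exported registry.
* Splits are grouped by subject (no patient contributes lesions to both
  sides) and stratified by class; a literal lesion-level split is
  available via `split.grouping: lesion`.
* No spatial resampling anywhere: features are computed on the native
  anisotropic grid, with physical spacing entering only the shape
  features; mask/volume grid or spacing mismatches fail loudly.
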