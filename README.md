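# specnn

Spectral origin classification with attention-enhanced 1D convolutional
networks, plus the full chemometric pipeline around them:

- **`specnn.dataset`** — labelled reflectance-spectrum tables (delimited
  text in, validated `SpectralDataset` out), band trimming, class mean
  spectra, stratified 6:2:2 splitting (spectral-level by default, optional
  fruit-level grouped splitting).
- **`specnn.synth`** — synthetic three-class reflectance generator with two
  wavelength presets (`visnir`: 381–1016 nm / 123 bands, `swir`:
  959–1684 nm / 267 bands), smooth class templates, multiplicative+additive
  scatter and white noise. The SWIR preset deliberately overlaps two
  classes so it is harder than Vis–NIR.
- **`specnn.preprocess`** — Savitzky–Golay smoothing (window 5, order 3),
  SNV, MSC with fit-on-train/apply-anywhere pipelines.
- **`specnn.dimreduce`** — in-house PCA (SVD, fixed sign convention,
  train-fitted) and a UMAP wrapper (optional dependency) for 3-D
  visualisation and 20-D reduced-feature modelling.
- **`specnn.net`** — NumPy-native 1D conv networks with hand-written
  backward passes: the ECA channel-attention module with adaptive kernel
  size (C=16/32 → k=3, C=64 → k=5), and declarative builders for ECNN-1D,
  CNN-1D (the no-attention ablation), VGG-1D and ResNet-1D, all with an
  attention on/off switch. AdamW optimizer included.
- **`specnn.train`** — training protocol: batch size 8, lr 5e-4, weight
  decay 1e-5, ≤50 epochs, early stopping with patience 10 on validation
  accuracy, best-checkpoint restoration, five-seed mean±std aggregation.
- **`specnn.evaluate`** — confusion matrices, accuracy, per-class and macro
  precision/recall/F1, classical baselines (LDA/RF/KNN/SVM via
  scikit-learn), and a model × dataset benchmark/ablation grid.

Everything is deterministic under a seed, including network training.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; the two
training-based criteria (full presets, five seeds each) take a few minutes
on one CPU, everything else finishes in seconds.

## CLI

```bash
# generate a synthetic dataset
specnn simulate --preset visnir --n-per-class 220 --seed 0 --out visnir.csv

# preprocess (fit stateful steps on a manifest of training sample ids)
specnn preprocess --steps sg:5:3,snv --in visnir.csv --out visnir_prep.csv

# dimensionality reduction
specnn reduce --method pca --dims 20 --in visnir_prep.csv --out scores.csv

# train one model over five seeds
specnn train --model ecnn1d --in visnir.csv --steps sg:5:3,snv --out report.json

# benchmark grid / ablation
specnn benchmark --models lda,rf,knn,svm,ecnn1d --in visnir visnir.csv --out grid.csv
specnn ablate --in visnir.csv --out ablation.csv

# or drive several stages from one YAML config
specnn run --config pipeline.yaml
```

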