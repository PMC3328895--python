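# tearfilm

Automatic classification of tear-film lipid layer interference patterns
from eye photographs, together with the statistical machinery to compare
classifiers on accuracy tables.

The pipeline:

1. **ROI extraction** (`tearfilm.roi`) — the most illuminated region
   (bottom of the iris) is located by maximum normalised cross-correlation
   between the luminance (L) channel and a set of illumination-profile
   templates, then cropped.
2. **Colour analysis** (`tearfilm.colour`) — images are analysed in
   grayscale, CIE L\*a\*b\* and Hering opponent channels
   (RG = R − p∗G, GR = G − p∗R, BY = B − p∗(R+G), with p a unit-DC Gaussian
   lowpass). Multichannel descriptors concatenate the three per-channel
   descriptors.
3. **Texture descriptors** (`tearfilm.texture`) — five families:
   a 9-filter second-order Butterworth bandpass bank (16-bin nonequidistant
   histograms), a 2-scale orthonormal Haar pyramid (12 components),
   grey-level co-occurrence matrices with the 14 Haralick statistics
   (mean + range over the 4d orientations → 28 features), Gaussian Markov
   random fields (4d directional residual variances), and a 16-filter Gabor
   bank (per-filter nonequidistant histograms with 3/5/7/9 bins).
4. **Classification** (`tearfilm.classify`) — NB, LMT, RT, RF and SVM
   evaluated by stratified 10-fold cross-validation, reported as
   percentage accuracies.
5. **Statistical comparison** (`tearfilm.stats`, `tearfilm.tables`) —
   Lilliefors normality gate (Monte-Carlo p-values), one-way ANOVA and
   Tukey HSD over classifier accuracy tables. Transcribed reference
   accuracy tables ship as fixtures and every published ANOVA block and
   Tukey verdict is recomputed from them (`reproduce_reference_stats`).
6. **Synthetic data** (`tearfilm.synth`) — seeded generators for the four
   texture categories (sparse/dense grey meshwork, oriented grey waves,
   brown/blue colour fringes) and full synthetic eye frames with a known
   planted ROI, so the whole pipeline is testable without clinical data.

## CLI

```sh
tearfilm synth --what dataset --seed 1 --out out/ds        # 105 labelled images
tearfilm synth --what eye --seed 1 --out out/eye           # eye frame + ground truth
tearfilm roi --image out/eye/eye.png --json roi.json --out crop.png
tearfilm features --image crop.png --method cooccurrence --space lab --param 5 --out f.csv
tearfilm evaluate --features all.csv --labels labels.csv --classifier svm --out cv.json
tearfilm compare --table table.csv --space grayscale --out cmp.json
tearfilm run-experiment --method cooccurrence --seed 1 --out exp.json
tearfilm reproduce-paper --out report.json                 # all 12 ANOVA blocks
```

## Notes

* The clinical 105-image dataset behind the reference accuracy tables is
  not public; absolute classification accuracies are therefore validated
  on synthetic data (separability contract: co-occurrence d=5 in Lab +
  SVM reaches ≥85% on the default synthetic dataset; permuted labels fall
  to chance).
* Several conventions left open by the source description (grayscale
  weights, lowpass width, filter-bank tilings, GLCM quantisation depth,
  classifier hyperparameters, CV seeding) are pinned in
  `tearfilm.config.PipelineConfig` and echoed in every run's output.
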