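# serofir

Machine-learning-assisted FTIR serum fingerprinting: a complete, tested
pipeline that stratifies **non-allergic**, **allergic** and
**immunotherapy-treated (SIT / tolerized)** subjects from mid-infrared
transmission spectra of dried serum films.

Allergic disease and successful allergen-specific immunotherapy both leave
broad compositional traces in serum — shifted lipid, protein and
carbohydrate profiles — that appear as small absorbance changes in the
1800–900 cm⁻¹ fingerprint window of an FTIR spectrum.  `serofir`
implements the full workflow needed to turn raw serum spectra into
per-class diagnostic merits:

1. **simulate** — a synthetic serum-spectrum generator (Gaussian band
   model, subject-level biological variability, scatter/baseline/noise/
   water-vapour artifacts, batch effects, gross outliers) standing in for
   cohort data that are not public;
2. **qc** — per-spectrum quality checks (absorbance level, signal-to-noise,
   water-vapour lines) plus Hotelling T² / Q-residual outlier charts on a
   PCA model of the mean-centred spectra;
3. **preprocess** — truncation to 1800–900 cm⁻¹, Savitzky–Golay second
   derivative (15-point window), multiplicative scatter correction, unit
   vector normalization, train-fitted scaling;
4. **transfer** — piecewise direct standardization (PDS) mapping spectra
   of a second measurement batch onto the first so multi-experiment data
   pool cleanly;
5. **unsupervised** — PCA stratification with explained-variance
   reporting, 95 % confidence ellipses per group, and Mardia's multivariate
   normality screen;
6. **classify** — a 1-D convolutional neural network (SGD + momentum + L2,
   early stopping on validation error) over repeated stratified 65/20/15
   splits, with Bayesian hyperparameter optimization (Gaussian-process
   surrogate, expected improvement) of depth, learning rate, momentum, L2,
   filter size and filter count;
7. **evaluate** — pooled test confusion matrix, one-vs-rest sensitivity /
   specificity / PPV per class, overall accuracy, and chord-diagram edge
   lists.

Transformers and the classifier follow the scikit-learn estimator API
(`fit` / `transform` / `predict`, fitted attributes with trailing
underscores), so they compose with sklearn pipelines and model selection.
See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from serofir import (preset, generate_dataset, qc_report, apply_outlier_filter,
                     preprocess_pipeline, PreprocessParams, fit_pca,
                     run_classification)

cfg = preset("mouse", separation="moderate", seed=7)  # 3 groups x 10 subjects x 20 replicates
dataset, truth = generate_dataset(cfg)

report = qc_report(dataset)                           # quality checks + T2/Q chart
clean, excluded = apply_outlier_filter(dataset, report)
print(f"QC: {len(excluded)} of {dataset.n_spectra} spectra excluded")

pre = preprocess_pipeline(clean, PreprocessParams(scale_mode="mean-center"))
pca = fit_pca(pre, n_components=2)
print("explained variance: PC-1 {:.0%}, PC-2 {:.0%}".format(
    *pca.explained_variance_ratio_))

run = run_classification(clean, grouping="spectrum", n_repeats=3,
                         bayes_budget=0, seed=1,
                         class_order=("non_allergic", "allergic", "sit"))
print(run.confusion.to_frame())
print(run.metrics[["sensitivity", "specificity", "ppv", "accuracy"]].round(3))
```

prints

```
QC: 32 of 600 spectra excluded
explained variance: PC-1 64%, PC-2 13%
              non_allergic  allergic  sit
non_allergic            84         0    0
allergic                 0        84    0
sit                      0         0   87
              sensitivity  specificity  ppv  accuracy
class
non_allergic          1.0          1.0  1.0       1.0
allergic              1.0          1.0  1.0       1.0
sit                   1.0          1.0  1.0       1.0
```

The QC chart excluded 32 spectra (the T²/Q limits sit at the 95 %
confidence level, so a few percent of clean spectra are always flagged);
the first two principal components carry 64 % and 13 % of the variance and
separate the three groups; and the CNN classifies the pooled held-out test
spectra of three repeated splits perfectly at this separation level —
replicate spectra of each subject appear on both sides of a spectrum-mode
split, so this measures the pipeline's operating point rather than
subject-level generalisation (use `grouping="subject"` for the latter).

A YAML-configured end-to-end run (simulate → QC → PDS → PCA → CNN →
merits, with a manifest and per-stage artifacts) is available as
`serofir run --config run.yaml`; see also `serofir simulate`, `serofir qc`,
`serofir preprocess`, `serofir transfer`, `serofir pca`, `serofir train`
and `serofir evaluate`.

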