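# Annotated configuration for `serofir run --config run.yaml`.
# Unknown keys anywhere in this file are rejected before execution.

preset: mouse          # mouse: 3x10 subjects, 2 batches | human: 3x20, 1 batch
separation: moderate   # low / moderate / high class-effect magnitude
seed: 42               # drives simulation, splits, optimization, training
out_dir: serofir_run   # per-stage artifacts + manifest.json land here

sim:                   # SimConfig overrides (any field except the band list)
  n_replicates_per_subject: 20
  outlier_fraction: 0.02    # fraction of spectra corrupted into gross outliers

qc_enabled: true
qc:
  absorbance_min: 0.05      # AU, fingerprint-window peak must exceed this
  absorbance_max: 3.0       # AU, and stay under this
  snr_min: 50               # amide-I height over detrended noise floor
  water_vapor_max: 5.0e-4   # 2nd-derivative peak-to-peak, 1847-1837 cm-1
  variance_fraction: 0.95   # PCA rank retained for the T2/Q chart
  alpha: 0.05               # confidence level of both chart limits

transfer_enabled: true      # skipped automatically when only one batch exists
transfer:
  half_width: 7             # PDS window half-width in grid points
  rank_tol: 1.0e-6          # truncated-SVD relative cutoff
  n_transfer_subjects: 10   # paired transfer standards used to fit PDS

preprocess:
  window_low: 900           # cm-1, closed truncation window
  window_high: 1800
  sg_points: 15             # Savitzky-Golay window (odd)
  sg_polyorder: 3

pca:
  n_components: 2

classify:
  grouping: spectrum        # spectrum | subject (keeps replicates together)
  n_repeats: 10             # repeated stratified 65/20/15 splits
  bayes_budget: 15          # hyperparameter evaluations (0 = use defaults)
  max_epochs: 50
  patience: 8
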