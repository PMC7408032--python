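# Methods

`serofir` implements a complete chemometric workflow for mid-infrared
(FTIR) serum fingerprinting of three clinical groups — non-allergic
controls, allergic subjects, and subjects treated by allergen-specific
immunotherapy (SIT; oral tolerization in the mouse model) — together with
a synthetic spectrum generator that stands in for the non-public cohort
data.  This note records the models, their assumptions, the defaults and
why, and what the synthetic benchmarks do and do not demonstrate.

## The synthetic serum spectrum model

A measured absorbance spectrum is modelled as

    y(w) = b · g^k · x(w − k·Δ) + a + p(w) + c · v(w) + ε(w)

where

* `x(w) = Σ_j A_j · e_j(class) · f_j · G_j(w)` is the noiseless subject
  spectrum: a sum of Gaussian bands `G_j` (truncated to compact support at
  ±4σ), each with base amplitude `A_j` (AU), a per-class multiplicative
  effect `e_j`, and a per-subject log-normal factor `f_j`;
* `(a, b)` are per-measurement scatter offset and gain (film-thickness and
  scatter variation), `p(w)` a random polynomial baseline, `v(w)` a fixed
  comb of narrow water-vapour lines with a random per-measurement
  coefficient `c`, and `ε` white noise;
* `k` is the batch index: batch `k` shifts the grid by `k·batch_shift`
  (linear interpolation) and scales the response by `batch_gain^k`,
  emulating a second experiment/instrument state.

Band truncation at ±4σ is deliberate: it makes between-class differences
*exactly* zero outside the bands whose class effects differ, a property the
test suite asserts literally (an untruncated Gaussian is nowhere zero).

**Grid.** Default 500–4000 cm⁻¹ at 1.5 cm⁻¹ spacing, with grid points
anchored at integer multiples of the step.  This anchoring puts 900 and
1800 cm⁻¹ on the grid, so the closed fingerprint window holds exactly
601 points (2333 points overall).

**Bands.** Thirteen bands with centres inside the canonical serum
assignments — ester carbonyl 1740, amide I 1655, amide II 1545, CH₂ 1455,
amide III/collagen 1400–1310, phosphate diester 1240, carbohydrates
1165/1120/1080/1030 cm⁻¹ — plus two broad out-of-window bands (amide A
3300, CH stretch 2930) so that the full-grid QC sees realistic structure.
Exact centres and amplitudes are configuration, not physics.

**Class effects.** The allergic class perturbs the ester band (+10 %) and
the amide I/II bands (−8 %); the treated class perturbs the carbohydrate
bands (+8 %).  Quantitative effect sizes for serum compositional change are not
established; these magnitudes are benchmark choices that produce moderate
separation, exposed through the `separation` knob (`low`/`moderate`/`high`
scale the deviations by 0.5/1/2).

**Presets.** `mouse`: 3 groups × 10 subjects, 2 measurement batches,
subject factor σ = 0.05 (genetically identical animals, two independent
experiments).  `human`: 3 groups × 20 subjects, 1 batch, σ = 0.10
(heterogeneous cohort).  Both use 20 replicate spectra per subject.
Default artifact levels: scatter gain σ 0.08, offset σ 0.01 AU, quadratic
baseline with coefficient σ 0.005 AU, noise σ 0.0015 AU, water-vapour
coefficient σ 0.001 AU.  These were chosen once to give raw-spectrum
signal-to-noise of a few hundred, typical of transmission measurements of
dried serum films.

**Determinism.** Subject-level draws are keyed by (seed, class index,
subject index) and replicate-level draws additionally by replicate index,
so enlarging the design (more replicates or subjects) never changes
existing draws; equal configuration gives bit-identical datasets.

**Gross outliers.** `floor(fraction · n)` spectra (at least one when the
fraction is positive) are corrupted by one of: 10× amplitude scaling, a
saturated flat-top segment pinned at 6 AU, or an added baseline ramp up to
6 AU — all far outside the clean envelope, emulating failed films or
detector saturation.

What the generator does **not** emulate: Mie scattering and its resonant
distortions, atmospheric CO₂ bands, correlated (pink) detector noise,
instrument line-shape/apodization effects, metabolite covariance structure
between bands, or any real biochemical effect size.  Passing benchmarks
therefore demonstrate that the *pipeline machinery* recovers a signal of
the assumed structure at realistic noise — not that real sera are
classifiable at these rates.

## Quality control

Stage one re-specifies the three classical per-spectrum checks with
explicit windows (the vendor tool's rules are proprietary):

* **absorbance**: max in 1800–900 cm⁻¹ within [0.05, 3.0] AU;
* **signal-to-noise**: amide-I peak height in 1700–1600 cm⁻¹ above a
  straight baseline through the window edges, divided by the standard
  deviation of the linearly detrended 2200–1900 cm⁻¹ region (band-free);
  floor 50;
* **water vapour**: peak-to-peak of the Savitzky–Golay second derivative
  in 1847–1837 cm⁻¹ (two comb lines of the generator sit in this window);
  ceiling 5·10⁻⁴ AU/(cm⁻¹)², about four times the 99th percentile of the
  clean-data score at default artifact levels.

Stage two fits PCA to the mean-centred raw spectra, retaining the smallest
rank `k` reaching 95 % cumulative variance, and flags spectra on the
Hotelling T² versus Q-residual chart: `T²_i = Σ_{j≤k} t_ij²/λ_j` with the
F-based control limit `k(n−1)/(n−k)·F_{0.95}(k, n−k)`, and
`Q_i = ‖x_i − x̂_i‖²` with the Jackson–Mudholkar limit computed from the
residual eigenvalues.  A spectrum passes QC iff it passes all three checks
and sits at or under both limits.  With an OR-exclusion at α = 0.05 the
clean-data exclusion is ≈ 5 % (T²) + ≈ 5 % (Q) minus overlap, i.e. about
10 % — the documented price of the declared confidence level; gross
corruptions are excluded with full recall in the seeded benchmark.

## Preprocessing

Fixed order: (i) truncation to the closed 1800–900 cm⁻¹ window; (ii)
Savitzky–Golay second derivative, 15-point window, cubic fitting
polynomial, physical-step scaling (units AU/(cm⁻¹)²), with the 7 edge
points at each end dropped rather than padded so no fabricated values
enter classification; (iii) multiplicative scatter correction against the
mean of the (training) data — per spectrum the OLS fit `x = a + b·ref` is
inverted as `(x − a)/b`; (iv) unit vector normalization; (v) scaling —
mean-centering feeds PCA, per-wavenumber standardization feeds the CNN,
both fitted on training rows only and reused on held-out rows.

The cubic fitting order is the common chemometrics choice compatible with
a second derivative at 15 points.  The SG estimator's bias grows with
(window/band-width)²: the analytic-oracle test verifies the ≤ 2 %
agreement at σ = 40 cm⁻¹, a band the 15-point window resolves; narrower
bands (amide I, σ ≈ 18) are reproduced with proportionally larger
smoothing bias, which is immaterial here because every spectrum passes the
identical filter.

## Calibration transfer (PDS)

Piecewise Direct Standardization maps each slave-batch wavenumber `j` from
the slave window `[j−h, j+h]` (default h = 7 points ≈ ±10.5 cm⁻¹) plus an
intercept onto the master value at `j`, solved per window by truncated SVD
(relative cutoff 1e-6) on paired transfer measurements and assembled into
one banded operator.  The windowed regressions have `2h+2` free parameters,
so the transfer set must comfortably exceed that: the shipped pairing
helper emits `n_subjects × n_replicates` paired measurements (default
10 × 4 = 40) of identical underlying subject spectra measured under both
batch responses.  All-constant windows (possible with compact-support
bands) fall back to an intercept-only map.  PDS is fitted on truncated raw
absorbance — standardization corrects the instrument response, which
precedes chemometric correction.

## Unsupervised stratification

PCA by SVD of mean-centred spectra; explained-variance fractions use all
eigenvalues in the denominator ("PC-1 73 %"-style reporting); loading signs
are fixed by making each row's largest-magnitude element positive, so runs
are bit-reproducible.  Group clouds in (PC-1, PC-2) are summarised by
chi-square confidence ellipses (semi-axes `sqrt(λ_i · χ²₂(level))`).
Mardia's multivariate skewness (`n·b1/6` against χ² with d(d+1)(d+2)/6 df)
and kurtosis (z against `d(d+2)` with variance `8d(d+2)/n`) screen the
score distribution for normality, deciding parametric versus nonparametric
framing; Royston's test is not implemented (the screen's outcome rests on
Mardia alone).  PCA runs on all replicate spectra, not per-subject means.

## Supervised classification

**Architecture.** A 1-D CNN: `section_depth` blocks of
conv(filter_size) → ReLU → max-pool(2), then two further conv+pool blocks,
then flatten → dense(64) → ReLU → dropout(0.3) → dense(3) → softmax.
Filter counts double per block from `n_filters`, capped at 32 (the cap
bounds single-CPU training cost).  With this flatten-dense head, total
parameter counts need not grow with depth — extra pooling shrinks the
dominant dense layer — but the feature-extraction stack strictly gains
parameters, which is what the depth test asserts.  A global-average-pool
head (which would make totals monotone) was evaluated and rejected: it
collapsed benchmark accuracy.

**Training.** Plain SGD with momentum and L2 weight decay on weight
matrices (biases undecayed) minimising softmax cross-entropy, batch 32,
at most 50 epochs.  Early stopping monitors the validation classification
error: training stops once the error has not improved for `patience = 8`
epochs (validation loss breaks ties at equal error) and the best-validation
weights are restored.  Divergence (non-finite loss) raises a labelled
error; the campaign driver retries a diverged repeat at half the learning
rate.  The network runs in single precision; trained-weight bit
reproducibility is therefore best-effort, while split tables, traces and
confusion matrices are exactly reproducible for a fixed seed.

**Splits.** A stated 65/20/15 train/validation/test split combined with
"10-fold cross-validation" is internally contradictory (15 % ≠ 1/10), so
the default is *repeated hold-out*: 10 independent stratified 65/20/15
splits with largest-remainder rounding inside each class stratum, test
predictions pooled over repeats; a strict k-fold mode (test = fold,
remainder split 65:20) is available.  Grouping is by subject (all
replicates of a subject share one subset — no replicate leakage) or by
spectrum (the literal reading of "65 % of the spectra"); the shipped
benchmark uses spectrum grouping and therefore measures the pipeline's
operating point on replicate-structured data, not subject-level
generalisation — both modes are exercised in the tests.

**Hyperparameter search.** Bayesian optimization over section depth
(1–3), log-uniform learning rate (1e-3–1e-1), momentum (0.5–0.95),
log-uniform L2 (1e-6–1e-2), filter size {3,5,7,9} and filter count (4–16):
a Gaussian-process surrogate (Matérn 5/2, normalised outputs) with
expected-improvement acquisition over 512 random candidates per iteration,
after 5 random initial points; budget 15 evaluations on the first split's
validation error with a shortened schedule (≤ 30 epochs), then the best
point trains every repeat in full.  Failed evaluations (divergence) are
recorded as NaN and skipped by the surrogate.  A pure random-search
fallback flag exists.

**Merits.** Pooled test predictions form one confusion matrix in the fixed
class order (non-allergic, allergic, SIT).  Per class, one-vs-rest TP, TN,
FP, FN give sensitivity TP/(TP+FN), specificity TN/(TN+FP) and PPV
TP/(TP+FP); overall accuracy is trace/total.  Zero-denominator rates are
explicit NaN markers, never silent zeros.  The confusion structure exports
as a chord-diagram edge list (true class → predicted class, weight =
count); graphical rendering is out of scope.

## Benchmarks and problem sizes

The shipped reference benchmark (`serofir.benchmark.human_benchmark`) is
the human preset at moderate separation, generator seed 42 (1200 spectra),
QC at defaults, Bayesian budget 15, 10 repeated splits — roughly five
minutes on one CPU; the clean-QC benchmark uses generator seed 7.  The two
generator seeds are part of the benchmark definitions; the training seed is
free.  Unit tests run on shrunk designs (coarser 3 cm⁻¹ grids, 4–8
subjects per class, fewer replicates) chosen so the whole suite stays
fast while every contract is still exercised at full fidelity.

## Known limitations

* The QC thresholds are a surrogate for a proprietary vendor tool; they
  share the three named criteria, not its numeric rules.
* The OR-combination of T² and Q at α = 0.05 excludes ≈ 10 % of perfectly
  clean data by construction; practitioners wanting the literal ">95 %
  pass" behaviour should raise the confidence level.
* Spectrum-grouped splits measure replicate-level discrimination;
  subject-grouped splits are the honest generalisation estimate and give
  lower numbers on hard (low-separation) settings.
* JCAMP-DX support covers the XYDATA `(X++(Y..Y))` and XYPOINTS dialects
  with AFFN and SQZ/DIF/DUP ordinates only.
* The CNN is a NumPy implementation tuned for sub-thousand-point spectra
  on a single CPU; it is not a GPU training framework.
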