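# Methods

## Scope and model

`phenospec` turns per-sample reflectance spectra into a binary phenolic
class call. The statistical model is deliberately simple: a spectrum is a
latent "clean" trace distorted by per-sample multiplicative/additive
scatter, and phenolic content modulates the clean trace through a fixed,
band-limited signature. Preprocessing inverts the scatter model, feature
extraction compresses each trace to 22 scalar statistics, and an
imbalance-aware repeated cross-validation protocol estimates how well the
statistics predict the class.

## Synthetic cohorts

The generator's forward model per sample *j* is

    s_j = a_j · (ref + boost_j + c · g(TPC_j) · signature) + b_j + ε

with `a_j = exp(N(0, scatter_slope_sd))`, `b_j ~ N(0, scatter_offset_sd)`,
band-wise noise `ε ~ N(0, noise_sd)`, and `g(TPC) = (TPC − μ)/σ` the
standardized phenolic content. Defaults are the study conditions:

| parameter | default | units / meaning |
|---|---|---|
| n_cultivars × n_cuts × n_replicates | 26 × 3 × 3 | ≈234 samples |
| wavelength grid | 355–1700 nm, 2 nm | 673 bands |
| tpc_mean, tpc_sd | 28.8219, 5.4564 | mg GAE/gDW |
| class_effect *c* | 0.02 | reflectance units per SD of TPC |
| scatter_slope_sd / offset_sd | 0.10 / 0.02 | log-slope SD / offset SD |
| noise_sd | 0.005 | reflectance units per band |
| cut1_reflectance_boost | 0.05 | added to cut-1 clean traces |

The reference trace is a smooth vegetation-like curve (low visible
reflectance, green bump at 550 nm, red edge near 715 nm, NIR plateau,
water-absorption dips at 970/1200/1450 nm), deterministic given the grid.
The class signature is a frozen unit Gaussian bump at 600 nm (width 40 nm,
clipped to 500–700 nm) — the pigment-sensitive window — so feature
selection has a stable localized signal to find. TPC is truncated at zero
by resampling, preserving approximate normality; scatter is applied before
noise so MSC inverts exactly the distortion it models. Replicates default
to 3 per cultivar × cut because the emulated study's replicate layout is
unpublished; 26 × 3 × 3 matches its cohort size to first order.

What the generator does **not** emulate: instrument line shape, detector
noise correlation across bands, cultivar-specific spectral baselines,
non-normal empirical TPC distributions, or any radiative-transfer physics.
Passing tests therefore demonstrate pipeline correctness and statistical
behaviour under the stated model, not performance on real spectra. In
particular, the study this emulates observed a 91/229 ≈ 0.40 low-class
fraction where a normal TPC model implies Φ(−1) ≈ 0.16 — the empirical TPC
was evidently not normal, and the generator reproduces the stated moments,
not that skew. Injected outliers are constant reflectance offsets sized in
units of the cohort's summary SD; they are detectable by the z-score filter
by construction but, being pure additive shifts, would also be absorbed by
MSC — tests exercise the filter on uncorrected cohorts.

## Preprocessing

MSC fits `s ≈ a·ref + b` by ordinary least squares over bands and corrects
with `(s − b)/a`; the reference defaults to the band-wise mean of the input
set (standard MSC), computed once per call. Slopes below 1e-8 in magnitude
are an error naming the sample. Corrected values are floored at 0 to keep
reflectance physical.

Outlier removal z-scores one scalar per record — its mean reflectance
across bands — using the sample SD (n−1), and removes |z| > 3 in a single,
non-iterative pass. The alternative (per-band z-scores with any-band
exceedance) is far more aggressive and was rejected; the chosen convention
is recorded in the `PreprocessReport`. Zero-variance summaries remove
nothing and log a warning.

Cut comparison uses Welch's unequal-variance t-test on per-sample mean
reflectance for every cut pair — the safer default when group variances
may differ with plant age.

Stage order is subsample → MSC → outlier removal; the MSC reference is
computed after subsampling and not re-derived after removals.

## Features

Time-domain variance uses the n−1 denominator; skewness and kurtosis use
population (1/n) third/fourth moments over SD powers, and kurtosis is
non-excess (a Gaussian signal scores 3). The margin factor is
`max/((1/n)Σ√|s_i|)²`, the conventional fourth member of the
crest/form/pulse family. The band power spectrum is the unnormalized
real-input DFT magnitude squared, one-sided with the DC term included
(length ⌊n/2⌋+1); all eight frequency statistics are scale-covariant, so
any fixed transform convention is internally consistent — this one is
frozen for reproducibility. Constant or zero-mean inputs raise a
degenerate-input error naming the undefined statistics rather than
returning NaN.

Feature standardization is z-scoring with the population-SD convention,
always fitted on training data only (inside each CV fold, after
balancing) and applied to held-out data with the stored parameters —
no leakage from test folds.

## Cross-validation protocol

Ten repetitions of five-fold CV, fold partitions shuffled (unstratified;
a stratified option exists, off by default). Per training fold, in order:
undersample the majority class to the minority count (without
replacement), fit standardization, run RFECV (logistic-regression
estimator, elimination step 1, 3-fold stratified inner CV, accuracy),
grid-search the classifier hyperparameters (3-fold, accuracy), fit, score
the untouched test fold. Each sample collects exactly R out-of-fold
probabilities; R×K fit records keep the selected features, chosen
hyperparameters and test-fold membership.

Seeding is counter-based: the master seed fans out through
`SeedSequence(entropy=master, spawn_key=(rep, fold, stage))`, so any
single fit is reproducible in isolation and all derived seeds stay below
2³¹. Tree and naive-Bayes families are bit-deterministic given the seed;
the neural network is reproducible under its fixed framework seed.

The neural network is a feedforward classifier with two ReLU hidden
layers sharing one tuned width (20/40/60), trained by adaptive-moment
gradient descent on binary cross-entropy with tuned epochs (50/100/150)
and batch size (16/32/64); the batch size is clipped to the training-fold
size when the balanced fold is smaller. Gradient-boosted trees expose the
five conventional knobs (n_estimators, min_child_weight, gamma, subsample,
max_depth); random forest and Gaussian naive Bayes carry small
conventional grids. The grid search is a deterministic loop over the
combination product with a first-combination tie-break; a one-combination
grid skips the search. Tests and examples use compact single-combination
grids and cohorts of ~150–250 samples so full 10×5 runs complete in tens
of seconds; the default grids implement the full tuning protocol.

## Metrics

The ROC sweeps thresholds over the unique observed scores plus a +∞
sentinel under "predict positive iff score ≥ t"; AUC is the trapezoidal
area and equals the tie-corrected Mann–Whitney pairwise concordance.
Accuracy uses the strict rule (predict 1 iff score > 0.5): a score of
exactly 0.5 counts as class 0. The a20-index is m20/n with both the 0.2
and 0.8 boundaries inclusive. The Youden threshold maximizes J = TPR −
FPR with ties broken to the smallest threshold. Headline aggregation:
AUC on per-sample median scores (per-repetition AUCs also reported);
accuracy averaged over the R×K test folds (a pooled variant derives from
the median scores); a20 averaged over repetitions. High-confidence
selection keeps samples with aggregate score ≥ {0.8, 0.9, 0.95} whose
laboratory label is normal-to-high, counted per cut.

## Numerical and design choices

- Threshold = mean − 1·sample SD of the full TPC cohort, derived once
  before CV: it defines the target, not a learned parameter.
- Ties at the threshold label as normal-to-high (≥, not >).
- MSC exactness tolerance 1e-10; feature-oracle agreement asserted at
  1e-9 relative; ROC identities at 1e-12.
- Machine learning defaults to cuts 2–3 (`cuts_for_ml=(2, 3)`): the
  youngest harvest's spectra differ systematically and would confound the
  phenolic signal with age.
- Degenerate inputs fail loudly with the sample named; the pipeline
  aborts at the failing stage rather than propagating NaN.

## Known limitations

- The synthetic class signal is a single fixed bump; real phenolic
  signatures spread over multiple bands and interact with water/pigment
  features.
- The MSC reference is the cohort mean; with many outliers the reference
  itself is contaminated (removal happens after correction, mirroring the
  emulated order).
- Constant-offset injected outliers are invisible to the filter if MSC
  runs first; shape-distorting outliers are not simulated.
- AUC confidence intervals, calibration analysis and multi-class targets
  are out of scope.
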