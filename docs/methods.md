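# Methods

## Problem and model

`phenoyield` models end-of-season maize grain yield at the breeding-plot
level from three time-resolved input streams: per-plot hyperspectral canopy
reflectance (VNIR, 400–1000 nm), normalized-height LiDAR point clouds, and
cumulative weather. Each plot contributes a sequence over seven acquisition
dates spanning V8 to R5; per date the inputs are reduced to 9 spectral
features (two band-range integrals, the NIR first-derivative integral, and
the indices VOG3, NDRE, MCARI2, DATT3, PSRI, RDVI), 7 canopy-structure
features (P75/P90 height, quadratic mean height, 8 cm column voxel volume,
canopy cover at the 20th/50th/75th percentile heights) and 3 weather
accumulations (growing degree days, precipitation, radiation since
planting).

Three sequence models map these tensors to yield:

1. **Vanilla stacked LSTM** — all modalities concatenated per date (early
   fusion), a 2-layer LSTM, linear head on the final hidden state.
2. **Attention LSTM** — the same encoder plus additive (Bahdanau-style)
   attention scored per (date, feature) pair with a joint softmax, so each
   plot carries an interpretable weight map over dates and features that
   sums to one. An optional mid-season gate masks the attention support to a
   configured date subset.
3. **Multi-modal late fusion** — one attention branch per remote-sensing
   modality (each concatenated with weather along its own date axis); branch
   context vectors are fused by two sigmoid dense layers into a single
   prediction, and branch-specific auxiliary losses are blended into the
   total loss (gradient-blending in the loss-weighting sense).

Training uses Adam at learning rate 0.001 on MSE with targets min-max
scaled to [0, 1] from the training split (the sigmoid fusion head requires a
bounded target), dropout 0.2 after each LSTM layer, minibatches (default
64; the bundled experiments use 32), and early stopping on validation MSE
(patience 25 by default; the bundled experiments use patience 100 with up
to 1000 epochs). The best-validation
parameter snapshot is restored after fitting. Evaluation uses R² measured
against the 1:1 observed-vs-predicted line, 1 − SSres/SStot (a printed-form
flag returns the bare ratio), and RMSE.

The networks are implemented on a small reverse-mode automatic
differentiation engine over numpy (`phenoyield.nn`): broadcasting
arithmetic, batched matrix products, tanh/sigmoid/exp/log, reductions and
shape ops. Gradient correctness is verified against central finite
differences in the test suite, end to end through the LSTM + attention
stack.

## Architecture choices that were genuinely open

- **Per-(date, feature) attention decomposition.** Scores are
  `v·tanh(W_h h_t + u_f + x_{t,f} s_f + D_t + b)` with `h_t` the top LSTM
  hidden state, `u_f`/`s_f` learned per-feature keys, and `D_t` a learned
  per-date key (positional embedding) that is zero-initialized so the
  initial attention carries no date preference. The context vector is the
  weight- and value-weighted sum of learned per-feature embeddings. The
  per-date key exists because the hidden state alone discriminates dates
  only weakly; without it, temporal importance converges too slowly to be
  interpretable at desk scale.
- **Query.** A learned query (implicit in `v`) is the default; a
  final-hidden-state query is a config option.
- **Blend weights.** Default (1.0, 0.1, 0.1) for (fusion, branch, branch).
  Larger auxiliary weights drag the fusion optimum toward the
  single-modality solutions and measurably reduce held-out accuracy. An
  "auto" mode re-estimates branch weights every 10 epochs from
  overfitting/gain ratios; it is a documented approximation of
  gradient blending, not a reproduction of the original schedule.
- **Scenario date axes.** When a scenario gives the two modalities different
  date sets, the early-fusion models place features on the union of dates
  with zeros (the post-standardization mean) where a modality was not
  acquired; the late-fusion branches keep their native axes. Weather
  follows the union of retained dates.
- **Network width.** 2 layers × 32 units, attention dim 16, context dim 16
  by default — sized for ~500-plot trials with 19 features; all
  config-exposed.

## Numerical conventions

- Band lookup is nearest-band with ties to the lower wavelength (2.2 nm
  spacing makes interpolation differences negligible).
- Vegetation indices are computed per pixel over the OSAVI vegetation mask
  (soil factor 0.16, default threshold 0.4) and then averaged; zero
  denominator pixels are dropped with a logged count.
- Band-range integrals use the trapezoid rule on the band grid with linear
  interpolation at range endpoints. The NIR derivative integral uses
  per-interval finite-difference slopes integrated with overlap weights, a
  pairing that telescopes exactly to the interpolated S(λb) − S(λa); a
  central-difference/trapezoid pairing would leave an O(h²) ≈ 1e−4
  discrepancy at this band spacing. The derivative feature's range is
  910–1000 nm.
- RDVI is implemented with the plain sum denominator used in our feature
  table; the canonical square-root form is a flag. VOG3 is implemented as
  printed, with the (ρ734 − ρ747) numerator that is negative on green
  vegetation.
- Height percentiles interpolate linearly between order statistics. Canopy
  cover takes its threshold from non-ground heights but counts
  strictly-above returns over all returns, so closed canopies score high
  instead of trivially returning 1 − p/100. Voxel volume is 2.5D column
  volume at 8 cm cells.
- Genetic PCA centers but does not variance-scale dosages (flag available).
  The elbow rule normalizes the scree to the unit square and retains the
  components before the point of maximum distance to the first–last chord;
  on the L-shaped screes that cluster-structured marker data produce, the
  max-distance point is the first noise component. A matrix with six
  structure axes therefore selects six components.
- Stratified folds allocate per-cluster counts by largest remainder with
  seeded tie-breaks: per fold 20% test, then a 90/10 train/validation split
  of the remainder, all per cluster.

## The synthetic trial generator

Real trials of this design are not redistributable, so the generator
emulates their statistical structure with planted, recoverable ground
truth:

- **Genetics.** A varieties × markers dosage matrix in {0,1,2}; each marker
  has a base allele frequency and cluster-specific deviations scaling with a
  divergence parameter. By default two clusters: doubled-haploid hybrids
  (95%) and replicated check hybrids (~5% of plots), mirroring a
  two-population PCA structure. Checks are excluded before folding.
- **Season.** A sinusoidal temperature season with stochastic precipitation
  and radiation; GDD accumulates under the base-50 °F/cap-86 °F maize rule.
  The seven acquisition dates are placed where cumulative GDD crosses
  (499, 857, 1222, 1494, 1660, 1803, 2288) — V8 through R5.
- **Canopy.** Logistic-in-GDD height and cover growth, a rise-then-senesce
  chlorophyll curve, and an NIR plateau tracking biomass. Each plot has
  persistent structural and chlorophyll traits (~10% of scale) and each
  (plot, date) has independent idiosyncratic deviations (~15–25%) drawn
  separately per channel. The idiosyncratic share must dominate for
  per-date importance to be identifiable at all: if plot traits persist
  across the season, every date carries the same information and "which
  date mattered" is ill-posed. Channel independence (height/cover vs
  chlorophyll/plateau) keeps the two modalities' planted signals separable.
- **Spectra and point clouds.** Reflectance curves are monotone-PCHIP
  visible control points blended into the NIR plateau through a logistic red
  edge whose inflection shifts with chlorophyll (705–735 nm); pixels add
  Gaussian noise and clip to [0, 1] with a warning. Point clouds place
  ground returns at height zero with fraction 1 − cover and canopy returns
  from a truncated normal, uniformly over the row-trimmed 4.575 m × 1.5 m
  plot (0.40 m trimmed per row end).
- **Yields.** Per modality, the planted per-date signal is the leading
  principal axis of that date's standardized features (canopy vigour /
  chlorophyll status) weighted by the planted importance profile; each
  modality part is normalized to unit variance so the profile, not the
  coefficient draw, sets the shares. The sum is rescaled to a signal SD of
  9 (arbitrary bu/ac-like units around a mean of 150), a per-cluster
  effect is added, and observation noise is N(0, 3), giving an oracle R² of
  0.9. Coefficients, profiles and effects are returned as ground truth. A
  leading-axis signal (rather than a random coefficient draw) keeps the
  planted signal well-conditioned despite strong collinearity among height
  percentiles and among chlorophyll indices. Default profiles put all
  LiDAR importance on the 3rd date and all hyperspectral importance on the
  5th; `full_season_profiles()` gives season-spanning profiles peaked at the
  same dates for the scenario experiments.

What the generator does **not** emulate: radiative transfer (no PROSAIL),
spatial autocorrelation between plots, sensor geometry or occlusion in
point clouds, genotype-specific growth-curve shapes, or missing acquisition
dates. Passing tests therefore demonstrate that the pipeline recovers
structure it is designed to recover under clean conditions — not
field-level accuracy.

## Experiment battery and problem sizes

The bundled experiments (`phenoyield.experiments`) run 500-plot, 7-date
trials with 250 varieties × 2000 markers; after check exclusion, splits are
20% test / 10% validation / 70% train. The experiments are:

- **Attention recovery** — per-modality attention models; the averaged
  temporal profile should peak at the planted dates, with the LiDAR peak at
  or before the hyperspectral peak.
- **Architecture comparison** — the fused network against each
  single-modality model on the same split.
- **Scenario comparison** — the attention model under scenario 1 (all
  dates), 2 (first three dates) and 3 (early LiDAR vs shifted
  hyperspectral dates) on a full-season-signal trial.
- **Noise-free identifiability** — the fused network on a noise-free trial
  (held-out R² should approach 1).

The test suite runs each battery over five seeds; `scripts/acceptance.py`
reports medians over three seeds, alongside exact-agreement checks of every
feature formula and accuracy metric against independently coded oracles.

## Known limitations

- Single-modality predictive accuracy is modest by construction (each
  modality carries half the planted signal) and those fits overfit freely;
  only their attention maps, not their accuracies, are the deliverable.
- The gradient-blending "auto" mode is a heuristic reweighting, not the
  published schedule.
- The elbow rule is one convention among several; screes without a plateau
  fall back to one component with a warning.
- Training is single-threaded numpy; the defaults are sized for hundreds of
  plots, not thousands.
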