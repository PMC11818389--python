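# Methods

## Problem and approach

An RF ablation lesion can be terminated by three different stopping
rules: reaching an Ablation Index (AI) target, reaching a Lesion Size
Index (LSI) target, or reaching the plateau of the local-impedance (LI)
drop. AI and LSI are proprietary — their functional forms are published,
their coefficients are not — and LI-guided platforms report neither
index. The package therefore (1) trains per-timepoint surrogate
regressors for AI and LSI on traces where the index is known, and
(2) applies them to LI-guided traces so the three stopping times can be
compared lesion by lesion.

Since no clinical exports are distributable, the package works on a
synthetic cohort with *stand-in* index constants. This changes what
results mean: nothing here estimates the true proprietary coefficients
or the clinical durations, but every stage of the machinery — integration,
filtering, plateau detection, surrogate training, statistics — is checked
against exact ground truth that the generator knows.

## Index oracles

- **AI**: `AI(τ) = K (∫₀^τ CF^a P^b ds)^c`, cumulative composite Simpson
  on the uniform grid, outer exponent `c` applied to the integral and `K`
  outside. The alternative nesting (exponent inside) can be emulated via
  the configurable constants; the adopted grouping is the one in which
  the formula is dimensionally coherent.
- **LSI**: sum of two saturating terms (force, squared current) times a
  time factor normalized to equal exactly 1 at τ = 60 s. The grouping is
  exposed as one pluggable expression; the saturation bound is b0 + b2.
  F and I are 6 s *trailing* window means, truncated at the trace start
  (edge handling is otherwise unspecified in the published form).
- **RF current**: I = √(P/Z) (Ohm's law for AC), reported in mA.

Default constants are never hard-coded "true" values: they are produced
by `calibrate_constants`, which solves for K (given exponents
a = 0.6, b = 1.4, c = 0.35) so AI crosses 400 at 7 s under the reference
inputs CF = 15 g, P = 40 W, and scales (b0, b2) jointly (given
b1 = 10 g, b3 = 2.5·10⁵ mA², b4 = 0.75, b5 = 20 s) so LSI crosses 4 at
20 s under F = 15 g, I = 500 mA. A `saturation_cap` bounds the
admissible b0 + b2, rejecting targets that would demand implausibly
steep saturating terms. The calibration times (7 s and 20 s) straddle
the LI-plateau times the generator produces (~7–13 s), which is what
creates the AI < LI < LSI ordering the comparison stage should detect.

### Numerical caveats

- Cumulative Simpson is exact (to round-off) on polynomial integrands of
  degree ≤ 3 *at paired-interval (even) indices*; at interior odd indices
  the quadratic interpolant is exact only to degree 2. On
  noise-dominated integrands the interpolant can overshoot, producing
  μ-scale local decreases of the cumulative integral; monotonicity of the
  index series is guaranteed only for integrands resolved by the grid
  (at 997 Hz, any physiological CF signal).
- Target crossing uses the first grid sample ≥ target with no sub-sample
  interpolation; at 997 Hz the induced error is ≤ 1 ms (stride-s
  prediction grids raise this to s/997 s).

## Synthetic cohort

Noiseless LI model: `LI(t) = li0 − drop·(1−e^{−t/τ}) + rebound·t`,
which has exactly one interior minimum at
`t* = τ·ln(drop/(rebound·τ))` — the ground-truth plateau. The linear
drift term runs from t = 0 (rather than switching on at the plateau):
this is the simplest form with a guaranteed, analytically known,
tunable minimum. White noise is added per raw sample; raw sampling is
irregular (±30% uniform jitter on nominal gaps) so resampling is
genuinely exercised. Contact force is an AR(1)-smoothed wobble
(correlation time 1 s) around the per-lesion mean, so 6 s windowed CF
differs from instantaneous CF. Lesion centres sit at equal angles on a
ring plus isotropic jitter; tips scatter around their centre per sample.

Default study conditions (chosen once to match the clinically reported
summary scales, and so that every stage operates in its intended
regime):

| parameter | default | rationale |
|---|---|---|
| duration | 28 s | covers the slowest LSI crossings; leaves a censored tail |
| CF mean | lognormal, median 18 g (σ=0.35), clipped 6–40 g | clinical median ≈ 18 g |
| power | 40 / 45 / 50 W per lesion | the reported generator settings |
| LI start | N(146.6, 8) Ω | clinical median ≈ 147 Ω |
| LI drop | lognormal, median 24 Ω (σ=0.25) | clinical drops ~14–28 Ω |
| decay τ | U(2.0, 3.5) s | plateau at 7–13 s, between AI and LSI times |
| rebound | U(0.25, 0.5) Ω/s | minimum curvature rebound/τ large enough for the 1.5 s filter to localize the plateau under 0.5 Ω noise |
| noise SD | 0.5 Ω | visible on a ~20 Ω drop |
| raw rate | 400 Hz | fast raw sampling keeps interpolated noise nearly white |
| ring | 30 lesions, r = 17.5 mm, jitter 0.3 mm | chord 2r·sin(π/30) ≈ 3.66 mm, the clinical ILD scale |

What the generator does **not** emulate: lesion biophysics (temperature,
steam pops), catheter instability and respiration, segment-dependent
targets, inter-patient covariance structure beyond independent per-lesion
draws, and any real relationship between LI dynamics and the true
(unknown) indices. Passing tests therefore demonstrate correctness of
the *pipeline*, not clinical validity of the stand-in constants.

Missing LSI durations arise naturally (lesions whose predicted LSI never
reaches 4 within the trace — low-CF lesions, hence MAR-like), and can be
injected explicitly (MCAR uniform, or MAR with rank-linear deletion
probability in a driver covariate at a controlled expected rate) with a
truth mask for recovery tests.

## Trace processing

- Resampling: linear interpolation of every channel onto a uniform
  997 Hz grid within the raw span (no extrapolation).
- LI filter: moving mean over round(1.5 s · fs) samples, forced odd,
  centered (a trailing variant is available); shrinking windows at the
  edges. One full window length is trimmed from the left edge, where the
  output is partially supported — so `li_start` is the filtered value at
  ≈1.5 s after RF onset, and measured LI drops are smaller than the
  generator's asymptotic `drop` parameter. The right edge keeps
  shrinking-window means so a plateau near the trace end stays defined.
- Plateau: the global minimum of the filtered LI. On a drop-then-rebound
  trace this is the interior local minimum, and the rule is
  deterministic; a strict-local-minimum detector with a prominence
  threshold exists as an option. A minimum on the last sample sets a
  `no_rebound` flag (the automated stand-in for visual confirmation).
  The centered mean biases the minimum of an asymmetric valley toward
  the shallower side; for the generator's exponential-plus-linear shape
  the bias is `τ·ln((2τ/w)·sinh(w/2τ))` (≈ 30–40 ms at defaults), which
  the noiseless recovery tests use as their tolerance.
- `cf_start` is the mean CF over the first 1 s (a single first sample
  would be noise-dominated); `cf_mean` is over the whole lesion.
- ILD: per lesion, Euclidean distance to the nearest *other* lesion's
  mean tip position within the same procedure (spatial nearest
  neighbour, k = 1, self excluded); singleton procedures yield missing.

## Surrogate models

Feature sets mirror each formula's inputs — AI: (τ, CF, FTI, P);
LSI: (τ, 6 s windowed CF, 6 s windowed current, P). Current for the
feature tables is derived from a lightly smoothed (untrimmed, centered)
LI so features exist from τ = 0. Splits and CV folds are grouped by
lesion: row-level splits would leak near-identical neighbouring
timepoints of the same lesion into both partitions. The protocol is a
grouped 70/30 holdout, grid-search CV (10-fold, grouped) on the 70%,
metrics (R², MAE) on back-transformed predictions for the held-out
lesions. The LSI target can be quantile-transformed to a normal
reference (invertible on the training range). Default grids are small
implementer-chosen ranges (tree count/depth; regularization strength);
the gradient-boosting family is implemented with the histogram-based
regressor, which fits the ~5·10⁵-row tables in seconds. Tables default
to stride-10 downsampling of the 997 Hz grid (desk-scale runtimes;
stride 1 is supported). Prediction on a trace flags (never rejects)
rows whose features leave the training range by more than 1% of that
range; an optional isotonic post-pass enforces a monotone series.

## Cohort statistics

- Exclusions: strictly over 30 s (LI-guided, i.e. actually delivered,
  duration) or strictly over 6 mm ILD; boundary values retained; missing
  ILD never excludes. Filters commute and are idempotent.
- Little's MCAR test: EM estimates (ML, multivariate normal) of mean and
  covariance under missingness; statistic
  `Σ_j n_j (ȳ_oj − μ̂_oj)' Σ̂_oj⁻¹ (ȳ_oj − μ̂_oj)` over missingness
  patterns, df = Σ|o_j| − p, chi-square upper tail. Undefined (raises)
  with a single pattern.
- Imputation: chained equations (Bayesian-ridge conditionals, posterior
  sampling, 5 iterations, pooled over 5 imputations) with mean, median
  and kNN comparators; cross-method agreement (R²-style concordance,
  MAE discrepancy) is computed on the imputed cells only; observed cells
  are never altered.
- Comparison: Friedman chi-square on the within-lesion ranks of the
  three durations; three pairwise Wilcoxon signed-rank tests (zeros
  dropped; exact enumeration for n ≤ 25 without ties, otherwise
  continuity-corrected normal approximation), Bonferroni factor fixed
  at 3. Effect size r = |Z|/√n signed by the median paired difference of
  (first-listed − second-listed); with pairs ordered (AI,LI), (LI,LSI),
  (AI,LSI), a faster first-listed rule yields negative r.

## Predictor analysis

Five covariates (mean CF, start CF, LI drop, LI start, ILD). Normality:
Shapiro–Wilk and Anderson–Darling; collinearity: VIF = 1/(1−R²_j) plus
Pearson correlations; heteroscedasticity: Breusch–Pagan LM
(n·R² of squared residuals on the design). The duration regressions pair
a GAM (one cubic B-spline smooth of 6 basis functions per predictor,
penalty selected per term by generalized cross-validation, per-term Wald
significance) with a random forest (impurity importances normalized to
sum 1; cross-validated MSE and R² from identical settings). A
cross-validated R² below 0.2 automatically flags the importances as
unreliable. On the synthetic cohort, mean CF carries the top importance
for the AI-guided duration — the expected pattern, since the CF exponent
makes contact force the dominant driver of that index.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is cleanly
identifiable: 200-lesion cohorts (≈ 5.6·10⁵ timepoint rows at stride
10) for surrogate recovery, 300 lesions for the end-to-end ordering,
200–500 Monte-Carlo replicates for calibration checks, n ≤ 10 for the
exhaustive enumeration oracles.

## Known limitations

- The LI trace model is phenomenological; its single-minimum guarantee
  is a design convenience, not physiology.
- Stand-in constants reproduce the qualitative duration ordering by
  construction (calibration choice), so the end-to-end comparison checks
  machinery, not clinical effect sizes.
- Little's test inherits the multivariate-normal working model; with
  heavy-tailed covariates its level can drift.
- GAM per-term p-values are Wald-type on penalized fits and are
  approximate; under heavy smoothing they become conservative.
- The LSI series is guaranteed non-decreasing only for constant windowed
  inputs; with a rebounding LI the current term can shrink slightly,
  though the time factor dominates at the defaults.
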