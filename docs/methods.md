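# Methods

## The problem

DNA methylation at many CpG sites drifts with chronological age, and
penalized regressions on array beta values ("epigenetic clocks") predict
age from those sites. Most published clocks are trained either on a
single tissue (usually blood) or pooled across tissues. `tissueclock`
implements the alternative protocol of training one clock per tissue and
then asking which of the selected aging CpGs are shared between tissue
models (*tissue-common*) and which belong to exactly one
(*tissue-specific*), and how those two classes differ in aging
direction, CpG island/shore location, and evolutionary conservation.

Because the original cohorts are large public array collections that
this package does not download, every analysis here runs on synthetic
multi-tissue panels with planted ground truth. The tests and the
acceptance script therefore check *method properties* — oracle
equivalence of the statistics, calibration, planted-signal recovery —
rather than reproducing cohort-level numbers.

## Pipeline

1. **Harmonization** (`tissueclock.io`). Each tissue arrives as two
   platform dialects (a 27K-style export whose probes are a subset of
   the 450K-style export). Probes are intersected on IDs, probes with 10
   or more missing values across the tissue's samples are dropped
   (strictly fewer than 10 survive; `max_missing=0` keeps only complete
   probes), the remainder are mean-imputed per probe, and each platform
   batch is quantile-normalized per probe to the uniform \[0,1\] scale
   (`(rank − 1)/(n − 1)`, average ranks for ties) before column-wise
   merging. Normalization defaults to "whenever more than one dataset is
   merged" and can be forced either way. Direction and young/old
   analyses deliberately use the *unnormalized* merged betas, since they
   describe methylation levels rather than ranks.

2. **Age association** (`tissueclock.association`). Per probe, ordinary
   least squares of beta on age; the overall regression F-statistic
   equals the squared slope t-statistic (single regressor), with the
   p-value from the F(1, n−2) upper tail. Benjamini–Hochberg q-values
   are computed over the whole surviving probe family of a tissue, and
   probes with q strictly below 0.05 proceed. Constant probes get F = 0,
   p = 1 rather than an error; fewer than 3 samples or constant ages are
   errors.

3. **Stability selection** (`tissueclock.stability`). Samples are
   resampled with replacement (size n), an elastic net of age on the
   candidate probes is fitted per resample (500 resamples in the
   reference protocol; a probe is "present" when |coef| > 1e−8), and
   probes present in strictly more than 95% of resamples become the
   tissue's markers. The penalty mixing ratio (grid {0.2, 0.5, 0.8}) and
   strength are chosen once on the full data by 5-fold cross-validation
   and held fixed across bootstraps. We select the penalty by the
   **one-standard-error rule** (largest penalty within one SE of the CV
   minimum): the plain CV minimum systematically under-penalizes
   noise-dominated data, which lets a few spuriously age-correlated
   probes survive nearly every bootstrap and defeats the point of
   stability selection. Resamples with zero age variance are redrawn;
   more than 10% redraws aborts.

4. **Clock** (`tissueclock.clock`). An ε-SVR on the marker submatrix.
   Hyperparameters come from an exhaustive grid — kernel ∈ {linear,
   rbf}, C ∈ {0.1, 1, 10, 100}, ε ∈ {0.1, 0.5, 1, 2} years, and for rbf
   γ ∈ {1/m, scale} — under seeded 10-fold cross-validation scored by
   mean absolute deviation (MAD), the criterion used for model
   comparison throughout. Ties resolve to linear before rbf, then
   smaller C, then smaller ε (the grid is ordered accordingly and the
   first minimum wins). Linear kernels consume raw betas; the rbf path
   standardizes features with training statistics stored in the model.
   Metrics: RMSE, MAD, Pearson's r (NaN for constant vectors), MAPE
   (percent; undefined when an observed age is 0), and Theil's U
   implemented as RMSE(model)/RMSE(mean-age predictor) — the variant
   name is carried in the metric object so U < 1 always reads "beats
   the mean-age baseline".

5. **Characterization** (`tissueclock.characterize`). Markers used by
   **two or more** tissue models are *common*, by exactly one
   *specific*; this ≥2 reading makes the two groups a partition of the
   marker union (a `strict_more_than_two` flag gives the literal ≥3
   reading, leaving occurrence-2 markers labelled `intermediate`).
   Direction is the sign of the Pearson correlation of a marker's raw
   training betas with age (positive ageCG = methylation rises with
   age); for common markers the per-tissue signs are combined by
   majority vote, with exact ties flagged ambiguous. Group-location
   contrasts use Fisher's exact test: 2×2 tables by the exact two-sided
   hypergeometric rule; larger tables by exact enumeration over the
   margin-conditioned table space when the enumeration stays below
   2×10⁵ tables, otherwise a seeded Monte-Carlo estimate with 10⁵
   draws (the method used is recorded in the result). Conservation is
   compared by the two-sample Kolmogorov–Smirnov test (asymptotic
   p-value); region scores are the arithmetic per-base mean. The
   young/old contrast takes the 5 oldest and 5 youngest samples (ties
   broken by sample ID), reports the group age gap and the mean marker
   beta difference, and flags cohorts whose gap is ≤ 40 years.

6. **Orchestration** (`tissueclock.pipeline`, `tissueclock.cli`). A
   linear stage DAG (simulate → harmonize → associate → select → train →
   evaluate → characterize) with all thresholds in `RunConfig`
   (defaults: max_missing 10, FDR 0.05, 500 bootstraps, frequency
   > 0.95, 10-fold CV, k = 5). Each stochastic stage derives its seed
   from the master seed as `(seed·1000003 + crc32(stage)) mod 2³¹`, so
   a rerun with the same config reproduces every output checksum, which
   the manifest records.

## The synthetic panels

`tissueclock.simulate.generate_panel` emulates the features the pipeline
is sensitive to, and nothing else:

- One probe universe shared by all tissues; per-tissue cohorts with ages
  drawn uniformly over a configured range (default 20–90 years, matching
  the broad flat cohort ranges typical of normal-tissue collections).
- Planted markers follow `beta = clamp(b0 + s·age + ε, 0, 1)` with
  ε ~ N(0, noise_sd): linear on the beta scale because the association
  stage fits linear regressions on betas. Intercepts are sampled so the
  noise-free trajectory stays within `max(0.05, 3·noise_sd)` of neither
  bound, keeping clamping rare (<1% of entries at defaults). Common
  markers carry the same signed slope in every tissue; specific markers
  have nonzero slope in exactly one.
- Defaults: slope magnitude 0.005 beta/yr and noise SD 0.02 — roughly a
  0.35 beta-range swing over a 70-year span against tight array noise,
  a strong but not degenerate signal; positive fractions 0.8 (common)
  and 0.4 (specific), planted as exact counts so group fractions are
  controlled; island probabilities 0.7/0.3/0.4 for common/specific/
  background (non-island mass split evenly between shore and other);
  conservation from Beta distributions with concentration 20 and means
  0.6/0.5/0.45, giving the KS comparison realistic power at ~100
  markers per group; 1% missing entries; a 50/50 sample split between
  dialects with 80% of probes on the 27K-style subset (planted markers
  always included, so harmonization cannot silently delete the signal).
- Not simulated: cell-type composition, batch effects beyond the two
  dialects, genome-realistic coordinates, or Infinium chemistry
  differences. Passing tests therefore demonstrate that the *pipeline
  machinery* is correct and calibrated under its own model; they say
  nothing about biological effect sizes in real cohorts, where noise is
  non-Gaussian, probes are correlated, and age-beta relationships can
  be nonlinear.

## Numerical and design choices

- BH q-values use the standard step-down cumulative minimum on the
  sorted scale; ties are handled by stable sorting and the invariant
  q ≥ p always holds.
- The per-probe OLS is vectorized over probes; an exact zero residual
  with nonzero slope (possible only through clamping artifacts) yields
  F = ∞, p = 0.
- TSV round-trips are exact: floats are written with `%.17g` and parsed
  with round-trip precision; missing entries are `NA`.
- `ElasticNet` fits reuse warm starts across bootstraps for speed; this
  does not affect the fitted optimum, only iteration counts.
- Problem sizes in the test-suite and acceptance runs (panels of
  800–2,000 probes, 100–200 samples per tissue, 100 bootstraps, 200
  calibration replicates) are the package's desk-scale defaults; the
  reference protocol value of 500 bootstraps remains the library
  default and is exercised by the analysis drivers.

## Known limitations

- The elastic-net penalty policy (one-SE rule, fixed across bootstraps)
  is one defensible choice among several; per-bootstrap retuning would
  be ~500× more expensive and is not implemented.
- The r×c Fisher Monte-Carlo p is an estimate with ~3×10⁻³ standard
  error at its default draw count; the exact enumerator covers all
  tables the pipeline produces at its default scales.
- Theil's U has more than one published form; only the
  RMSE-ratio-to-mean-baseline variant is implemented, and it is labelled
  as such in output.
- `predict_age` applies the model to whatever matrix it is given; any
  renormalization of external test data is the caller's responsibility
  (the pipeline applies the same harmonization to train and test
  columns before splitting).
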