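# Methods

## The model

A free-association chain is treated as the trajectory of a cognitive
process: each response is the stimulus for the next association, and the
semantic distance (SmD) between adjacent responses is one observation of
how far the process moved.  SmD is defined on an LSA word-vector space as
`1 − cosine`; negative cosines carry no interpretation as a distance and
are mapped to exactly 1 (the clamp is applied at the SmD level — the raw
`cosine` operation keeps its sign so users can inspect it).

The resulting series is characterised on the continuum
*random → flexible-stable → persistent* by its fractal scaling.  The two
scaling estimators measure the same quantity in different domains and are
linked by α = (1 − s)/2, where s is the log-log periodogram slope and α
the DFA exponent; the package verifies this relation on synthetic signals
(it holds within 0.1 for β ∈ {0, −1, −2} at n = 4096).  Sample entropy is
carried as a third, relative index of irregularity.

The inferential model is a quadratic multiple regression of a
divergent-thinking score on both scaling estimates and their squares,
with the overall F on (4, n − 5) degrees of freedom.  An inverted-U
relation — peak performance at flexible-stable structure — appears as a
negative, significant quadratic coefficient.  Predictors enter raw
(uncentred) before squaring by default; a `center` option exists because
raw squares are strongly collinear with their linear terms, and centring
changes the linear-term coefficients but neither the quadratic terms nor
the overall test.  Both plain and adjusted R² are reported, since
published R² values are often ambiguous between the two.

## Preprocessing choices

* **Token cleaning** keeps Unicode letters only (umlauts and ß survive),
  lowercases, and maps empty results to an invalid marker.  Cleaning is
  idempotent.  No spell correction is attempted: a token that fails
  vocabulary lookup becomes a missing value and is listed, with a reason,
  in the OOV report.
* **Missing values** (default policy `drop`) are removed and the
  remainder concatenated.  This distorts temporal spacing but invents no
  data; `linear-interpolate` is offered as the alternative and the chosen
  policy is echoed in all outputs.  Series with fewer than 32 observed
  values after missing handling are excluded (estimates on shorter series
  are too unreliable to interpret); exclusions are logged per participant.
* **Zero-padding** appends zeros up to the next power of two
  (115 → 128 with 13 zeros, 230 → 256 with 26).  The spectral estimator
  always receives the padded series — the dyadic-length requirement is a
  spectral one.  DFA, however, needs no dyadic length, and the appended
  zeros read as a level shift of the profile that inflates the
  fluctuation at large scales: measured on synthetic studies whose true
  exponents are known, padding DFA input biases α by about +0.20 and
  roughly doubles its error SD (r between true and estimated α drops from
  0.95 to 0.69).  The pipeline therefore pads PSD input only; a
  `pad_dfa` switch restores padding everywhere for users who want to
  mirror procedures that padded all estimator inputs.
* Sample entropy is always computed on the unpadded series — appended
  zeros would match each other as templates and deflate the entropy.

## Estimator numerics

* **PSD slope**: mean removal, raw (untapered, unaveraged) periodogram via
  FFT, DC excluded, OLS of log₁₀ power on log₁₀ frequency.  The default
  fit uses only the lower half of the frequencies
  (`drop_high_freq_fraction = 0.5`): near Nyquist the periodogram of
  steep spectra flattens through aliasing, and a whole-band fit on
  integrated white noise comes out around −1.8 instead of −2, while the
  lower-half fit recovers 0 / −1.0 / −1.95 for the three canonical
  classes.  Setting the fraction to 0 restores the whole-band fit.
  A constant series has zero power everywhere and raises a degenerate-
  series error.
* **DFA**: profile = cumulative sum of the mean-centred series; 10
  log-spaced window sizes from 4 to N/4; non-overlapping windows, each
  linearly detrended (the canonical per-window detrending — not global-
  trend subtraction); F(s) = RMS residual pooled over windows; α = OLS
  slope of log₁₀ F on log₁₀ s.  With this schedule, mean α on white noise
  at n = 1024 is ≈ 0.52 (small positive small-scale bias, shrinking with
  n), ≈ 0.99 on 1/f and ≈ 1.49 on integrated white noise.
* **Sample entropy**: m = 2 and r = 0.2 × SD of the series by default
  (the field-standard tolerance); matches counted under Chebyshev
  distance < r over the first N − m template positions for both lengths,
  self-matches excluded.  B = 0 returns NaN (undefined), A = 0 with
  B > 0 returns +inf.  The implementation is exact (verified against an
  exhaustive pair counter), not an approximation.
* **Structure labels** assign the nearest anchor (PSD 0/−1/−2,
  DFA 0.5/1/1.5), breaking exact ties toward flexible-stable.  They are a
  reading convenience, not part of the inferential procedure.
* **ICC(2,k)** is computed directly from the two-way ANOVA mean squares
  (two-way random effects, absolute agreement, average measures) and
  cross-checked in the test suite against an independent reference
  implementation.

## The synthetic-data generator

The generator exists so that every pipeline stage can be tested with
known ground truth; its defaults are the study conditions the package
targets, chosen once:

* **Power-law series** are made by spectral synthesis — amplitudes
  ∝ f^(β/2), independent uniform phases, Hermitian symmetry, inverse
  FFT, standardised to mean 0, SD 1.  Spectral synthesis (rather than
  circulant embedding of fractional Gaussian noise) is used because
  targets are specified as spectral exponents, the same scale the PSD
  anchors live on.
* **Semantic spaces** are clustered random unit vectors:
  `sqrt(c)·center + sqrt(1−c)·noise`, giving within-cluster cosine ≈ c
  and cross-cluster cosine ≈ 0 ± 1/√dim.  The study-scale default
  (vocab 5000, dim 12, 50 clusters, c = 0.6) keeps the dimension low on
  purpose: with 5000 candidate words, a cosine spread of 1/√12 ≈ 0.29
  makes the full range of intermediate SmD values reachable from any
  word, which a high-dimensional space (where all cross-cluster cosines
  pile up near 0) would not.
* **Chains** realise a target SmD trajectory by a greedy walk: the next
  word minimises |SmD − target| among words unused in the last 10 steps,
  ties broken randomly under the seed.  Realised series correlate ≥ 0.7
  with their targets at vocab 5000, and the DFA ordering of white / 1/f /
  integrated-white targets survives the quantisation in ≥ 95% of triples.
* **Studies** draw per-participant β uniformly from [−2, 0]
  (α ∈ [0.5, 1.5]), chain lengths uniformly from 42–370 words, and scores
  from `b0 + b1·α + b2·α² + N(0, 0.3)` with defaults (−0.55, 6, −3):
  an inverted-U peaking at the flexible-stable anchor α = 1, giving
  creativity ratings with mean ≈ 2.3 and SD ≈ 0.4 on the 1–5 scale.
  Response times emulate a fixed 35-minute session (mean RT
  ≈ 2100 s / chain length, lognormal jitter), and the serial-order effect
  is planted by shifting the centre of each participant's SmD mapping
  window upward with mean RT (`rt_coupling`, default 0.01 per second).
  All targets are mapped into a window inside [0.05, 0.95] to avoid
  boundary saturation.  Every generator emits its ground truth
  (`ground_truth.json`) for recovery tests.

### What the generator does not emulate

Synthetic "words" are arbitrary identifiers with no psycholinguistic
structure; the semantic geometry is isotropic within clusters, unlike
real lexical spaces; response times are gamma jitter around a
session-budget mean, not a cognitive latency model; and scores depend on
the *true* generating exponent, so pipeline recovery is attenuated by
estimation error exactly as a real study's would be.  Passing tests
therefore show that the estimators and the inferential chain work as
specified on data with known structure — not that human association
chains are fractal, nor that the inverted-U holds empirically.

## Problem sizes used in the test and acceptance runs

Estimator calibration uses 200 series of length 1024 per signal class;
the theoretical-consistency check 50 series of length 4096 per β; the
parameter-recovery simulations 50 studies of 200 participants each for
the planted effect and the same for the null; correlation/ICC simulations
use 100–1000 replicates at study-scale n.  These sizes give Monte-Carlo
error comfortably inside each assertion band.

## Known limitations

* Estimates on series near the 32-observation floor are noisy; the
  pipeline reports per-fit R² and warns below 0.8 rather than refusing.
* The raw periodogram is a noisy spectral estimator by construction;
  slope averaging across participants, not tapering, is the intended use.
* The `drop` missing policy compresses time; with heavy missingness
  (> ~20%) both estimators drift toward white-noise values.
* The greedy chain walk realises trajectories only as well as the space's
  SmD distribution allows; sparse regions of that distribution quantise
  the series and attenuate extreme exponents toward 0.5.
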