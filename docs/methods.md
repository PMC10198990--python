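# Methods

## Consensus model

Continuous affect ratings have no external ground truth. The package
scores raters against an *informal cultural consensus*: for each video
and rating dimension, the time × rater matrix is assembled, each rater's
series is z-scored (so per-rater gain and offset are nuisance — this is
correlation-matrix PCA), and the first principal component's factor
scores over time serve as the consensus trajectory. Mutually consistent
raters receive the largest loadings, which is precisely the informal
consensus-theory idea that agreement identifies both the answer key and
rater competence; no guessing correction is needed for continuous
responses. Accuracy is the Pearson correlation between a rater's series
and the consensus; pooling over videos or raters is Fisher-Z averaging
`tanh(mean(atanh(r)))`, with r clipped to ±(1 − 1e−7) so a perfect
correlation stays finite while perturbing pooled values far below
reporting precision.

Conventions that the mathematics does not fix, chosen once and exposed
as switches:

* **Leave-in consensus.** The scored rater's own column is included in
  the PCA by default ("all ratings for a given video"); a
  `loo_consensus` switch recomputes the consensus without them. At 30+
  raters the two differ by well under 0.05 per cell (regression-tested).
* **Sign.** The leading eigenvector's sign is arbitrary; scores are
  flipped so the mean loading is non-negative, with an exact tie broken
  toward a non-negative loading for the first (sorted) rater id.
* **Zero-variance raters** (cursor never moved) are dropped from the
  consensus and their cells recorded as *missing*, never as r = 0 — a
  zero would be an invented datum.
* Valence and arousal are scored as independent dimensions.

## Reliability diagnostics

* **Bootstrap CIs**: percentile bootstrap (B = 5000 by default) on the
  accuracy cells behind each per-participant or per-video pooled score.
* **Shift null**: each rater-video trajectory is circularly shifted by a
  uniform random lag at least 10 s away from zero (in either direction)
  and re-scored against the unshifted consensus. The circular shift
  preserves the series' autocorrelation and marginal distribution while
  destroying temporal alignment. It is computed exactly via FFT circular
  cross-correlation (one transform yields r at every lag). Because
  circular correlations over *all* lags sum to zero and the guard band
  excludes the positive-correlation neighbourhood of lag 0, the null
  mean sits slightly below zero; with the default 4 s latent correlation
  time and 1–3 min clips the bias stays within ±0.05.
* **Difficulty function and responder flags**: videos ranked by pooled
  accuracy define the difficulty function. For each participant, their
  own per-video accuracy vector is correlated with the group's
  leave-one-out pooled vector; the null permutes the video labels of the
  participant's own vector (B = 5000). Participants inside the null 95%
  band are flagged as possible random responders, and the pipeline
  reports headline correlations both with and without them.

## Associations

Descriptives use the sample SD (n−1), the adjusted Fisher–Pearson
skewness and bias-corrected excess kurtosis. All correlations are
rank-based: Spearman's rho is computed as the Pearson correlation of
average ranks, with the large-sample t approximation for p. Partial
Spearman correlations rank-transform every variable and correlate the
least-squares residuals after projecting onto the covariate ranks plus
intercept; with no covariates this reduces *exactly* to plain Spearman
(both are correlations of intercept-residualized ranks), and for one
covariate it equals the recursive partial-correlation formula applied to
rank correlations (tested to 1e−10). Multiplicity is handled by
Bonferroni over a declared plan; the default plan crosses the four task
scores (valence accuracy, arousal accuracy, Eyes Test, Films task) with
four traits (AQ, EQ, fluid, crystallized intelligence) and adds a
flagged-rater sensitivity re-run of the headline valence~AQ comparison,
17 comparisons in all. The plan is configuration data, logged with every
run, because the membership of a planned-comparison family is a design
declaration, not something the data can decide.

Bootstrap inference resamples participants (cases) with replacement,
recomputes the statistic per resample, reports the Fisher-Z mean and the
2.5/97.5 percentile interval, and redraws degenerate resamples (bounded
retries). Permutation tests permute one variable uniformly and use the
add-one rule `p = (1 + #{|rho*| ≥ |rho|}) / (B + 1)`; an exact
enumeration mode (n ≤ 8) exists as an oracle for the sampled version.

## Video item analysis

Treating videos as test items: for each subset size k, 5000 random
k-subsets are drawn without replacement, each participant's accuracy is
Fisher-Z pooled over the subset, correlated with AQ, and the iteration
rhos are Fisher-Z averaged. At k = V the curve equals the full-sample
rho exactly. The minimum videos to reach a fraction (default 75%) of the
full effect compares curve *magnitudes* — the signed values are
negative, and magnitude comparison keeps the rule direction-agnostic.
Best videos are the n (default 7) with the most negative per-video
accuracy~AQ rho (the hypothesized direction); ties and ordering break by
sorted video id so results are independent of row order. Split-sample
reliability partitions participants into five near-equal random chunks,
correlates per chunk, Fisher-Z averages, and repeats 5000 times.

Group splits sort by (trait, participant id) — the id breaks ties at the
median deterministically — and cut in half (median mode) or at rank
quartiles. Quartile sizes are `floor(n/4)` per group with the remainder
in the top group (25/25/25/27 at n = 102); when `n mod 4 = 3` the
remainder is spread so sizes never differ by more than 2. Group
differences use a two-sided case-resampling bootstrap sign test,
`p = 2·min(P(diff* ≤ 0), P(diff* ≥ 0))`. This test is mildly
anticonservative in small groups (measured type-I error ≈ 0.085 at 20
per group, ≈ 0.069 at 51 per group under the null over 1000+
replicates); interpret small-sample split p-values accordingly.

## Synthetic cohort generator

The generator defines the study conditions used throughout the tests:
102 participants × 35 videos, clip durations uniform on 60–180 s,
ratings sampled at 10 Hz (the rating rate of the original apparatus is
not public; 10 Hz is a typical continuous-rating cadence and all
downstream statistics are correlation-based, hence insensitive to it).

* **Latent affect course**: per video and dimension, a stationary
  unit-variance Ornstein–Uhlenbeck (AR(1)) process squashed by `tanh`
  into the grid [−1, 1] — smooth, bounded, with one smoothness knob. The
  default correlation time is 4 s, so the shift null's 10 s guard band
  spans 2.5 correlation times and the null decorrelates.
* **Rater model**: `rating = gain·(m·latent + (1−m)·distractor) + bias
  + noise`, clipped to the grid, where `m` is the rater's competency
  (uniform on [0.25, 0.95] by default), the distractor is an independent
  draw of the same latent process (low-competency raters are internally
  consistent but wrong), noise is white with SD 0.2, gain is
  log-normal (σ = 0.1), bias Gaussian (σ = 0.05), and each sample
  freezes-and-holds with probability 0.01 (attentional lapses). These
  defaults put pooled accuracies around 0.65–0.75 with a wide individual
  spread, matching the observed scale of such studies.
* **Video difficulty**: per-video noise scales follow a geometric ramp
  spanning 4× by default, giving the cohort a genuine difficulty
  function; planted-structure experiments can instead supply explicit
  per-video signal or noise scale vectors, or explicit competencies.
* **Questionnaires**: integer totals are Gaussian-copula draws matched
  to each instrument's observed mean, SD and range (AQ on 9–33 with
  mean ≈ 19, etc.), never exceeding instrument maxima. AQ's latent
  score correlates with competency at `trait_loading` (−0.4 by
  default); the other instruments load on a social factor, a general
  intelligence factor and competency through a small factor model whose
  loadings are user-replaceable. The rank (Spearman) correlation
  realized between competency and AQ is slightly attenuated relative to
  the latent loading (≈ 0.956·λ for bivariate Gaussian copulas, plus
  integer discretization), which is well inside the sampling noise at
  n = 102.

What the generator does *not* emulate: dimension-specific deficits (one
competency drives both valence and arousal, so synthetic arousal~AQ
correlations are as strong as valence ones, unlike real cohorts),
serially correlated rating noise, rater-specific reaction-time lags, and
item content effects. Passing tests therefore establish that the
*analysis* recovers known structure, not that real data share that
structure.

## Numerical choices

* Constant-series detection uses a relative SD threshold (1e−12 of the
  series scale) rather than exact zero.
* Fisher-Z clipping bound 1 − 1e−7 everywhere.
* Consensus factor scores come from the SVD of the standardized data
  matrix; the test suite checks them against an explicit covariance
  eigendecomposition to 1e−8 on random matrices.
* All Monte-Carlo procedures accept either an integer seed or a
  `numpy.random.Generator`; the pipeline derives named per-stage seeds
  from one base seed, and identical (inputs, config) pairs reproduce
  byte-identical artifacts.
* Monte-Carlo sizes: B = 5000 wherever a count is a free choice in
  production runs; the test suite and acceptance script use 500–2000 to
  keep a full run around a minute, which is ample for the 2-decimal
  quantities they check.

## Known limitations

* With a leave-in consensus on strongly autocorrelated series, a cohort
  consisting *entirely* of noise raters scores above the shift null —
  PCA overfits the noise when the number of effective time samples is
  comparable to the number of raters. Noise raters embedded in a
  signal-carrying cohort are correctly null-consistent; diagnosing a
  wholly random cohort requires the leave-one-out consensus switch.
* The difficulty-function flagging procedure presumes most raters are
  engaged (well above chance); in cohorts dominated by near-chance
  raters it flags liberally, which is the intended failure direction.
* The 17-comparison plan is a declaration; users analysing other
  questionnaire batteries must supply their own plan, and the Bonferroni
  multiplier follows the plan size.
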