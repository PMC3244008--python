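# Methods

This note records the models implemented in `actiseq`, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Framing and features

A recording is a channels × time matrix at a stated sampling rate (default
76.25 Hz). Frames are 512-sample windows taken at stride
`width · (1 − overlap)` (default 50% overlap → stride 256, one frame every
3.35 s, 6.7 s per frame); a trailing window that does not fill 512 samples
is dropped, never padded.

Per channel and frame:

* **DC component** — arithmetic mean. Dominated by the projection of gravity
  on the sensor axis; the primary posture discriminator.
* **Energy** — sum of squared magnitudes of the *orthonormal* DFT
  coefficients of the detrended channel, excluding the zero-frequency bin,
  divided by the window length. Under this normalisation the quantity equals
  the time-domain variance of the detrended samples exactly (Parseval),
  which the suite asserts to 1e−9; the frequency-domain form is kept because
  it is the natural home for band-limited variants.
* **Frequency-domain entropy** — magnitudes of the positive-frequency
  Fourier coefficients of the detrended channel (a single 512-sample
  transform per frame; no sub-windows) are treated as a sample; an
  Epanechnikov kernel density (K(u) = 0.75(1 − u²) on |u| ≤ 1) is fitted
  with Silverman's bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5), and the
  differential entropy −∫ p ln p is integrated by the trapezoid rule on a
  512-point grid spanning [min − 3h, max + 3h]. Densities are clipped at
  1e−12 before the logarithm; all logarithms are natural. A constant
  channel has a degenerate density; its entropy is reported as 0 with a
  warning. Impact-rich gaits (walking, running, stair climbing) spread
  spectral mass and score high; a pure tone (cycling) scores low — the
  ordering the suite checks.
* **Correlations** — cosine similarity of the detrended channel vectors for
  every unordered pair *including* self-pairs, giving c(c+1)/2 = 55 values
  for ten channels and the documented total of 3c + c(c+1)/2 = 85
  components. Detrending makes the value the Pearson coefficient of the raw
  channels; without it the gravity offsets would dominate every pair.
  Self-pairs are constant 1 and carry no information; they are kept so the
  pair count and component total match the documented dimensionality, and
  the selection stage discards them naturally (a constant feature can never
  improve the criterion). A zero-norm (constant) channel yields 0 for its
  pairs, with a warning.

## Feature selection

The separability criterion is the mean (over instances) distance to the k
nearest *other*-class neighbours divided by the mean distance to the k
nearest *same*-class neighbours (self excluded), Euclidean, after
per-feature standardisation; k = 1 by default. Standardisation is
per-feature, so a subset's squared distance matrix is an exact sum of
per-feature terms; the search caches those terms and evaluates candidate
subsets incrementally — results are identical to evaluating the criterion
from scratch (cross-checked in the suite).

SFS adds, at each step, the feature maximising the criterion (ties → lowest
index). SFFS additionally tries, after each inclusion, to exclude features
while exclusion *strictly* improves the best criterion recorded at the
reduced size (strictness guarantees termination); the best subset per size
is recorded, and the record is seeded with the greedy path so it dominates
SFS at every size by construction. `sffs_select` reports the argmax over
sizes as `chosen_size`.

The pipeline, however, trains on the floating-search subset at a *fixed*
working size (default 17). On these synthetic libraries the raw criterion
is structurally maximal at size 1: in one dimension the nearest same-class
neighbour is degenerately close (spacing ~ range/N), so the intra-class
denominator collapses and no multi-feature subset can compete. A fixed
working dimensionality sidesteps that artefact of the mean-kNN aggregation
while keeping the search itself faithful.

## Single-frame classifiers

All probabilistic classifiers use the maximum-likelihood rule
argmax_i p(x|C_i) — class priors deliberately *not* applied, matching the
decision rule the sequential classifier's emissions are trained for; a
prior-weighted option exists behind `use_priors`. Ties break to the lowest
class index (classes in sorted order). Implementations: naive Bayes
(per-feature univariate Gaussians), GMM (per-class M-component mixture;
M = 1 closed form, M > 1 by EM with k-means-style seeding from a fixed
seed, 100 iterations max, relative tolerance 1e−6), Parzen (Gaussian
product kernel, per-class Silverman bandwidths), nearest mean and k-NN
(majority vote, ties → lowest class index). Every covariance is
regularised by adding 1e−6 · (mean diagonal) · I.

Evaluation is by confusion matrices; aggregation over subjects or runs is
an elementwise sum, so aggregate accuracy is the outcome-weighted mean.

## The observable Markov chain and the cHMM

A composite activity is a first-order chain over Q = 7 primitives.
`estimate_omm` counts events: a_ij = (count(i→j) + δ)/(departures(i) + Qδ),
π from sequence starts, δ = 0 by default; a state with no departures falls
back to a uniform row with a warning. The default seven-state chain ships
with the package; its rows are normalised to unit sum on construction and
its prior is the stationary distribution of the transition matrix (computed
by eigen-decomposition, not stored).

The sequential classifier is a Gaussian continuous-emission HMM,
λ = (π, A, B), M = 1 Gaussian per state by default (larger M gave only
marginal gains in this regime and is configurable). First-phase training is
fully supervised and reuses the exact class-conditional fit of the GMM
classifier per state. The second phase is Baum-Welch on incoming unlabelled
sequences; the default mode re-estimates only (π, A) — its purpose is
adapting to transition structure that drifted from the training regime —
with `mode="all"` updating emissions too (covariances floored by the same
regulariser, with a warning on collapse). Stopping: relative log-likelihood
gain below 1e−4 or 100 iterations; the likelihood history is returned and
asserted monotone in the suite.

Forward, backward and Viterbi all run in log space with per-column
max-shifted log-sum-exp (a single global shift is *not* safe here: emission
log-densities can span ±10⁵ across states, and dropping columns far below
the global maximum corrupts the recursion — found the hard way, now covered
by the exhaustive-enumeration oracle tests). Viterbi ties break to the
lower state index at every backtrack step. Posterior quantities are clipped
at probability 1 before exponentiation to absorb rounding residue.

The pipeline trains the chain with δ = 0.5 (a half-count): five sequences
of 300 frames leave rare-but-real transitions (generating probabilities
down to 1e−4) uncounted, and an exact zero in A can never be traversed by
Viterbi nor resurrected by Baum-Welch. The half-count keeps those paths
merely expensive instead of impossible. `estimate_omm` itself keeps δ = 0.

## Spurious-frame rejection

Score = max over states of log b_j(x) (alternatives: log-sum, or a
stationary-weighted sum; the max is the least prior-dependent and is the
default). The threshold is swept over all midpoints of the pooled
calibration scores; sensitivity = fraction of outliers below threshold,
specificity = fraction of inliers at/above it; the Youden optimum
(max sensitivity + specificity) is chosen, ties resolving to the *lower*
threshold (rejects less). Rejected frames are excluded from the decoded
chain — the chain skips them — and labelled `SPURIOUS` in the output at
their original positions; imputation alternatives were rejected for
simplicity, since flagged frames are meant never to reach the classifier.
Sequence accuracy counts spurious frames as their own class: without a
rejector every garbage frame is wrong by construction; with one it is
correct exactly when rejected. Accuracy restricted to genuine frames is
reported alongside.

## Synthetic data: what it emulates, what it does not

Each activity is a recipe: per-channel gravity projection (DC), sinusoidal
components at an activity-specific fundamental and harmonic with
channel-specific gains and fixed phase lags, optional exponentially
decaying broadband bursts at Poisson foot-strike times (rate tied to the
cadence), white noise, slow baseline wander (low-passed noise, sd
0.5 m/s² — posture adjustment and sensor micro-shift; without it per-frame
features are nearly noiseless and every classifier saturates), and 15%
slow amplitude jitter (stride-to-stride variability). The seven default
recipes were set so the single-frame problem has realistic difficulty:
postures separate by DC, walking/climbing/running share the upright DC
profile and must be separated by energy, entropy and arm-engagement
correlations, and the small-sample (K = 7) GMM lands well below the
large-sample classifiers. Garbage recipes use off-gravity DC offsets, odd
fundamentals and heavy noise so rejection is learnable but not trivial.

Virtual experiments sample, for each state of an OMM-generated sequence,
one feature vector with replacement from that activity's pool (default pool
sizes drawn from 18–58 per class), then intersperse ⌊ratio·T⌋ garbage
frames at uniformly random positions (ratio ≤ 1/3, i.e. at most one
spurious frame per three genuine frames).

Not emulated: fuzzy postural transitions (frames are cleanly one activity),
subject-to-subject mannerism, sensor placement error, and any biomechanical
gait structure beyond the spectral signature. Passing tests therefore
demonstrate the *algorithms* — recursion correctness, training behaviour,
and the orderings (sequential ≥ single-frame GMM; garbage collapse and
rejection recovery) — under controlled conditions; they do not certify
accuracy figures on real recordings.

## Default study conditions

Q = 7 primitives, 512-sample frames at 76.25 Hz with 50% overlap, feature
library of 18–58 frames per class, SFFS to a working dimensionality of 17,
K = 7 single-frame training frames per class, S = 20 virtual experiments of
T = 300 frames with P = 5 in training, M = 1, δ = 0.5, garbage ratio 1:3,
60 garbage frames split between threshold calibration and injection. These
sizes keep a full study run around ten seconds; all are `RunConfig` fields.

## Limitations

* The k-NN separability criterion's mean aggregation is scale-sensitive at
  tiny subset sizes (see above); the argmax-over-sizes rule is exposed but
  not used by the pipeline.
* Event counting with δ = 0 cannot represent transitions absent from
  training; the pipeline's half-count is a pragmatic, not a Bayesian,
  choice.
* The rejection threshold is calibrated globally, not per subject; with a
  single synthetic "subject" per run the distinction does not arise.
* Discrete-emission HMMs and wavelet/PCA/ICA feature variants are out of
  scope.
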