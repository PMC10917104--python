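# Methods

## The decoding problem

Given single-trial multichannel EEG windows (1.5 s preceding a button
press) labeled with one of three choices, the pipeline learns, per
participant, a mapping from trial to choice, evaluated on a strictly later
block of trials. Spatial covariance structure is the carrier of
information: different choices are assumed to engage differently weighted
cortical source configurations, which CSP is designed to separate.

## Pipeline model and assumptions

**Trial covariance (CSP).** Each trial's covariance is trace-normalized,
S = EEᵀ/tr(EEᵀ), making features invariant to global amplitude scaling and
letting trials of different overall power contribute equally to the class
mean S̄_c. CSP assumes the discriminative signal lives in second-order
statistics (band-limited variance), not in phase or waveform shape — hence
the filter bank, which restores coarse spectral specificity by fitting CSP
independently in five 4-Hz bands (1–20 Hz).

The generalized eigenproblem S̄ₓw = λ(S̄ₓ+S̄ᵧ)w is solved by whitening with
the composite covariance (eigendecomposition, eigenvalue floor 1e-12) and
then symmetrically eigendecomposing the whitened S̄ₓ — numerically stable
and algebraically equivalent. Should the composite be rank deficient
(near-duplicate channels, heavy preprocessing), a ridge of 1e-8·trace is
added with a logged warning. Selected filters satisfy W(S̄ₓ+S̄ᵧ)Wᵀ = I, so
the eigenvalue under the other class is exactly 1−λ. Four filter pairs per
band are kept (top-4 and bottom-4 eigenvectors, stored in descending-λ
order); each filter row is sign-fixed so its largest-magnitude coefficient
is positive, and the matching spatial patterns (rows of the inverse-
transpose of the full filter matrix) are stored alongside for inspection
and validation.

**Features.** The canonical normalized log-variance feature
fᵢ = log(var(wᵢE)/Σⱼvar(wⱼE)) over the 2m components of a band, so
Σᵢ exp(fᵢ) = 1 per band. Five bands × 8 components = 40 features per trial
and class pair.

**Attractor-metagene ranking.** The AM iteration is unsupervised: weights
start random (uniform(0,1), normalized, seeded; an all-equal deterministic
init is available), the metagene M = wG is formed, and each feature's next
weight is NMI(M, Gⱼ)^α, zeroed when the Pearson correlation with the
metagene is not strictly positive. Iteration stops when the max absolute
weight change falls below `tol` or `max_iter` is hit. The NMI estimator
bins both variables into B = max(2, ⌊√(n/5)⌋) equal-frequency bins and
normalizes MI by min(H(X), H(Y)), bounding it in [0, 1]; a constant input
returns 0 with a warning. If every weight is driven to zero (no feature
positively correlated with the metagene) a degenerate-attractor error names
the iteration.

Parameters: α = 5.0 by default — small-integer-range exponents are
customary for attractor weighting, and α of this size sharpens the
attractor enough that noise features decay while redundant informative
features survive; α = 0 degenerates to a pure positivity filter.
tol = 1e-4, max_iter = 100. Weights stay in [0, 1] at every iteration by
construction.

**Minimal-k subset.** Features are sorted by descending AM weight (ties:
ascending index). For k = 1..40 a fresh classifier is fit on the first k
ranked features and scored on the training set itself; the smallest k
attaining the maximum score wins, and the classifier is refit on that
subset. Training-set scoring is the most direct reading of choosing the
"best fit" during the ranked search; an internal validation split would
cost training data in an already-small per-pair sample and is left
configurable at the call site via the classifier factory.

**OVO aggregation.** One binary model per unordered class pair
(lexicographic order fixes all indexing). At test time each pair casts a
vote with a confidence in [0, 1] — the probability estimate of the
predicted label where the estimator has one, otherwise a logistic link
calibrated on training decision margins. With three classes the vote tally
is only ever 2-1-0 or 1-1-1; the 1-1-1 tie resolves to the class whose
cast vote carries the largest confidence (confidences of votes *against* a
class are not counted), with any residual exact tie going to the earlier
class in declared class order.

**Temporal split.** The first ⌊2N/3⌋ trials train, the rest test, stored as
the exact fraction 2/3. No shuffling and no cross-validation: predictions
about later trials may only use earlier trials.

**Permutation test.** The trained model's predictions are held fixed and
the true labels shuffled n_perm = 10,000 times;
p = (1 + #{null ≥ observed})/(1 + n_perm). This +1-corrected form is a
valid finite-sample p-value and never returns 0 (floor 1/(n_perm+1)).
Retraining inside the permutation loop is not done: the null hypothesis is
"predictions carry no label information", which the fixed-prediction
shuffle tests directly, and retraining 10,000 times would be prohibitive.
The null-distribution mean equals Σ_c (prediction share of c)·(label share
of c), a closed form used as a cross-check in the tests.

## Preprocessing rules

- Reaction-time exclusion: keep |rt − mean| ≤ 3·SD, mean and SD computed
  once over the full supplied vector (not iteratively re-estimated); with
  SD = 0 nothing is excluded.
- Amplitude rejection: an epoch is dropped iff any sample exceeds ±75 µV
  *exclusive* — exactly ±75 µV is inside the accepted range.
- Participant retention: a participant is kept iff at least one third of
  their trials survive (boundary inclusive).
- Windowing: epochs are the half-open sample interval [response − 768,
  response) at 512 Hz; indices are 0-based.
- Filter bank: 4th-order Butterworth band-passes applied forward-backward
  (zero phase), one per band, each designed from the raw input. Adjacent
  bands share −6 dB (after the two passes) edges; their summed response
  tracks a brick-wall 1–20 Hz filter to within ~10% relative error on
  broadband noise, measured away from edge transients.
- Re-referencing and ICA ocular correction are deliberately out of scope;
  inputs are assumed cleaned upstream.

## Synthetic sessions

The generator emulates the study geometry: 330 trials, 34 channels, 512 Hz,
1.5 s windows, balanced shuffled three-class labels (counts differ by ≤ 1).
Background noise is temporally white, spatially correlated Gaussian noise —
a random full-rank mixing matrix drawn once per session, scaled to an
average channel SD of 10 µV so amplitude-rejection thresholds are
physically meaningful. Each class owns a unit-norm spatial pattern per
source band (orthonormal across classes by default, drawn from the seed);
the class-specific source is an amplitude-modulated sinusoid at the band
midpoint (modulation depth 0.5 at 0.5 Hz, random phase per trial, ±20%
per-trial amplitude jitter with unit mean square).

`snr` is defined *in-band*: the expected ratio of planted source power to
the background noise power falling inside the source band (white-noise
band fraction (high−low)/(f_N)). This makes the planted CSP eigenvalue
analytically predictable — for orthogonal patterns the top whitened
eigenvalue is ≈ (snr + 1/C)/(snr + 2/C) — and is what the realized-SNR
validation measures by differencing band power against a matched snr = 0
session. At snr = 0 nothing is planted and signals are exactly
label-independent.

What the simulator does **not** model: ocular/muscle artifacts, volume
conduction, 1/f spectra, across-block nonstationarity. Passing tests
therefore certify the algorithmic chain (filters recover planted spatial
structure; the null is calibrated), not performance on real EEG.

## Numerical and design choices

- Eigenvalue floor 1e-12 (whitening), ridge 1e-8·trace (rank deficiency),
  variance floor at machine epsilon in the log-variance transform; all
  logged when triggered.
- Classifier defaults are ordinary library defaults (documented in
  `CLASSIFIER_DEFAULTS`) with seeds threaded through; LDA is the package
  default for being deterministic and fast at these sample sizes.
- Seeds: a master seed spawns independent sub-seeds (NumPy `SeedSequence`)
  for simulation, per-pair AM initialization, classifier randomness and
  permutation draws; every serialized artifact embeds the config hash and
  seeds used.
- Epoch bundles are a `.npy` array plus JSON sidecar; model bundles a JSON
  description plus `.npz` arrays. A minimal EDF (16-bit) / BDF (24-bit)
  writer is included for exporting continuous simulated recordings; reading
  goes through `mne`.

## Problem sizes used in validation

Unit tests run on miniature sessions (16 channels, 128 Hz, 90 trials) that
preserve every structural property at a fraction of the cost. The
validation battery (`scripts/acceptance.py` and the end-to-end test module)
uses full-geometry sessions — 34 channels, 512 Hz, 200–300 trials, 10
replicate seeds per condition, 500 replicates for permutation calibration —
sizes at which the Monte-Carlo error of each checked quantity is well
inside its assertion band.

## Known limitations

- AM convergence is to *an* attractor; with weak structure the iteration
  can settle on a noise cluster (observed occasionally in planted-relevance
  runs), which is why ranking guarantees are stated as medians over seeds.
- Training-accuracy subset scoring can saturate (score 1.0 at small k) for
  flexible classifiers, making k=1 selections common for trees/forests.
- The permutation test treats predictions as fixed; it does not account
  for training-stage selection noise.
- The EDF writer quantizes to its fixed physical range (±3276 µV at 16
  bit ≈ 0.1 µV resolution), adequate for µV-scale EEG but not for
  arbitrary-scale data.
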