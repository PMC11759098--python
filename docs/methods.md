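# Methods

## Problem and approach

In a two-talker scene, a listener's auditory cortex tracks the attended
talker more strongly than the ignored one.  Auditory attention decoding
(AAD) infers the attended talker from neural recordings.  The standard
linear baseline, canonical correlation analysis (CCA), learns a spatial
filter `w_x` on the neural channels and a temporal filter `w_y` on
[-500, 0] ms lags of a talker's acoustic envelope so that the two
projections are maximally correlated; at test time the talker with the
higher windowed Pearson correlation `r` between projections is decoded as
the target.

The framework implemented here instead *classifies* event-related
responses.  Acoustic **peakRate events** — local maxima of the half-wave
rectified derivative of the 1-10 Hz band-limited speech envelope — mark
acoustic edges near syllable onsets.  Each event is scored for energetic
masking against the competing talker: over the [-200, +200] ms window and
all 100 spectrogram bands, the **glimpse ratio** is the fraction of bins
where the talker's magnitude is at least the background's scaled by the
glimpse SNR (-4 dB; a bin may fall up to 4 dB below the background and
still count), and the mask ratio is its complement.  Events with glimpse
ratio > 0.9 are *glimpsed*; with mask ratio > 0.8, *masked*.

For a decoding window, the [0, 500] ms high-gamma responses (51 lags at
100 Hz) to one talker's glimpsed events are averaged per channel,
flattened to `N_ch x 51` features, and classified by an RBF-kernel SVM
(C = 10) with Platt-scaled probabilities; a separate classifier handles
masked events.  The per-talker probability is the mean of the two type
probabilities (or the single available one).  The talker with the higher
probability is decoded; with evidence from only one talker the 50% line
decides; windows with no labeled events either hold the previous
decision (ERPC-hold) or are decided by CCA (ERPC-fallback).  One model is
trained per (window duration, event type) pair, with non-overlapping
left-aligned training windows so a given set of ERPs is used once.

## Signal-processing choices

* **Auditory spectrogram.** A constant-Q bank of 100 bandpass filters,
  log-spaced 50 Hz-8 kHz (2nd-order Butterworth; band edges at the
  geometric means between neighboring centers, so adjacent bands meet
  near -3 dB), half-wave rectification, leaky integration with a 4 ms
  time constant, and 10 ms frame averages.  The filter bank is a
  swappable argument, so an exact cochlear-model backend can be dropped
  in; only the frame/band geometry matters downstream.
* **peakRate extraction.** Zero-phase 3rd-order Butterworth bandpass
  1-10 Hz; forward-difference derivative scaled by the frame rate,
  clipped at zero; a sample is a peak iff `d[i] > d[i-1]` and
  `d[i] >= d[i+1]` (left-strict, deterministic on plateaus); events below
  `0.1 sigma` are discarded, with sigma the SD of the whole rectified
  derivative series (one sigma per talker per session, so event sets are
  window-independent).  Envelopes are assumed silence-trimmed upstream.
  No events are emitted within 0.5 s of either end (zero-phase filter
  transients).  An isolated unipolar bump in an otherwise silent
  envelope additionally sheds a small (~6% magnitude) recovery transient
  from the 1 Hz high-pass edge; at syllabic density these transients
  merge into the following rise and do not surface as events.
* **High gamma.** Resample to 500 Hz if higher; 1st-order Butterworth
  high-pass at 1 Hz; local re-reference (subtract the unweighted mean of
  the user-supplied neighbors); 2nd-order IIR notches at 60/120/180/240
  Hz (1 Hz bandwidth); eight contiguous 10 Hz Chebyshev-II bands spanning
  70-150 Hz (40 dB stopband, stopband edges 5 Hz outside each band,
  minimum-order design); per-band analytic magnitude via the Hilbert
  transform, averaged across bands; resample to 100 Hz; per-channel
  z-score against the pre-stimulus silent span.  All filtering is
  zero-phase.  Channels are screened by Cohen's D (pooled, (n-1)-weighted
  SD) between speech and silence, retained strictly above 0.2.
* **Masking arithmetic.** Spectrogram bins are treated as amplitude
  magnitudes, so the dB criterion maps to `10^(dB/20)` (a `power`
  convention, `10^(dB/10)`, is a config switch).  The [-200, 200] ms
  window maps to 41 inclusive frames; ties (`>=`) count as glimpsed; the
  denominator is the full bin count of the window.  With more than two
  sources the background is the element-wise sum of all non-self
  spectrograms.
* **CCA solver.** Covariances of the centered views with ridge 1e-6,
  symmetric inverse square roots by eigendecomposition, SVD of the
  whitened cross-covariance; the top singular pair gives the weights and
  the canonical correlation.  Training uses the attended talker's
  envelope (a `train_on="both"` option stacks the unattended envelope as
  additional pairs).  Zero-variance test windows define `r = 0`;
  correlation ties break to the lower talker index; windows shorter than
  3 samples are an error.
* **Classifier.** `StandardScaler` on the flattened ERP features (RBF
  kernels are scale-sensitive) followed by an SVC calibrated by Platt
  scaling with internal 3-fold cross-validation.  Exact probability ties
  between talkers break deterministically to the lower index.

## Evaluation protocol

Cross-validation splits whole trials into contiguous folds (7 per fold
for the standard 35-trial session).  Continuous decoders slide a window
in 0.1 s steps (configurable); accuracy is the fraction of time steps
whose decision matches the true target, so held decisions are charged at
every step.  Steps before the first evidence update have no defined
decision and are excluded from the denominator (their count is
reported).  Standalone classifiers are scored per (window, talker)
sample over non-overlapping test windows.

Attention switching is simulated by relabeling each test fold so the
target alternates trial by trial (talker streams are swapped on
relabeled trials); switch points are the interior trial boundaries —
6 per 7-trial fold, 30 per 5-fold session.  Evidence traces (probabilities
for ERPC, correlations for CCA) are sampled on a +/-8 s grid around each
switch and averaged; switch latency is the first post-switch time the
new target's average evidence strictly exceeds the old target's (an
exact-equality run leading into the crossing counts; never crossing
reports +inf).  Stability is the distribution of hold durations between
decoded switches, including the initial hold, compared against the trial
durations (the simulated switch intervals).  Method comparisons use
paired t-tests per duration with Bonferroni correction over the duration
grid of one comparison.  The default duration grid
(0.5, 1, 2, 4, 8, 16 s) is a configuration choice; durations longer than
the shortest trial are skipped with a warning.

## Synthetic sessions

The generator emulates the structure of a blocked two-talker listening
experiment on one continuous 100 Hz clock:

* 35 trials; durations `9 + 21 * Beta(2.1, 1.9)` s (range 9-30 s, mean
  20.0 s); the attended talker alternates across 4 blocks.
* Per-talker event streams at ~4 events/s with a 150 ms refractory gap;
  lognormal event magnitudes.
* Per-event glimpse ratios from `Beta(2.709, 1.591)` — moment-matched to
  mean 0.63, SD 0.21 — with labels from the standard 0.9/0.8 thresholds.
* Per-talker envelopes as Gaussian syllabic bumps (SD = width/6, width
  0.3 s) whose rising-edge inflection sits at each event time; Gaussian
  bumps are band-limited well inside 1-10 Hz, so isolated bumps do not
  ring the peakRate filter.  Rank-1 spectrograms (envelope x unit-sum
  spectral profile, distinct profiles per talker) are available for the
  masking path.
* Neural channels: each event adds the ratio-weighted mixture of four
  51-lag kernels indexed by (attended?, glimpsed?), times a per-channel
  gain (uniform 0.5-1.5), plus white noise (SD 1).  The acoustic part is
  an early gamma bump (peak 120 ms) for glimpsed energy and a later one
  (peak 250 ms) for masked energy, attention-independent.  The
  attentional part is a shared component (peak 150 ms) *added* for
  attended-glimpsed and *subtracted* for attended-masked events (signs
  flipped when unattended), so clearly glimpsed and clearly masked
  events are strongly and distinctly attention-modulated while
  intermediate events carry almost no attention information — mirroring
  the empirical finding that classification improves as the glimpse/mask
  criterion is made stricter.  `kernel_contrast` (default 5) is the
  attended-minus-unattended kernel peak for a pure-type event in noise-SD
  units; at 0 the session carries no attention signal and decoding sits
  at chance.

A single seeded RNG stream determines everything; the stored ground
truth (events, kernels, gains, noise seed) reconstructs the neural data
exactly.

What the generator does **not** emulate: real speech acoustics (no
audio waveforms; spectrograms are rank-1), onset responses at trial
pauses, epileptiform or movement artifacts, electrode geometry,
correlated (1/f) noise, and real attention switches (switching is
simulated by relabeling, as in the evaluation protocol).  Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and its
behavior under the stated encoding model, not performance on recorded
iEEG.

Under these conditions the synthetic CCA baseline is strong (the
envelope-to-response mapping is exactly linear and stationary), so CCA
switch latency is near-ideal rather than sluggish as on real recordings;
the stability contrast (CCA flips between talkers far more often than
ERPC) does reproduce.  ERPC's accuracy advantage at short windows and
the superiority of masking-specific classifiers over the generic
all-event classifier both reproduce.

## Problem sizes

Default evaluation runs use the full 35-trial session with 8 channels
and 5 folds.  The replicate study comparing type-specific to generic
classifiers uses ten 21-trial, 6-channel, 3-fold sessions at 1 s
windows; examples use 10-21-trial sessions.  These sizes give stable
statistics (hundreds of decoding windows per fold) while keeping any
single analysis in the seconds-to-minutes range.

## Known limitations

* The constant-Q front end approximates the published cochlear-model
  spectrogram; exact NSL bandwidths and nonlinearities are not
  reproduced (the filter bank is swappable).
* Event-to-frame alignment rounds event times to the nearest 10 ms
  frame.
* Pre-first-evidence steps are excluded from accuracy rather than
  defaulting to 0.5 (flag available at the call site).
* The trace decoder treats a fold as one contiguous span; ERPs near
  trial boundaries read into the neighboring trial of the same fold,
  exactly as when trials are concatenated.
* Electrode localization, artifact rejection, and behavioral scoring are
  out of scope.
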