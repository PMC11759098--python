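# aaderp

Auditory attention decoding (AAD) from intracranial-style neural
recordings by **classifying event-related potentials (ERPs) to glimpsed
and masked acoustic events**, with a canonical-correlation-analysis (CCA)
baseline and a full evaluation suite.

## Who this is for

Researchers working on neuro-steered hearing devices and multitalker
speech perception.  In a two-talker scene, a listener's auditory cortex
preferentially tracks the attended talker.  Classical AAD correlates the
speech envelope with the neural response (CCA) regardless of how much
the talkers overlap at any moment.  This package implements an
event-based alternative: it finds **peakRate events** (local maxima of
the rate of change of the 1-10 Hz speech envelope — acoustic edges near
syllable onsets), scores each event's energetic masking against the
competing talker, and classifies the high-gamma ERPs to clearly
*glimpsed* and clearly *masked* events with calibrated SVMs to decide,
per talker, whether its events look target-evoked.

## The method in brief

For talker spectrograms `S_T` (self) and `S_B` (background), an event's
glimpse ratio over the [-200, +200] ms window is

    ratio_G = |S_T >= S_B * SNR_G| / |S_T|,      SNR_G = -4 dB,

the fraction of spectrotemporal bins where the talker stays within 4 dB
of the background; `ratio_M = 1 - ratio_G`.  Events with `ratio_G > 0.9`
are glimpsed, `ratio_M > 0.8` masked.  For a decoding window, the
[0, 500] ms high-gamma responses to a talker's glimpsed events are
averaged per channel into an `N_ch x 51` feature vector and classified
(RBF-SVM, C = 10, Platt scaling); likewise for masked events.  The
talker's probability of being attended is the mean of the two
classifiers (or the single available one); the higher-probability talker
is decoded.  Windows with no labeled events hold the previous decision
or fall back to CCA (which uses [-500, 0] ms envelope lags and the top
canonical component).  See `docs/methods.md` for every numerical choice.

## Worked example

`examples/03_decode_session.py` generates a synthetic 14-trial
two-talker session (known attention-modulated event responses plus
noise) and runs cross-validated continuous decoding:

```
session: 271 s, 2173 events, 6 channels
time-step decoding accuracy (fraction of 100 ms steps correct):
  cca           2 s: 0.831      4 s: 0.916
  erpc-hold     2 s: 0.972      4 s: 0.983
```

Each number is the percentage of 100 ms time steps on which the
continuously operating decoder named the truly attended talker, for a
2 s and a 4 s decoding window; the event-based classifier (`erpc-hold`)
beats the correlation baseline, most clearly at the short window.
`examples/04_attention_switching.py` adds simulated attention switches
and prints switch latency (time for the evidence to favor the new
target; ideal is half the window) and decoding stability (how long each
decoded target is held):

```
erpc-hold  18 switches | latency 2.3 s (ideal 2.0 s) | decoded switches: 20, 5% held < 4 s ...
cca        18 switches | latency 2.1 s (ideal 2.0 s) | decoded switches: 112, 75% held < 4 s ...
```

The other examples cover peakRate extraction against known syllable
times and glimpse/mask scoring of a two-talker mixture.

## Command line

A thin CLI wraps the library for file-based pipelines:

```bash
aaderp synth --seed 7 --out session.h5            # synthetic session
aaderp features --wav A.wav --wav B.wav --out feats.h5
aaderp events --features feats.h5 --out events.csv
aaderp mask --features feats.h5 --events events.csv --out labeled.csv
aaderp decode --session session.h5 --mode erpc-hold --duration 4 --out trace.csv
aaderp evaluate --session session.h5 --methods cca,erpc-hold --durations 2,4,8 --out curve.csv
aaderp switchsim --session session.h5 --method erpc-hold --duration 4
```

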