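"""Synthetic two-talker sessions with known ground truth.

The generator emulates the structure of a two-talker selective-attention
experiment: 35 trials of 9-30 s (mean ~20 s) concatenated into one
continuous 100 Hz session; per-talker peakRate event streams (~4 events/s,
syllabic rate, 150 ms refractory); per-event glimpse ratios drawn from a
Beta distribution moment-matched to a mean of 0.63 and SD of 0.21; and
multichannel high-gamma-like neural envelopes in which each event evokes a
51-lag response kernel whose shape depends on the event's masking (glimpsed
vs masked) and whose amplitude depends on whether the event's talker is
attended, plus white noise.

Each event's response is the ratio-weighted mixture of the four kernels
indexed by (attended?, glimpsed?).  The acoustic part differs by masking
(an early bump, peak ~120 ms, for glimpsed energy; a later bump, peak
~250 ms, for masked energy) and is attention-independent; the attentional
part is a shared component added for attended-glimpsed and
attended-masked events with opposite signs, so clearly glimpsed and
clearly masked events are strongly (and distinctly) attention-modulated
while events of intermediate masking carry almost no attention
information — the same structure seen in real recordings, where
classification improves as the glimpse/mask criterion is made stricter.
``kernel_contrast`` is the attended-minus-unattended kernel difference
for a fully glimpsed (or fully masked) event, in units of the noise SD.

Everything downstream (event extraction, masking, ERPC, CCA, switching
analyses) can be exercised end-to-end against the stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import Envelope, PeakRateEvent, Spectrogram
from .masking import MaskingConfig, allocate_events
from .neural import NeuralEnvelope

__all__ = [
    "SessionSpec",
    "GroundTruth",
    "Session",
    "EnvelopePair",
    "generate_session",
    "generate_envelope_pair",
    "envelope_from_bumps",
    "rank1_spectrogram",
    "response_kernels",
    "render_neural",
]

N_KERNEL_LAGS = 51
RATE = 100.0


@dataclass
class SessionSpec:
    """Study conditions of a synthetic two-talker session."""

    n_trials: int = 35
    trial_min_s: float = 9.0
    trial_max_s: float = 30.0
    # Beta(2.1, 1.9) scaled to [min, max] has mean 20.0 s
    trial_beta: tuple[float, float] = (2.1, 1.9)
    event_rate_hz: float = 4.0
    refractory_s: float = 0.15
    glimpse_mean: float = 0.63
    glimpse_sd: float = 0.21
    n_channels: int = 8
    #: attended-minus-unattended kernel peak difference (for a fully
    #: glimpsed or fully masked event), in noise-SD units
    kernel_contrast: float = 5.0
    #: peak amplitude of the attention-independent acoustic response
    acoustic_amp: float = 0.5
    noise_sd: float = 1.0
    n_blocks: int = 4
    seed: int = 0

    def glimpse_beta_params(self) -> tuple[float, float]:
        m, v = self.glimpse_mean, self.glimpse_sd**2
        nu = m * (1 - m) / v - 1
        if nu <= 0:
            raise ValueError("glimpse_sd too large for a Beta distribution")
        return m * nu, (1 - m) * nu


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the generated neural data."""

    events: pd.DataFrame  # talker, time_s, frame, magnitude, glimpse_ratio, label, attended, trial
    kernels: dict  # (attended: bool, type: str) -> (n_channels, 51) effective kernels
    channel_gains: np.ndarray
    trial_targets: np.ndarray
    noise_seed: int


@dataclass
class Session:
    """A complete synthetic session on a single 100 Hz clock."""

    spec: SessionSpec
    rate: float
    trial_starts_s: np.ndarray
    trial_durations_s: np.ndarray
    trial_targets: np.ndarray
    envelopes: list[Envelope]
    neural: NeuralEnvelope
    truth: GroundTruth

    @property
    def n_frames(self) -> int:
        return self.neural.n_frames

    @property
    def duration_s(self) -> float:
        return float(self.trial_starts_s[-1] + self.trial_durations_s[-1])

    def trials(self) -> list[tuple[float, float, int]]:
        return [
            (float(s), float(d), int(t))
            for s, d, t in zip(self.trial_starts_s, self.trial_durations_s, self.trial_targets)
        ]

    def trial_spans_f(self) -> np.ndarray:
        s = np.round(self.trial_starts_s * self.rate).astype(int)
        e = np.round((self.trial_starts_s + self.trial_durations_s) * self.rate).astype(int)
        return np.stack([s, e], axis=1)

    def event_frames(self, talker: int | None = None) -> dict:
        """Per-talker event-onset frames split by masking label.

        Returns {talker: {"all"|"glimpsed"|"masked": sorted frame array}}
        (or the inner dict when ``talker`` is given).  "all" contains every
        ratio-set event regardless of label.
        """
        out = {}
        df = self.truth.events
        for t in (0, 1):
            sub = df[df.talker == t]
            typed = {
                "all": np.sort(sub.frame.to_numpy()),
                "glimpsed": np.sort(sub.frame[sub.label == "glimpsed"].to_numpy()),
                "masked": np.sort(sub.frame[sub.label == "masked"].to_numpy()),
            }
            out[t] = typed
        return out if talker is None else out[talker]

    def events_list(self, talker: int) -> list[PeakRateEvent]:
        df = self.truth.events
        sub = df[df.talker == talker]
        return [
            PeakRateEvent(
                time_s=row.time_s,
                magnitude=row.magnitude,
                talker_id=str(talker),
                glimpse_ratio=row.glimpse_ratio,
                mask_ratio=1.0 - row.glimpse_ratio,
                label=row.label,
            )
            for row in sub.itertuples()
        ]


# ---------------------------------------------------------------------------
# building blocks


def _kernel_shape(peak_s: float, sharpness: float = 3.0, rate: float = RATE) -> np.ndarray:
    """Gamma-function bump over [0, 500] ms, unit peak at ``peak_s``."""
    tau = np.arange(N_KERNEL_LAGS) / rate
    with np.errstate(divide="ignore", invalid="ignore"):
        x = tau / peak_s
        k = np.where(tau > 0, x**sharpness * np.exp(sharpness * (1 - x)), 0.0)
    return k / k.max()


def response_kernels(spec: SessionSpec, rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """Effective (attended?, type) -> channels x 51 kernels and channel gains.

    kernel(att, G) = acoustic_G + s * attention/2 and
    kernel(att, M) = acoustic_M - s * attention/2 with s = +1 when
    attended and -1 otherwise, so the attended-vs-unattended difference
    for a pure glimpsed (or masked) event has peak ``kernel_contrast *
    noise_sd`` and the ratio-weighted mixture at glimpse ratio 0.5
    carries no attention information.
    """
    gains = rng.uniform(0.5, 1.5, spec.n_channels)
    acoustic_g = spec.acoustic_amp * _kernel_shape(0.12)
    acoustic_m = spec.acoustic_amp * _kernel_shape(0.25)
    attention = 0.5 * spec.kernel_contrast * spec.noise_sd * _kernel_shape(0.15)
    kernels = {}
    for attended in (True, False):
        s = 1.0 if attended else -1.0
        kernels[(attended, "glimpsed")] = gains[:, None] * (acoustic_g + s * attention)[None, :]
        kernels[(attended, "masked")] = gains[:, None] * (acoustic_m - s * attention)[None, :]
    return kernels, gains


def render_neural(
    events: pd.DataFrame,
    kernels: dict,
    n_channels: int,
    n_frames: int,
    noise_sd: float = 0.0,
    noise_seed: int | None = None,
) -> np.ndarray:
    """Superpose per-event response kernels (ratio-weighted mixture) + noise.

    Each event adds ``g * K(attended, glimpsed) + (1-g) * K(attended,
    masked)`` at its onset frame, where g is the event's glimpse ratio.
    """
    for key in kernels:
        if kernels[key].shape != (n_channels, N_KERNEL_LAGS):
            raise ValueError(f"kernel {key} must have shape (n_channels, {N_KERNEL_LAGS})")
    out = np.zeros((n_channels, n_frames))
    for row in events.itertuples():
        f = int(row.frame)
        if f < 0 or f + N_KERNEL_LAGS > n_frames:
            continue
        att = bool(row.attended)
        mix = row.glimpse_ratio * kernels[(att, "glimpsed")] + (1.0 - row.glimpse_ratio) * kernels[
            (att, "masked")
        ]
        out[:, f : f + N_KERNEL_LAGS] += mix
    if noise_sd > 0:
        nrng = np.random.default_rng(noise_seed)
        out += nrng.normal(0.0, noise_sd, out.shape)
    return out


def envelope_from_bumps(
    times_s: np.ndarray,
    magnitudes: np.ndarray | float,
    duration_s: float,
    rate: float = RATE,
    width_s: float = 0.3,
    talker_id: str = "",
) -> Envelope:
    """Sum of Gaussian syllabic bumps with maximal slope at each time.

    Bump SD is ``width_s / 6`` (so the bump effectively spans
    ``width_s``) and centers sit one SD after the requested times, placing
    the rising-edge inflection — the peakRate location — at each time.
    Gaussian bumps are band-limited well inside the 1-10 Hz peakRate
    band, so isolated bumps do not excite filter ringing.
    """
    times_s = np.asarray(times_s, dtype=float)
    mags = np.broadcast_to(np.asarray(magnitudes, dtype=float), times_s.shape)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    env = np.zeros(n)
    sd = width_s / 6.0
    for tc, m in zip(times_s + sd, mags):
        sel = np.abs(t - tc) <= 5 * sd
        env[sel] += m * np.exp(-0.5 * ((t[sel] - tc) / sd) ** 2)
    return Envelope(env, rate=rate, talker_id=talker_id)


def _spectral_profile(n_bands: int, center: float, width: float) -> np.ndarray:
    x = np.arange(n_bands)
    p = np.exp(-0.5 * ((x - center) / width) ** 2) + 1e-4
    return p / p.sum()


def rank1_spectrogram(env: Envelope, profile: np.ndarray, talker_id: str = "") -> Spectrogram:
    """Rank-1 spectrogram env x spectral profile; profile sums to 1, so
    summing bins recovers the envelope exactly."""
    from .audio import _default_centers

    values = env.values[:, None] * profile[None, :]
    return Spectrogram(
        values,
        frame_rate=env.rate,
        freq_centers=_default_centers(profile.size),
        talker_id=talker_id or env.talker_id,
    )


def _event_times(
    rng: np.random.Generator, t_lo: float, t_hi: float, rate_hz: float, refractory_s: float
) -> np.ndarray:
    """Refractory Poisson stream with overall rate ``rate_hz`` on [t_lo, t_hi]."""
    mean_gap = 1.0 / rate_hz
    exp_mean = max(mean_gap - refractory_s, 1e-3)
    times = []
    t = t_lo + rng.exponential(exp_mean)
    while t < t_hi:
        times.append(t)
        t += refractory_s + rng.exponential(exp_mean)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# session generation


def generate_session(spec: SessionSpec | None = None, seed: int | None = None) -> Session:
    """Generate a complete synthetic session (events, envelopes, neural).

    The target talker alternates across ``n_blocks`` blocks of trials (as
    in a block-design attention experiment).  Event labels follow the
    standard glimpse/mask thresholds (glimpse ratio > 0.9, mask ratio
    > 0.8).  The seed fully determines the output.
    """
    spec = spec or SessionSpec()
    if seed is not None:
        spec = SessionSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)

    a, b = spec.trial_beta
    durs = spec.trial_min_s + (spec.trial_max_s - spec.trial_min_s) * rng.beta(
        a, b, spec.n_trials
    )
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    total = float(starts[-1] + durs[-1])
    n_frames = int(round(total * RATE))

    block = np.minimum(
        (np.arange(spec.n_trials) * spec.n_blocks) // spec.n_trials, spec.n_blocks - 1
    )
    targets = (block % 2).astype(int)  # block-alternating attended talker

    ga, gb = spec.glimpse_beta_params()
    rows = []
    for talker in (0, 1):
        times = _event_times(rng, 0.5, total - 0.8, spec.event_rate_hz, spec.refractory_s)
        mags = rng.lognormal(0.0, 0.2, times.size)
        ratios = rng.beta(ga, gb, times.size)
        trial_idx = np.searchsorted(starts, times, side="right") - 1
        attended = targets[trial_idx] == talker
        for t, m, g, tr, att in zip(times, mags, ratios, trial_idx, attended):
            rows.append((talker, t, int(round(t * RATE)), m, g, int(tr), bool(att)))
    events = pd.DataFrame(
        rows, columns=["talker", "time_s", "frame", "magnitude", "glimpse_ratio", "trial", "attended"]
    ).sort_values(["talker", "time_s"], ignore_index=True)

    mcfg = MaskingConfig()
    labeled = allocate_events(
        [
            PeakRateEvent(r.time_s, r.magnitude, str(r.talker), r.glimpse_ratio, 1 - r.glimpse_ratio)
            for r in events.itertuples()
        ],
        mcfg,
    )
    events["label"] = [ev.label for ev in labeled]

    kernels, gains = response_kernels(spec, rng)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    neural_vals = render_neural(
        events, kernels, spec.n_channels, n_frames, spec.noise_sd, noise_seed
    )
    neural = NeuralEnvelope(neural_vals, rate=RATE)

    envelopes = []
    for talker in (0, 1):
        sub = events[events.talker == talker]
        envelopes.append(
            envelope_from_bumps(
                sub.time_s.to_numpy(), sub.magnitude.to_numpy(), total, talker_id=str(talker)
            )
        )

    truth = GroundTruth(
        events=events,
        kernels=kernels,
        channel_gains=gains,
        trial_targets=targets,
        noise_seed=noise_seed,
    )
    return Session(
        spec=spec,
        rate=RATE,
        trial_starts_s=starts,
        trial_durations_s=durs,
        trial_targets=targets,
        envelopes=envelopes,
        neural=neural,
        truth=truth,
    )


@dataclass
class EnvelopePair:
    """Two talkers' synthetic envelopes + rank-1 spectrograms + bump times."""

    envelopes: list[Envelope]
    spectrograms: list[Spectrogram]
    bump_times: list[np.ndarray]


def generate_envelope_pair(
    duration_s: float = 60.0,
    event_rate_hz: float = 4.0,
    refractory_s: float = 0.15,
    seed: int = 0,
    alternate: bool = False,
    n_bands: int = 100,
    profile_centers: tuple[float, float] = (30.0, 60.0),
    profile_width: float = 10.0,
) -> EnvelopePair:
    """Bump-train envelopes and rank-1 spectrograms for two talkers.

    ``alternate=True`` interleaves the two talkers' bumps on a sparse grid
    whose spacing clears the +/-200 ms masking window plus a bump width,
    so the background is silent around every event (nearly all events
    glimpsed).
    """
    rng = np.random.default_rng(seed)
    times: list[np.ndarray] = []
    if alternate:
        spacing = max(1.0 / event_rate_hz, 1.0)
        grid = np.arange(1.0, duration_s - 1.0, spacing)
        times = [grid[::2], grid[1::2]]
    else:
        for _ in range(2):
            times.append(_event_times(rng, 1.0, duration_s - 1.0, event_rate_hz, refractory_s))
    envelopes, spectrograms = [], []
    for talker in (0, 1):
        mags = rng.lognormal(0.0, 0.2, times[talker].size)
        env = envelope_from_bumps(times[talker], mags, duration_s, talker_id=str(talker))
        profile = _spectral_profile(n_bands, profile_centers[talker], profile_width)
        envelopes.append(env)
        spectrograms.append(rank1_spectrogram(env, profile, talker_id=str(talker)))
    return EnvelopePair(envelopes=envelopes, spectrograms=spectrograms, bump_times=times)
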