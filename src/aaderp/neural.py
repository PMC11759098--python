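"""Neural preprocessing: high-gamma envelopes, channel screening, ERPs.

Raw multichannel recordings are turned into normalized 100 Hz high-gamma
(70-150 Hz) envelopes: high-pass at 1 Hz, local re-referencing against
each channel's spatial neighbors, line-noise notches, an 8 x 10 Hz
Chebyshev-II band decomposition with per-band Hilbert magnitudes averaged
into one envelope, resampling to 100 Hz, and z-scoring against a
pre-stimulus silent baseline.  Channels are screened for speech
responsiveness by Cohen's D between speech and silence, and event-related
potentials are the [0, 500] ms envelope segments following peakRate
events, averaged per channel over the events in a decoding window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .audio import PeakRateEvent

__all__ = [
    "RawRecording",
    "NeuralEnvelope",
    "ErpSample",
    "extract_high_gamma",
    "screen_speech_responsive",
    "cohens_d",
    "average_erp",
    "erp_matrix",
]

HG_BAND_EDGES = np.arange(70, 151, 10)  # 8 contiguous 10 Hz bands, 70-150 Hz
NOTCH_FREQS = (60.0, 120.0, 180.0, 240.0)


@dataclass
class RawRecording:
    """Raw broadband recording with re-referencing and baseline metadata."""

    samples: np.ndarray  # channels x time
    rate: float
    channel_ids: list[str] = field(default_factory=list)
    neighbor_map: Mapping[str, Sequence[str]] | None = None
    prestim_span: tuple[float, float] | None = None  # seconds on recording clock

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids does not match number of channels")


@dataclass
class NeuralEnvelope:
    """Channels x time high-gamma envelope at the 100 Hz analysis rate."""

    values: np.ndarray
    rate: float = 100.0
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.values.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ErpSample:
    """Per-channel average response over events in one decoding window."""

    values: np.ndarray  # channels x lags
    lag_span_s: tuple[float, float] = (0.0, 0.5)
    n_events: int = 1
    event_type: str = "all"
    talker_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.n_events < 1:
            raise ValueError("an ERP must average at least one event")

    def flatten(self) -> np.ndarray:
        """Feature vector of length n_channels x n_lags."""
        return self.values.ravel()


# ---------------------------------------------------------------------------
# high-gamma extraction


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    frac = Fraction(int(round(rate_out)), int(round(rate_in))).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def _local_rereference(
    x: np.ndarray, channel_ids: Sequence[str], neighbor_map: Mapping[str, Sequence[str]]
) -> np.ndarray:
    idx = {cid: i for i, cid in enumerate(channel_ids)}
    out = np.empty_like(x)
    for i, cid in enumerate(channel_ids):
        nbs = [idx[n] for n in neighbor_map.get(cid, []) if n in idx]
        if not nbs:
            raise ValueError(f"channel {cid!r} has no neighbors for re-referencing")
        out[i] = x[i] - x[nbs].mean(axis=0)
    return out


def _hg_band_sos(rate: float) -> list[np.ndarray]:
    sos_list = []
    for lo, hi in zip(HG_BAND_EDGES[:-1], HG_BAND_EDGES[1:]):
        n, wn = signal.cheb2ord([lo, hi], [lo - 5.0, hi + 5.0], gpass=1.0, gstop=40.0, fs=rate)
        sos_list.append(signal.cheby2(n, 40.0, wn, btype="bandpass", fs=rate, output="sos"))
    return sos_list


def extract_high_gamma(
    raw: RawRecording,
    out_rate: float = 100.0,
    work_rate: float = 500.0,
) -> NeuralEnvelope:
    """Normalized 100 Hz high-gamma envelope of a raw recording.

    All filters are applied zero-phase (forward-backward).  The output is
    z-scored per channel against the pre-stimulus silent span.
    """
    if raw.rate < 2 * HG_BAND_EDGES[-1] + 10:
        raise ValueError("sampling rate too low to contain the 150 Hz band")
    if raw.prestim_span is None:
        raise ValueError("prestim_span is required for baseline normalization")

    x = raw.samples
    rate = raw.rate
    if rate > work_rate:
        x = _resample(x, rate, work_rate)
        rate = work_rate

    sos_hp = signal.butter(1, 1.0, btype="highpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos_hp, x, axis=-1)

    if raw.neighbor_map is not None:
        x = _local_rereference(x, raw.channel_ids, raw.neighbor_map)

    for f0 in NOTCH_FREQS:
        if f0 >= rate / 2:
            continue
        b, a = signal.iirnotch(f0, Q=f0 / 1.0, fs=rate)
        x = signal.filtfilt(b, a, x, axis=-1)

    n = x.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(max(n, 2))))
    env = np.zeros_like(x)
    for sos in _hg_band_sos(rate):
        band = signal.sosfiltfilt(sos, x, axis=-1)
        analytic = signal.hilbert(band, N=nfft, axis=-1)[..., :n]
        env += np.abs(analytic)
    env /= len(HG_BAND_EDGES) - 1

    env = _resample(env, rate, out_rate)
    np.maximum(env, 0.0, out=env)

    t0, t1 = raw.prestim_span
    lo, hi = int(round(t0 * out_rate)), int(round(t1 * out_rate))
    if not (0 <= lo < hi <= env.shape[-1]):
        raise ValueError("prestim_span lies outside the recording")
    base = env[:, lo:hi]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return NeuralEnvelope((env - mu) / sd, rate=out_rate, channel_ids=list(raw.channel_ids))


# ---------------------------------------------------------------------------
# channel screening


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's D with the pooled (n-1)-weighted standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per condition")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return np.nan
    return float((a.mean() - b.mean()) / pooled)


def screen_speech_responsive(
    env: NeuralEnvelope,
    speech_mask: np.ndarray,
    silence_mask: np.ndarray,
    d_min: float = 0.2,
) -> list[str]:
    """Channels whose speech-vs-silence effect size exceeds ``d_min``.

    Retention requires strictly ``D > d_min``; channels with zero pooled
    SD are excluded with a warning.
    """
    speech_mask = np.asarray(speech_mask, dtype=bool)
    silence_mask = np.asarray(silence_mask, dtype=bool)
    if np.any(speech_mask & silence_mask):
        raise ValueError("speech and silence masks overlap")
    kept = []
    for i, cid in enumerate(env.channel_ids):
        d = cohens_d(env.values[i, speech_mask], env.values[i, silence_mask])
        if np.isnan(d):
            warnings.warn(f"channel {cid!r} has zero pooled SD; excluded")
            continue
        if d > d_min:
            kept.append(cid)
    return kept


# ---------------------------------------------------------------------------
# ERPs


def n_lags(window: tuple[float, float] = (0.0, 0.5), rate: float = 100.0) -> int:
    """Inclusive lag count: (t_max - t_min) * rate + 1 (= 51 by default)."""
    return int(round((window[1] - window[0]) * rate)) + 1


def erp_matrix(
    env: NeuralEnvelope,
    event_frames: np.ndarray,
    window: tuple[float, float] = (0.0, 0.5),
) -> np.ndarray:
    """Stacked single-event ERPs, shape (n_events, n_channels, n_lags)."""
    nl = n_lags(window, env.rate)
    off = int(round(window[0] * env.rate))
    frames = np.asarray(event_frames, dtype=int) + off
    if frames.size and (frames.min() < 0 or frames.max() + nl > env.n_frames):
        raise ValueError("an event lacks full ERP coverage in the recording")
    idx = frames[:, None] + np.arange(nl)[None, :]
    return env.values[:, idx].transpose(1, 0, 2)


def average_erp(
    env: NeuralEnvelope,
    events: Sequence[PeakRateEvent] | np.ndarray,
    window: tuple[float, float] = (0.0, 0.5),
    event_type: str = "all",
    talker_id: str = "",
) -> ErpSample:
    """Mean [0, 500] ms response over a set of events (>= 1 required)."""
    if isinstance(events, np.ndarray):
        frames = np.asarray(events, dtype=int)
    else:
        frames = np.array([int(round(ev.time_s * env.rate)) for ev in events], dtype=int)
    if frames.size == 0:
        raise ValueError("average_erp requires at least one event")
    stack = erp_matrix(env, frames, window)
    return ErpSample(
        stack.mean(axis=0),
        lag_span_s=window,
        n_events=frames.size,
        event_type=event_type,
        talker_id=talker_id,
    )
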