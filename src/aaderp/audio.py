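"""Acoustic feature extraction: auditory spectrograms, envelopes, peakRate events.

The front end mirrors the standard cochleagram-based pipeline used in
intracranial speech studies: a constant-Q filter bank (100 bands,
log-spaced 50 Hz - 8 kHz) produces a 10 ms-frame auditory spectrogram;
summing across frequency gives a 100 Hz broadband envelope; acoustic
"peakRate" events are the thresholded local maxima of the half-wave
rectified derivative of the 1-10 Hz band-limited envelope.  peakRate
events sit near syllabic-nucleus onsets and are the anchor points for
all downstream event-related decoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Spectrogram",
    "Envelope",
    "SpectrogramConfig",
    "PeakRateConfig",
    "PeakRateEvent",
    "compute_spectrogram",
    "compute_envelope",
    "extract_peakrate_events",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Spectrogram:
    """Time x frequency magnitude matrix for one talker.

    ``values[t, f]`` is the non-negative magnitude of band ``f`` in 10 ms
    frame ``t``.  ``freq_centers`` holds the 100 log-spaced band center
    frequencies (Hz), strictly increasing.
    """

    values: np.ndarray
    frame_rate: float = 100.0
    freq_centers: np.ndarray = field(default_factory=lambda: _default_centers())
    talker_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freq_centers = np.asarray(self.freq_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram must be 2-D (time x frequency)")
        if self.values.shape[1] != self.freq_centers.size:
            raise ValueError("frequency axis does not match freq_centers")
        if np.any(self.values < 0):
            raise ValueError("spectrogram magnitudes must be non-negative")
        if np.any(np.diff(self.freq_centers) <= 0):
            raise ValueError("freq_centers must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]


@dataclass
class Envelope:
    """1-D non-negative broadband envelope at ``rate`` Hz (100 by default)."""

    values: np.ndarray
    rate: float = 100.0
    talker_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be 1-D")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate


@dataclass
class SpectrogramConfig:
    """Constant-Q auditory-spectrogram settings.

    100 bands log-spaced between 50 Hz and 8 kHz, leaky integration with a
    4 ms time constant, and 10 ms output frames.  Q is fixed so adjacent
    bands meet near their -3 dB points (band edges at the geometric means
    between neighboring centers).
    """

    n_bands: int = 100
    f_lo: float = 50.0
    f_hi: float = 8000.0
    frame_rate: float = 100.0
    integration_tau_s: float = 0.004
    sample_rate: float = 16000.0
    filter_order: int = 2


@dataclass
class PeakRateConfig:
    """peakRate extraction settings.

    The envelope is band-limited to ``band_lo``-``band_hi`` Hz with a
    zero-phase Butterworth filter of ``filter_order`` before
    differentiation.  Events whose rate magnitude falls below
    ``magnitude_threshold_scale`` x sigma are discarded, where sigma is the
    standard deviation of the whole half-wave rectified derivative series.
    No events are emitted within ``edge_margin_s`` of either end (filter
    settling).
    """

    band_lo: float = 1.0
    band_hi: float = 10.0
    filter_order: int = 3
    magnitude_threshold_scale: float = 0.1
    edge_margin_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("need 0 < band_lo < band_hi")
        if self.magnitude_threshold_scale < 0:
            raise ValueError("magnitude_threshold_scale must be >= 0")


@dataclass
class PeakRateEvent:
    """A timestamped acoustic event with optional masking annotation.

    ``glimpse_ratio``/``mask_ratio`` are filled by the masking module; they
    sum to 1 when set.  ``label`` is one of ``glimpsed``/``masked``/
    ``unlabeled``.
    """

    time_s: float
    magnitude: float
    talker_id: str = ""
    glimpse_ratio: float | None = None
    mask_ratio: float | None = None
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("event time must be >= 0")
        if self.glimpse_ratio is not None and self.mask_ratio is not None:
            if abs(self.glimpse_ratio + self.mask_ratio - 1.0) > 1e-9:
                raise ValueError("glimpse_ratio + mask_ratio must equal 1")

    def with_ratios(self, glimpse_ratio: float | None, label: str = "unlabeled") -> "PeakRateEvent":
        if glimpse_ratio is None:
            return replace(self, glimpse_ratio=None, mask_ratio=None, label="unlabeled")
        return replace(
            self,
            glimpse_ratio=float(glimpse_ratio),
            mask_ratio=1.0 - float(glimpse_ratio),
            label=label,
        )


def _default_centers(n_bands: int = 100, f_lo: float = 50.0, f_hi: float = 8000.0) -> np.ndarray:
    return np.geomspace(f_lo, f_hi, n_bands)


# ---------------------------------------------------------------------------
# spectrogram


def constant_q_filterbank(cfg: SpectrogramConfig) -> tuple[np.ndarray, list[np.ndarray]]:
    """Design the constant-Q bandpass bank; returns (centers, sos list).

    Band edges are the geometric means between adjacent centers (so the
    fractional bandwidth, hence Q, is constant).  The top edge is clipped
    just under Nyquist.
    """
    centers = _default_centers(cfg.n_bands, cfg.f_lo, cfg.f_hi)
    ratio = centers[1] / centers[0]
    half = math.sqrt(ratio)
    nyq = cfg.sample_rate / 2.0
    sos_list = []
    for cf in centers:
        lo = cf / half
        hi = min(cf * half, 0.999 * nyq)
        sos = signal.butter(
            cfg.filter_order, [lo, hi], btype="bandpass", fs=cfg.sample_rate, output="sos"
        )
        sos_list.append(sos)
    return centers, sos_list


def compute_spectrogram(
    wave: np.ndarray,
    cfg: SpectrogramConfig | None = None,
    sample_rate: float | None = None,
    talker_id: str = "",
    filterbank=constant_q_filterbank,
) -> Spectrogram:
    """Constant-Q auditory spectrogram of a mono waveform.

    Pipeline: bandpass bank -> half-wave rectification -> leaky
    integration (tau = 4 ms) -> mean over 10 ms frames.  ``filterbank`` is
    swappable so an exact cochlear-model backend can be substituted.

    The output has ``ceil(duration / 10 ms)`` frames and one column per
    band; magnitudes are non-negative.
    """
    cfg = cfg or SpectrogramConfig()
    wave = np.asarray(wave, dtype=float).squeeze()
    if wave.ndim != 1 or wave.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    if not np.all(np.isfinite(wave)):
        raise ValueError("waveform contains non-finite samples")
    if sample_rate is not None and sample_rate != cfg.sample_rate:
        from fractions import Fraction

        frac = Fraction(int(round(cfg.sample_rate)), int(round(sample_rate))).limit_denominator(1000)
        wave = signal.resample_poly(wave, frac.numerator, frac.denominator)

    sr = cfg.sample_rate
    centers, sos_list = filterbank(cfg)
    n = wave.size
    frame_len = sr / cfg.frame_rate
    n_frames = int(math.ceil(n / frame_len))
    starts = np.minimum((np.arange(n_frames) * frame_len).astype(int), n - 1)

    # one-pole leaky integrator y[k] = a*y[k-1] + (1-a)*x[k]
    a = math.exp(-1.0 / (sr * cfg.integration_tau_s))
    out = np.empty((n_frames, len(sos_list)))
    counts = np.diff(np.append(starts, n))
    for j, sos in enumerate(sos_list):
        band = signal.sosfilt(sos, wave)
        np.maximum(band, 0.0, out=band)
        band = signal.lfilter([1.0 - a], [1.0, -a], band)
        out[:, j] = np.add.reduceat(band, starts) / counts
    np.maximum(out, 0.0, out=out)
    return Spectrogram(out, frame_rate=cfg.frame_rate, freq_centers=centers, talker_id=talker_id)


# ---------------------------------------------------------------------------
# envelope


def compute_envelope(spec: Spectrogram) -> Envelope:
    """Broadband envelope: sum of all frequency bins per frame (100 Hz)."""
    return Envelope(spec.values.sum(axis=1), rate=spec.frame_rate, talker_id=spec.talker_id)


# ---------------------------------------------------------------------------
# peakRate events


def rectified_rate(env: Envelope, cfg: PeakRateConfig | None = None) -> np.ndarray:
    """Half-wave rectified derivative of the 1-10 Hz filtered envelope.

    Returned series has ``len(env) - 1`` samples; element i is the forward
    difference between samples i and i+1, scaled to units/s, clipped at 0.
    """
    cfg = cfg or PeakRateConfig()
    x = env.values
    if x.size < 3:
        raise ValueError("envelope too short for peakRate extraction")
    sos = signal.butter(
        cfg.filter_order, [cfg.band_lo, cfg.band_hi], btype="bandpass", fs=env.rate, output="sos"
    )
    filt = signal.sosfiltfilt(sos, x)
    d = np.diff(filt) * env.rate
    np.maximum(d, 0.0, out=d)
    return d


def extract_peakrate_events(
    env: Envelope, cfg: PeakRateConfig | None = None
) -> list[PeakRateEvent]:
    """Thresholded local maxima of the positive envelope rate of change.

    A sample i is a peak iff ``d[i] > d[i-1]`` and ``d[i] >= d[i+1]``
    (left-strict, deterministic on plateaus).  Peaks with magnitude below
    ``0.1 * sigma`` are discarded, sigma being the SD of the whole
    rectified-derivative series.  Events within 0.5 s of either end are
    suppressed (zero-phase filter transients).
    """
    cfg = cfg or PeakRateConfig()
    d = rectified_rate(env, cfg)
    sigma = float(np.std(d))
    # absolute floor guards against numerically-zero derivatives of flat
    # envelopes being promoted to events
    floor = 1e-9 * env.rate * max(float(np.max(np.abs(env.values))), 1e-12)
    thresh = max(cfg.magnitude_threshold_scale * sigma, floor)

    i = np.arange(1, d.size - 1)
    is_peak = (d[i] > d[i - 1]) & (d[i] >= d[i + 1])
    peaks = i[is_peak]
    peaks = peaks[d[peaks] >= thresh]
    # derivative sample i sits between envelope samples i and i+1
    times = (peaks + 0.5) / env.rate
    lo = cfg.edge_margin_s
    hi = env.duration_s - cfg.edge_margin_s
    keep = (times >= lo) & (times <= hi)
    return [
        PeakRateEvent(time_s=float(t), magnitude=float(d[p]), talker_id=env.talker_id)
        for t, p in zip(times[keep], peaks[keep])
        if d[p] > 0
    ]
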