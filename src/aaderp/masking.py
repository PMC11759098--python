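"""Glimpse/mask quantification of acoustic events against competing talkers.

In a multi-talker mixture, a spectrotemporal bin of a talker is "glimpsed"
when its magnitude is at least the background's scaled by the glimpse SNR
(-4 dB by default, i.e. a talker bin may fall up to 4 dB below the
background and still count), and "masked" otherwise.  For each peakRate
event the glimpse ratio is the fraction of glimpsed bins in the
[-200, +200] ms x all-frequency window around the event; the mask ratio is
its complement, so the two always sum to 1.  Events are then allocated to
the glimpsed class (glimpse ratio > 0.9), the masked class (mask ratio
> 0.8), or left unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .audio import PeakRateEvent, Spectrogram

__all__ = [
    "MaskingConfig",
    "compute_event_ratios",
    "allocate_events",
    "annotate_events",
]


@dataclass
class MaskingConfig:
    window_pre_s: float = 0.2
    window_post_s: float = 0.2
    glimpse_snr_db: float = -4.0
    glimpse_ratio_threshold: float = 0.9
    mask_ratio_threshold: float = 0.8
    #: how spectrogram bins are read when converting the dB criterion to a
    #: linear factor: "amplitude" -> 10^(dB/20), "power" -> 10^(dB/10)
    magnitude_convention: str = "amplitude"

    def __post_init__(self) -> None:
        if self.window_pre_s < 0 or self.window_post_s < 0:
            raise ValueError("window extents must be >= 0")
        for th in (self.glimpse_ratio_threshold, self.mask_ratio_threshold):
            if not 0.0 <= th <= 1.0:
                raise ValueError("ratio thresholds must lie in [0, 1]")
        if self.magnitude_convention not in ("amplitude", "power"):
            raise ValueError("magnitude_convention must be 'amplitude' or 'power'")

    @property
    def snr_factor(self) -> float:
        div = 20.0 if self.magnitude_convention == "amplitude" else 10.0
        return 10.0 ** (self.glimpse_snr_db / div)


def _check_grids(a: Spectrogram, b: Spectrogram) -> None:
    if a.values.shape != b.values.shape:
        raise ValueError("talker and background spectrograms have different shapes")
    if a.frame_rate != b.frame_rate:
        raise ValueError("talker and background spectrograms have different frame rates")
    if not np.allclose(a.freq_centers, b.freq_centers):
        raise ValueError("talker and background spectrograms have different frequency axes")


def compute_event_ratios(
    event: PeakRateEvent,
    talker_spec: Spectrogram,
    background_spec: Spectrogram,
    cfg: MaskingConfig | None = None,
) -> tuple[float | None, float | None]:
    """Glimpse and mask ratios for one event; (None, None) without context.

    Over the inclusive frame window [t - 200 ms, t + 200 ms] and all
    frequency bins, the glimpse ratio is the fraction of bins where
    ``talker >= background * 10^(snr_db/20)`` (ties glimpsed); the mask
    ratio is ``1 - glimpse_ratio``.  Events without a full window of
    context are left ratio-unset rather than raising.
    """
    cfg = cfg or MaskingConfig()
    _check_grids(talker_spec, background_spec)
    fr = talker_spec.frame_rate
    t = int(round(event.time_s * fr))
    lo = t - int(round(cfg.window_pre_s * fr))
    hi = t + int(round(cfg.window_post_s * fr))
    if lo < 0 or hi >= talker_spec.n_frames:
        return None, None
    s_t = talker_spec.values[lo : hi + 1]
    s_b = background_spec.values[lo : hi + 1]
    g = float(np.mean(s_t >= s_b * cfg.snr_factor))
    return g, 1.0 - g


def allocate_events(
    events: Sequence[PeakRateEvent], cfg: MaskingConfig | None = None
) -> list[PeakRateEvent]:
    """Label ratio-set events as glimpsed / masked / unlabeled by threshold."""
    cfg = cfg or MaskingConfig()
    out: list[PeakRateEvent] = []
    for ev in events:
        if ev.glimpse_ratio is None:
            out.append(ev.with_ratios(None))
            continue
        if ev.glimpse_ratio > cfg.glimpse_ratio_threshold:
            label = "glimpsed"
        elif (1.0 - ev.glimpse_ratio) > cfg.mask_ratio_threshold:
            label = "masked"
        else:
            label = "unlabeled"
        out.append(ev.with_ratios(ev.glimpse_ratio, label))
    return out


def annotate_events(
    events: Sequence[PeakRateEvent],
    spectrograms: dict[str, Spectrogram],
    cfg: MaskingConfig | None = None,
) -> list[PeakRateEvent]:
    """Fill ratios and labels for events from a set of talker spectrograms.

    For each event the background is the element-wise sum of all
    spectrograms other than the event's own talker.
    """
    cfg = cfg or MaskingConfig()
    backgrounds: dict[str, Spectrogram] = {}
    for tid, spec in spectrograms.items():
        others = [s.values for k, s in spectrograms.items() if k != tid]
        if not others:
            raise ValueError("need at least two talkers to compute masking")
        bg = others[0] if len(others) == 1 else np.sum(others, axis=0)
        backgrounds[tid] = Spectrogram(
            bg, frame_rate=spec.frame_rate, freq_centers=spec.freq_centers, talker_id="background"
        )
    out = []
    for ev in events:
        if ev.talker_id not in spectrograms:
            raise KeyError(f"no spectrogram for talker {ev.talker_id!r}")
        g, _ = compute_event_ratios(ev, spectrograms[ev.talker_id], backgrounds[ev.talker_id], cfg)
        out.append(ev.with_ratios(g))
    return allocate_events(out, cfg)
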