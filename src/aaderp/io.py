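"""File interfaces: WAV stimuli, HDF5 features/sessions, CSV events/traces."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audio import Envelope, PeakRateEvent, Spectrogram
from .neural import NeuralEnvelope
from .synth import GroundTruth, Session, SessionSpec

__all__ = [
    "read_wav",
    "events_to_frame",
    "events_from_frame",
    "write_events_csv",
    "read_events_csv",
    "save_features",
    "load_features",
    "save_session",
    "load_session",
    "write_trace_csv",
]

EVENT_COLUMNS = ["talker_id", "time_s", "magnitude", "glimpse_ratio", "mask_ratio", "label"]


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Mono float waveform in [-1, 1] and its sample rate."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def events_to_frame(events: list[PeakRateEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "talker_id": ev.talker_id,
                "time_s": ev.time_s,
                "magnitude": ev.magnitude,
                "glimpse_ratio": np.nan if ev.glimpse_ratio is None else ev.glimpse_ratio,
                "mask_ratio": np.nan if ev.mask_ratio is None else ev.mask_ratio,
                "label": ev.label,
            }
            for ev in events
        ],
        columns=EVENT_COLUMNS,
    )


def events_from_frame(df: pd.DataFrame) -> list[PeakRateEvent]:
    out = []
    for row in df.itertuples():
        g = None if pd.isna(row.glimpse_ratio) else float(row.glimpse_ratio)
        out.append(
            PeakRateEvent(
                time_s=float(row.time_s),
                magnitude=float(row.magnitude),
                talker_id=str(row.talker_id),
                glimpse_ratio=g,
                mask_ratio=None if g is None else 1.0 - g,
                label=str(row.label),
            )
        )
    return out


def write_events_csv(events: list[PeakRateEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[PeakRateEvent]:
    return events_from_frame(pd.read_csv(path))


def save_features(
    path: str | Path,
    spectrograms: dict[str, Spectrogram],
    envelopes: dict[str, Envelope] | None = None,
) -> None:
    """Spectrograms (+ envelopes) to HDF5 with rate / frequency metadata."""
    with h5py.File(path, "w") as f:
        for tid, spec in spectrograms.items():
            g = f.create_group(f"spectrograms/{tid}")
            g.create_dataset("values", data=spec.values)
            g.attrs["rate"] = spec.frame_rate
            g.create_dataset("freq_edges", data=spec.freq_centers)
        for tid, env in (envelopes or {}).items():
            g = f.create_group(f"envelopes/{tid}")
            g.create_dataset("values", data=env.values)
            g.attrs["rate"] = env.rate


def load_features(path: str | Path) -> tuple[dict[str, Spectrogram], dict[str, Envelope]]:
    specs: dict[str, Spectrogram] = {}
    envs: dict[str, Envelope] = {}
    with h5py.File(path, "r") as f:
        for tid, g in f.get("spectrograms", {}).items():
            specs[tid] = Spectrogram(
                g["values"][...],
                frame_rate=float(g.attrs["rate"]),
                freq_centers=g["freq_edges"][...],
                talker_id=tid,
            )
        for tid, g in f.get("envelopes", {}).items():
            envs[tid] = Envelope(g["values"][...], rate=float(g.attrs["rate"]), talker_id=tid)
    return specs, envs


def save_session(session: Session, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps(session.spec.__dict__)
        f.attrs["rate"] = session.rate
        g = f.create_group("neural")
        g.create_dataset("values", data=session.neural.values)
        g.attrs["rate"] = session.neural.rate
        for i, env in enumerate(session.envelopes):
            f.create_dataset(f"envelopes/{i}", data=env.values)
        tr = f.create_group("trials")
        tr.create_dataset("start_s", data=session.trial_starts_s)
        tr.create_dataset("duration_s", data=session.trial_durations_s)
        tr.create_dataset("target", data=session.trial_targets)
        ev = f.create_group("events")
        df = session.truth.events
        for col in ("talker", "frame", "trial"):
            ev.create_dataset(col, data=df[col].to_numpy(int))
        for col in ("time_s", "magnitude", "glimpse_ratio"):
            ev.create_dataset(col, data=df[col].to_numpy(float))
        ev.create_dataset("attended", data=df["attended"].to_numpy(bool))
        ev.create_dataset("label", data=df["label"].astype("S"))
        gt = f.create_group("truth")
        for (att, typ), k in session.truth.kernels.items():
            gt.create_dataset(f"kernel_{int(att)}_{typ}", data=k)
        gt.create_dataset("channel_gains", data=session.truth.channel_gains)
        gt.attrs["noise_seed"] = session.truth.noise_seed


def load_session(path: str | Path) -> Session:
    with h5py.File(path, "r") as f:
        spec_dict = json.loads(f.attrs["spec"])
        spec_dict["trial_beta"] = tuple(spec_dict["trial_beta"])
        spec = SessionSpec(**spec_dict)
        neural = NeuralEnvelope(f["neural/values"][...], rate=float(f["neural"].attrs["rate"]))
        envelopes = [
            Envelope(f[f"envelopes/{i}"][...], rate=float(f.attrs["rate"]), talker_id=str(i))
            for i in range(len(f["envelopes"]))
        ]
        ev = f["events"]
        events = pd.DataFrame(
            {
                "talker": ev["talker"][...],
                "time_s": ev["time_s"][...],
                "frame": ev["frame"][...],
                "magnitude": ev["magnitude"][...],
                "glimpse_ratio": ev["glimpse_ratio"][...],
                "trial": ev["trial"][...],
                "attended": ev["attended"][...],
                "label": [s.decode() for s in ev["label"][...]],
            }
        )
        gt = f["truth"]
        kernels = {}
        for name, ds in gt.items():
            if name.startswith("kernel_"):
                _, att, typ = name.split("_", 2)
                kernels[(bool(int(att)), typ)] = ds[...]
        truth = GroundTruth(
            events=events,
            kernels=kernels,
            channel_gains=gt["channel_gains"][...],
            trial_targets=f["trials/target"][...],
            noise_seed=int(gt.attrs["noise_seed"]),
        )
        return Session(
            spec=spec,
            rate=float(f.attrs["rate"]),
            trial_starts_s=f["trials/start_s"][...],
            trial_durations_s=f["trials/duration_s"][...],
            trial_targets=f["trials/target"][...],
            envelopes=envelopes,
            neural=neural,
            truth=truth,
        )


def write_trace_csv(trace, path: str | Path) -> None:
    """Decoding trace as CSV: time, evidence, decision, event counts."""
    df = pd.DataFrame(
        {
            "time_s": trace.times_s,
            "pT": trace.p[0],
            "pNT": trace.p[1],
            "rT": trace.r[0],
            "rNT": trace.r[1],
            "decision": trace.decision,
        }
    )
    for (talker, typ), cnt in trace.n_events.items():
        name = f"n_{typ}_{'T' if talker == 0 else 'NT'}"
        df[name] = cnt
    df.to_csv(path, index=False)
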