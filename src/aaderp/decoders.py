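"""Attention decoders: glimpsed/masked ERP classification and the CCA baseline.

Two families of decoder are implemented.

* ERPC (event-related potential classification): for each talker and
  decoding window, the [0, 500] ms high-gamma responses to that talker's
  peakRate events are averaged per channel, flattened to an
  ``n_channels x 51`` feature vector, and classified by an RBF-kernel SVM
  (C = 10) whose decision values are mapped to probabilities by Platt
  scaling.  Separate models are trained per window duration and per event
  type (all / glimpsed / masked); the glimpsed and masked probabilities
  are averaged into a joint per-talker probability.  Windows without
  sufficiently glimpsed/masked events either hold the previous decision
  or fall back to CCA.

* CCA: a spatial filter on the neural channels and a temporal filter on
  [-500, 0] ms lags of the speech envelope are learned jointly to
  maximize the correlation of the two projections (top canonical
  component); at test time the talker whose projected envelope correlates
  best with the projected neural data over the window is decoded as the
  target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .neural import NeuralEnvelope, erp_matrix, n_lags

__all__ = [
    "ClassifierConfig",
    "LagConfig",
    "ErpcModel",
    "CcaModel",
    "DecodingTrace",
    "tile_windows",
    "train_erpc",
    "combine_type_probs",
    "erpc_decode_window",
    "erpc_decide",
    "fit_cca",
    "decode_cca_window",
    "decode_trace",
]

EVENT_TYPES = ("all", "glimpsed", "masked")


@dataclass
class ClassifierConfig:
    kernel: str = "rbf"
    regularization_C: float = 10.0
    calibration: str = "platt"
    calibration_folds: int = 3
    erp_window_s: tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        if self.regularization_C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class LagConfig:
    """Envelope lag span for CCA: [-500, 0] ms at 100 Hz -> 51 lags."""

    t_min_s: float = -0.5
    t_max_s: float = 0.0
    rate: float = 100.0

    def __post_init__(self) -> None:
        if self.t_min_s >= self.t_max_s:
            raise ValueError("t_min_s must be < t_max_s")

    @property
    def n_lags(self) -> int:
        return int(round((self.t_max_s - self.t_min_s) * self.rate)) + 1


@dataclass
class ErpcModel:
    """One trained ERP classifier for a (window duration, event type) pair."""

    pipeline: Pipeline
    duration_s: float
    event_type: str
    n_channels: int
    n_lags: int
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def predict_target_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated P(evoked by the attended talker) for flattened ERPs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_channels * self.n_lags:
            raise ValueError(
                f"expected {self.n_channels * self.n_lags} features, got {X.shape[1]}"
            )
        cls = list(self.pipeline.classes_)
        return self.pipeline.predict_proba(X)[:, cls.index(1)]


@dataclass
class CcaModel:
    """Top canonical component: neural spatial + envelope temporal weights."""

    neural_weights: np.ndarray  # (n_channels,)
    envelope_weights: np.ndarray  # (n_lags,) ordered oldest lag first
    canonical_correlation: float
    lags: LagConfig = field(default_factory=LagConfig)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.neural_weights)) and np.all(np.isfinite(self.envelope_weights))):
            raise ValueError("CCA weights must be finite")

    def project_neural(self, env: NeuralEnvelope | np.ndarray) -> np.ndarray:
        vals = env.values if isinstance(env, NeuralEnvelope) else np.atleast_2d(env)
        return self.neural_weights @ vals

    def project_envelope(self, envelope: np.ndarray) -> np.ndarray:
        """Temporal projection v[t] = sum_j w[j] * env[t - (L-1) + j]."""
        from scipy.signal import lfilter

        return lfilter(self.envelope_weights[::-1], [1.0], np.asarray(envelope, dtype=float))


@dataclass
class DecodingTrace:
    """Per-talker decoder evidence and decisions on a uniform step grid."""

    times_s: np.ndarray
    p: np.ndarray  # (2, n_steps) held ERPC probabilities, NaN before evidence
    r: np.ndarray  # (2, n_steps) CCA window correlations, NaN if unused
    decision: np.ndarray  # (n_steps,) talker index, -1 while undefined
    evidence_updated: np.ndarray  # (n_steps,) bool: new evidence at this step
    n_events: dict = field(default_factory=dict)  # (talker, type) -> counts
    mode: str = "erpc-hold"
    duration_s: float = 0.0
    step_s: float = 0.1


# ---------------------------------------------------------------------------
# window tiling and ERP gathering


def tile_windows(
    trials: Sequence[tuple[float, float, int]], duration_s: float, rate: float = 100.0
) -> list[tuple[int, int, int]]:
    """Non-overlapping left-aligned windows per trial: (start_f, end_f, target).

    Trailing remainders shorter than ``duration_s`` are dropped so a given
    set of ERPs enters the train/test material exactly once.
    """
    out = []
    dur_f = int(round(duration_s * rate))
    for t0, dur, target in trials:
        n = int(dur // duration_s)
        s0 = int(round(t0 * rate))
        for k in range(n):
            out.append((s0 + k * dur_f, s0 + (k + 1) * dur_f, int(target)))
    return out


def _frames_in_window(frames: np.ndarray, start_f: int, end_f: int) -> np.ndarray:
    """Event onsets in the half-open window (start_f, end_f]."""
    i = np.searchsorted(frames, start_f, side="right")
    j = np.searchsorted(frames, end_f, side="right")
    return frames[i:j]


def _usable(frames: np.ndarray, env: NeuralEnvelope, nl: int, off: int) -> np.ndarray:
    frames = np.asarray(frames, dtype=int)
    keep = (frames + off >= 0) & (frames + off + nl <= env.n_frames)
    return np.sort(frames[keep])


# ---------------------------------------------------------------------------
# ERPC training


def train_erpc(
    env: NeuralEnvelope,
    events_by_talker: Mapping[int, Mapping[str, np.ndarray]],
    trials: Sequence[tuple[float, float, int]],
    duration_s: float,
    event_type: str = "all",
    cfg: ClassifierConfig | None = None,
    random_state: int = 0,
) -> ErpcModel:
    """Train one ERP classifier for a window duration and event type.

    Training windows tile each trial without reuse.  Each window
    contributes up to two samples: the average ERP to the attended
    talker's events (class 1) and to the unattended talker's events
    (class 0); windows lacking events of ``event_type`` for a talker
    contribute no sample for that talker.
    """
    cfg = cfg or ClassifierConfig()
    if event_type not in EVENT_TYPES:
        raise ValueError(f"event_type must be one of {EVENT_TYPES}")
    nl = n_lags(cfg.erp_window_s, env.rate)
    off = int(round(cfg.erp_window_s[0] * env.rate))
    windows = tile_windows(trials, duration_s, env.rate)

    X, y = [], []
    for start_f, end_f, target in windows:
        for talker, typed in events_by_talker.items():
            frames = _usable(np.asarray(typed[event_type]), env, nl, off)
            inwin = _frames_in_window(frames, start_f, end_f)
            if inwin.size == 0:
                continue
            X.append(erp_matrix(env, inwin, cfg.erp_window_s).mean(axis=0).ravel())
            y.append(1 if talker == target else 0)
    X = np.asarray(X)
    y = np.asarray(y)
    if X.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("training data must contain both target and non-target ERPs")
    if min(np.bincount(y)) < cfg.calibration_folds:
        raise ValueError("too few windows per class for calibrated training")

    svc = SVC(kernel=cfg.kernel, C=cfg.regularization_C, random_state=random_state)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", CalibratedClassifierCV(svc, method="sigmoid", cv=cfg.calibration_folds)),
        ]
    )
    pipe.fit(X, y)
    return ErpcModel(
        pipeline=pipe,
        duration_s=duration_s,
        event_type=event_type,
        n_channels=env.n_channels,
        n_lags=nl,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# ERPC window-level decoding rules


def combine_type_probs(p_glimpsed: float | None, p_masked: float | None) -> float | None:
    """Joint probability: mean of both type classifiers; one if only one
    type of event is present; None (no-decision) if neither."""
    if p_glimpsed is None and p_masked is None:
        return None
    if p_glimpsed is None:
        return float(p_masked)
    if p_masked is None:
        return float(p_glimpsed)
    return 0.5 * (float(p_glimpsed) + float(p_masked))


def erpc_decode_window(
    model_g: ErpcModel,
    model_m: ErpcModel,
    env: NeuralEnvelope,
    glimpsed_frames: np.ndarray,
    masked_frames: np.ndarray,
    erp_window: tuple[float, float] = (0.0, 0.5),
) -> float | None:
    """Joint talker probability for one window, or None without events."""
    p_g = p_m = None
    if np.asarray(glimpsed_frames).size:
        x = erp_matrix(env, np.asarray(glimpsed_frames, int), erp_window).mean(axis=0).ravel()
        p_g = float(model_g.predict_target_proba(x[None, :])[0])
    if np.asarray(masked_frames).size:
        x = erp_matrix(env, np.asarray(masked_frames, int), erp_window).mean(axis=0).ravel()
        p_m = float(model_m.predict_target_proba(x[None, :])[0])
    return combine_type_probs(p_g, p_m)


def erpc_decide(
    p_target: float | None,
    p_nontarget: float | None,
    previous_decision: int = -1,
    talkers: tuple[int, int] = (0, 1),
) -> int:
    """Window decision between two talkers given their joint probabilities.

    Both present: higher probability wins (ties -> lower talker index).
    One present: that talker iff p > 0.5, the other iff p < 0.5, held at
    exactly 0.5.  Neither: the previous decision is held (-1 if none yet).
    """
    a, b = talkers
    if p_target is not None and p_nontarget is not None:
        if p_target == p_nontarget:
            return min(a, b)
        return a if p_target > p_nontarget else b
    if p_target is not None:
        if p_target > 0.5:
            return a
        if p_target < 0.5:
            return b
        return previous_decision
    if p_nontarget is not None:
        if p_nontarget > 0.5:
            return b
        if p_nontarget < 0.5:
            return a
        return previous_decision
    return previous_decision


# ---------------------------------------------------------------------------
# CCA


def _lag_matrix(envelope: np.ndarray, nl: int) -> np.ndarray:
    """Row t holds envelope[t-nl+1 .. t] (zero-padded before the start)."""
    env = np.asarray(envelope, dtype=float)
    padded = np.concatenate([np.zeros(nl - 1), env])
    return np.lib.stride_tricks.sliding_window_view(padded, nl)


def _inv_sqrt(S: np.ndarray, ridge: float) -> np.ndarray:
    w, V = np.linalg.eigh(S + ridge * np.eye(S.shape[0]))
    w = np.clip(w, ridge, None)
    return (V / np.sqrt(w)) @ V.T


def fit_cca(
    env: NeuralEnvelope,
    target_envelope: np.ndarray,
    lags: LagConfig | None = None,
    sample_mask: np.ndarray | None = None,
    ridge: float = 1e-6,
    train_on: str = "attended",
    other_envelope: np.ndarray | None = None,
) -> CcaModel:
    """Two-view CCA via whitened cross-covariance SVD (top component).

    ``target_envelope`` is the attended talker's envelope on the neural
    frame grid.  ``sample_mask`` restricts the fit to training frames.
    With ``train_on="both"`` the unattended envelope (``other_envelope``)
    is stacked in as additional stimulus-response pairs.  A small ridge
    stabilizes near-rank-deficient covariances; genuinely deficient
    covariances are solved in regularized form with a warning.
    """
    lags = lags or LagConfig(rate=env.rate)
    X = env.values.T  # T x ch
    Y = _lag_matrix(target_envelope, lags.n_lags)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("neural data and envelope have different lengths")
    valid = np.zeros(X.shape[0], dtype=bool)
    valid[lags.n_lags - 1 :] = True
    if sample_mask is not None:
        valid &= np.asarray(sample_mask, dtype=bool)
    Xc = X[valid]
    Yc = Y[valid]
    if train_on == "both":
        if other_envelope is None:
            raise ValueError('train_on="both" requires other_envelope')
        Xc = np.vstack([Xc, Xc])
        Yc = np.vstack([Yc, _lag_matrix(other_envelope, lags.n_lags)[valid]])
    elif train_on != "attended":
        raise ValueError('train_on must be "attended" or "both"')
    n = Xc.shape[0]
    if n < 10 * (X.shape[1] + lags.n_lags):
        warnings.warn("few samples relative to CCA dimensionality; fit may be unstable")
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n
    if min(np.linalg.eigvalsh(Sxx).min(), np.linalg.eigvalsh(Syy).min()) <= 0:
        warnings.warn("rank-deficient covariance; using regularized solve")
    Wx = _inv_sqrt(Sxx, ridge)
    Wy = _inv_sqrt(Syy, ridge)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    wx = Wx @ U[:, 0]
    wy = Wy @ Vt[0]
    return CcaModel(
        neural_weights=wx,
        envelope_weights=wy,
        canonical_correlation=float(s[0]),
        lags=lags,
    )


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0:
        return 0.0
    return float((u @ v) / denom)


def decode_cca_window(
    model: CcaModel,
    env: NeuralEnvelope,
    talker_envelopes: Sequence[np.ndarray],
    window_f: tuple[int, int],
) -> tuple[int, tuple[float, ...]]:
    """Decision and per-talker correlations for one window (frames (s, e]).

    Zero-variance windows yield r = 0; ties break to the lower talker
    index (flagged by equal correlations in the returned tuple).
    """
    s, e = window_f
    if e - s < 3:
        raise ValueError("window too short to compute a correlation")
    u = model.project_neural(env)[s + 1 : e + 1]
    rs = []
    for envelope in talker_envelopes:
        v = model.project_envelope(envelope)[s + 1 : e + 1]
        rs.append(_pearson(u, v))
    return int(np.argmax(rs)), tuple(rs)


def _rolling_corr(u: np.ndarray, v: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    """Pearson r of u, v over the windows (end - length, end] for each end."""

    def cs(x):
        return np.concatenate([[0.0], np.cumsum(x)])

    su, sv = cs(u), cs(v)
    suu, svv, suv = cs(u * u), cs(v * v), cs(u * v)
    hi = ends + 1
    lo = ends + 1 - length
    n = float(length)
    s1 = su[hi] - su[lo]
    s2 = sv[hi] - sv[lo]
    s11 = suu[hi] - suu[lo]
    s22 = svv[hi] - svv[lo]
    s12 = suv[hi] - suv[lo]
    num = n * s12 - s1 * s2
    den = np.sqrt(np.clip(n * s11 - s1 * s1, 0, None) * np.clip(n * s22 - s2 * s2, 0, None))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


# ---------------------------------------------------------------------------
# continuous trace decoding


def decode_trace(
    env: NeuralEnvelope,
    span_f: tuple[int, int],
    duration_s: float,
    step_s: float = 0.1,
    mode: str = "erpc-hold",
    model_g: ErpcModel | None = None,
    model_m: ErpcModel | None = None,
    cca_model: CcaModel | None = None,
    events_by_talker: Mapping[int, Mapping[str, np.ndarray]] | None = None,
    talker_envelopes: Sequence[np.ndarray] | None = None,
    erp_window: tuple[float, float] = (0.0, 0.5),
) -> DecodingTrace:
    """Sliding-window decoding over one contiguous span of the session.

    Windows of ``duration_s`` end at each grid step (step ``step_s``)
    starting one full window after ``span_f[0]``.  ``mode`` selects the
    decision rule: ``erpc-hold`` (hold the previous decision on windows
    without labeled events), ``erpc-fallback`` (decide such windows by
    CCA), or ``cca``.
    """
    rate = env.rate
    f0, f1 = span_f
    dur_f = int(round(duration_s * rate))
    step_f = max(1, int(round(step_s * rate)))
    ends = np.arange(f0 + dur_f, f1 + 1, step_f)
    K = ends.size
    times = ends / rate
    p = np.full((2, K), np.nan)
    r = np.full((2, K), np.nan)
    decision = np.full(K, -1, dtype=int)
    updated = np.zeros(K, dtype=bool)
    counts: dict = {}

    need_cca = mode == "cca" or mode == "erpc-fallback"
    if need_cca:
        if cca_model is None or talker_envelopes is None:
            raise ValueError(f"mode {mode!r} requires a CCA model and talker envelopes")
        u = cca_model.project_neural(env)
        for talker in (0, 1):
            v = cca_model.project_envelope(talker_envelopes[talker])
            r[talker] = _rolling_corr(u, v, ends, dur_f)

    if mode == "cca":
        decision = np.where(r[0] >= r[1], 0, 1)
        updated[:] = True
        return DecodingTrace(times, p, r, decision, updated, counts, mode, duration_s, step_s)

    if mode not in ("erpc-hold", "erpc-fallback"):
        raise ValueError(f"unknown mode {mode!r}")
    if model_g is None or model_m is None or events_by_talker is None:
        raise ValueError("ERPC modes require glimpsed and masked models and event streams")

    nl = n_lags(erp_window, rate)
    off = int(round(erp_window[0] * rate))
    # per (talker, type): probabilities for every step, NaN where no events
    probs = {}
    for talker in (0, 1):
        for typ, model in (("glimpsed", model_g), ("masked", model_m)):
            frames = _usable(np.asarray(events_by_talker[talker][typ]), env, nl, off)
            i = np.searchsorted(frames, ends - dur_f, side="right")
            j = np.searchsorted(frames, ends, side="right")
            cnt = j - i
            counts[(talker, typ)] = cnt
            pr = np.full(K, np.nan)
            if frames.size:
                stack = erp_matrix(env, frames, erp_window).reshape(frames.size, -1)
                csum = np.vstack([np.zeros(stack.shape[1]), np.cumsum(stack, axis=0)])
                sel = cnt > 0
                if np.any(sel):
                    X = (csum[j[sel]] - csum[i[sel]]) / cnt[sel, None]
                    pr[sel] = model.predict_target_proba(X)
            probs[(talker, typ)] = pr

    prev_dec = -1
    held = [np.nan, np.nan]
    for k in range(K):
        pk = [
            combine_type_probs(
                None if np.isnan(probs[(t, "glimpsed")][k]) else probs[(t, "glimpsed")][k],
                None if np.isnan(probs[(t, "masked")][k]) else probs[(t, "masked")][k],
            )
            for t in (0, 1)
        ]
        if pk[0] is None and pk[1] is None:
            if mode == "erpc-fallback":
                decision[k] = 0 if r[0, k] >= r[1, k] else 1
                updated[k] = True
            else:
                decision[k] = prev_dec
        else:
            decision[k] = erpc_decide(pk[0], pk[1], prev_dec)
            updated[k] = True
        for t in (0, 1):
            if pk[t] is not None:
                held[t] = pk[t]
            p[t, k] = held[t]
        prev_dec = decision[k]
    return DecodingTrace(times, p, r, decision, updated, counts, mode, duration_s, step_s)
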