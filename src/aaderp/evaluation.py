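"""Evaluation: performance curves, simulated attention switching, stability.

Decoding is evaluated with 5-fold cross-validation over whole trials
(contiguous blocks, 7 trials per fold for a 35-trial session).  Two
accuracy notions are used, matching how each decoder would run:

* trace accuracy ("cca", "erpc-hold", "erpc-fallback"): the continuous
  sliding-window decision stream is compared to the true target at every
  time step, so accuracy is the percentage of time steps decoded
  correctly in a continuously operating system;
* window accuracy ("window-all", "window-glimpsed", "window-masked"):
  non-overlapping test windows are classified per talker and accuracy is
  the fraction of (window, talker) samples classified correctly.

Attention switching is simulated by relabeling the trials of each test
fold so the target alternates trial by trial (swapping the two talkers'
streams on relabeled trials); switch points are the trial boundaries, so
a fold of 7 trials contains 6 switches and a 5-fold session 30.  Switch
latency is read off the switch-locked average evidence time course, and
decoding stability is the distribution of intervals between consecutive
decision changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decoders import (
    ClassifierConfig,
    CcaModel,
    DecodingTrace,
    ErpcModel,
    LagConfig,
    decode_trace,
    fit_cca,
    tile_windows,
    train_erpc,
)
from .neural import erp_matrix, n_lags
from .synth import Session

__all__ = [
    "PerformanceCurve",
    "SwitchReport",
    "make_folds",
    "simulate_switching",
    "SwitchFold",
    "performance_curve",
    "decode_fold",
    "trace_accuracy",
    "average_switch_course",
    "switch_latency",
    "stability_intervals",
    "compare_methods",
]

TRACE_METHODS = ("cca", "erpc-hold", "erpc-fallback")
WINDOW_METHODS = ("window-all", "window-glimpsed", "window-masked")


@dataclass
class PerformanceCurve:
    """Accuracy as a function of decoding-window duration."""

    table: pd.DataFrame  # duration_s, method, fold, accuracy, n

    def mean(self) -> pd.DataFrame:
        return self.table.groupby(["method", "duration_s"], as_index=False).accuracy.mean()

    def accuracy(self, method: str, duration_s: float) -> float:
        sel = self.table[
            (self.table.method == method) & (self.table.duration_s == duration_s)
        ]
        return float(np.average(sel.accuracy, weights=sel.n))


@dataclass
class SwitchReport:
    """Switch-locked dynamics for one method and window duration."""

    rel_times_s: np.ndarray
    avg_new: np.ndarray  # mean evidence for the post-switch target
    avg_old: np.ndarray
    latency_s: float  # +inf if evidence never crosses
    intervals_s: np.ndarray  # time between decoded switches
    ideal_latency_s: float
    ideal_intervals_s: np.ndarray  # simulated switch (trial) durations
    n_switches: int


# ---------------------------------------------------------------------------
# folds and fold views


def make_folds(n_trials: int, n_folds: int = 5) -> list[np.ndarray]:
    """Contiguous trial blocks (7 per fold for 35 trials / 5 folds)."""
    if n_trials < n_folds:
        raise ValueError("need at least one trial per fold")
    edges = np.linspace(0, n_trials, n_folds + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class SwitchFold:
    """A test fold relabeled so the target alternates across trials."""

    trial_idx: np.ndarray
    swap: np.ndarray  # per trial: talker streams exchanged?
    truth: np.ndarray  # per trial target in the presented coordinates
    switch_times_s: np.ndarray  # interior trial boundaries
    span_f: tuple[int, int]


def _fold_span(session: Session, trial_idx: np.ndarray) -> tuple[int, int]:
    spans = session.trial_spans_f()
    return int(spans[trial_idx[0], 0]), int(spans[trial_idx[-1], 1])


def simulate_switching(session: Session, trial_idx: np.ndarray) -> SwitchFold:
    """Alternate the target across a fold's trials (switches at boundaries).

    The first trial keeps its original target; every subsequent trial's
    target alternates, and trials whose alternated target differs from
    their original one have their talker streams swapped.  A fold of n
    trials therefore contains n - 1 switches.
    """
    trial_idx = np.asarray(trial_idx)
    orig = session.trial_targets[trial_idx]
    truth = (orig[0] + np.arange(trial_idx.size)) % 2
    swap = truth != orig
    boundaries = session.trial_starts_s[trial_idx[1:]]
    return SwitchFold(
        trial_idx=trial_idx,
        swap=swap,
        truth=truth,
        switch_times_s=np.asarray(boundaries, dtype=float),
        span_f=_fold_span(session, trial_idx),
    )


def _fold_view(session: Session, fold: SwitchFold | None):
    """(events_by_talker, talker_envelopes) with per-trial swaps applied."""
    frames_by = session.event_frames()
    env_arrays = [e.values.copy() for e in session.envelopes]
    if fold is None or not np.any(fold.swap):
        return frames_by, env_arrays
    spans = session.trial_spans_f()
    df = session.truth.events
    out = {0: {}, 1: {}}
    for typ in ("all", "glimpsed", "masked"):
        per_talker = {0: [], 1: []}
        for k, tr in enumerate(fold.trial_idx):
            for talker in (0, 1):
                src = 1 - talker if fold.swap[k] else talker
                sub = df[(df.talker == src) & (df.trial == tr)]
                if typ != "all":
                    sub = sub[sub.label == typ]
                per_talker[talker].append(sub.frame.to_numpy())
        for talker in (0, 1):
            # events outside this fold stay with their own talker
            inside = np.concatenate(per_talker[talker]) if per_talker[talker] else np.array([], int)
            lo, hi = fold.span_f
            own = frames_by[talker][typ]
            outside = own[(own < lo) | (own >= hi)]
            out[talker][typ] = np.sort(np.concatenate([outside, inside])).astype(int)
    for k, tr in enumerate(fold.trial_idx):
        if fold.swap[k]:
            s, e = spans[tr]
            env_arrays[0][s:e], env_arrays[1][s:e] = (
                session.envelopes[1].values[s:e].copy(),
                session.envelopes[0].values[s:e].copy(),
            )
    return out, env_arrays


# ---------------------------------------------------------------------------
# fold training / decoding


def _train_fold(
    session: Session,
    train_trials: list[tuple[float, float, int]],
    duration_s: float,
    methods: tuple[str, ...],
    cfg: ClassifierConfig,
    lag_cfg: LagConfig | None = None,
):
    """Train whatever the requested methods need for one fold."""
    frames_by = session.event_frames()
    models: dict = {}
    need_erpc = any(m.startswith("erpc") or m.startswith("window") for m in methods)
    if need_erpc:
        for typ in ("glimpsed", "masked", "all"):
            if typ == "all" and "window-all" not in methods:
                continue
            models[typ] = train_erpc(
                session.neural, frames_by, train_trials, duration_s, typ, cfg
            )
    if any(m in ("cca", "erpc-fallback") for m in methods):
        mask = np.zeros(session.n_frames, dtype=bool)
        attended = np.zeros(session.n_frames)
        for t0, dur, target in train_trials:
            s, e = int(round(t0 * session.rate)), int(round((t0 + dur) * session.rate))
            mask[s:e] = True
            attended[s:e] = session.envelopes[target].values[s:e]
        models["cca"] = fit_cca(
            session.neural, attended, lag_cfg or LagConfig(rate=session.rate), sample_mask=mask
        )
    return models


def decode_fold(
    session: Session,
    models: dict,
    span_f: tuple[int, int],
    duration_s: float,
    method: str,
    step_s: float = 0.1,
    fold_view=None,
) -> DecodingTrace:
    events_by, envelopes = fold_view if fold_view is not None else _fold_view(session, None)
    return decode_trace(
        session.neural,
        span_f,
        duration_s,
        step_s=step_s,
        mode=method,
        model_g=models.get("glimpsed"),
        model_m=models.get("masked"),
        cca_model=models.get("cca"),
        events_by_talker=events_by,
        talker_envelopes=envelopes,
    )


def _truth_per_step(
    times_s: np.ndarray, trial_starts: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    idx = np.searchsorted(trial_starts, times_s - 1e-9, side="right") - 1
    idx = np.clip(idx, 0, targets.size - 1)
    return targets[idx]


def trace_accuracy(trace: DecodingTrace, truth: np.ndarray) -> tuple[float, int]:
    """Fraction of defined-decision steps that match the true target.

    Steps before the first evidence update (decision -1) are excluded from
    the denominator; their count is returned alongside.
    """
    defined = trace.decision >= 0
    n_excluded = int(np.sum(~defined))
    if not np.any(defined):
        return np.nan, n_excluded
    return float(np.mean(trace.decision[defined] == truth[defined])), n_excluded


def _window_accuracy(
    session: Session,
    models: dict,
    test_trials: list[tuple[float, float, int]],
    duration_s: float,
    event_type: str,
    erp_window=(0.0, 0.5),
) -> tuple[float, int]:
    """Standalone classifier accuracy over non-overlapping test windows."""
    model: ErpcModel = models[event_type]
    frames_by = session.event_frames()
    nl = n_lags(erp_window, session.rate)
    correct, total = 0, 0
    X, is_target = [], []
    for start_f, end_f, target in tile_windows(test_trials, duration_s, session.rate):
        for talker in (0, 1):
            frames = frames_by[talker][event_type]
            frames = frames[(frames > start_f) & (frames <= end_f)]
            frames = frames[frames + nl <= session.n_frames]
            if frames.size == 0:
                continue
            X.append(erp_matrix(session.neural, frames, erp_window).mean(axis=0).ravel())
            is_target.append(talker == target)
    if not X:
        return np.nan, 0
    p = model.predict_target_proba(np.asarray(X))
    is_target = np.asarray(is_target)
    correct = int(np.sum((p > 0.5) == is_target))
    total = len(is_target)
    return correct / total, total


def performance_curve(
    session: Session,
    methods: tuple[str, ...] = ("cca", "erpc-hold"),
    durations_s: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    n_folds: int = 5,
    step_s: float = 0.1,
    cfg: ClassifierConfig | None = None,
) -> PerformanceCurve:
    """Cross-validated accuracy-vs-duration curves, shared folds per method.

    Durations longer than the shortest trial are skipped with a warning
    (their training windows could not tile every trial).
    """
    cfg = cfg or ClassifierConfig()
    folds = make_folds(session.spec.n_trials, n_folds)
    trials = session.trials()
    rows = []
    min_trial = float(np.min(session.trial_durations_s))
    for duration_s in durations_s:
        if duration_s > min_trial:
            warnings.warn(f"duration {duration_s}s exceeds shortest trial; skipped")
            continue
        for fi, fold in enumerate(folds):
            train_trials = [trials[i] for i in range(len(trials)) if i not in set(fold)]
            test_trials = [trials[i] for i in fold]
            models = _train_fold(session, train_trials, duration_s, methods, cfg)
            span = _fold_span(session, fold)
            for method in methods:
                if method in TRACE_METHODS:
                    trace = decode_fold(session, models, span, duration_s, method, step_s)
                    truth = _truth_per_step(
                        trace.times_s, session.trial_starts_s, session.trial_targets
                    )
                    acc, _ = trace_accuracy(trace, truth)
                    n = int(np.sum(trace.decision >= 0))
                elif method in WINDOW_METHODS:
                    acc, n = _window_accuracy(
                        session, models, test_trials, duration_s, method.split("-")[1]
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append((duration_s, method, fi, acc, n))
    return PerformanceCurve(
        pd.DataFrame(rows, columns=["duration_s", "method", "fold", "accuracy", "n"])
    )


# ---------------------------------------------------------------------------
# switching dynamics


def average_switch_course(
    traces: list[DecodingTrace],
    folds: list[SwitchFold],
    evidence: str = "p",
    span_s: float = 8.0,
    step_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Switch-locked average evidence for the new and old targets.

    Evidence traces ("p" for ERPC probabilities, "r" for CCA correlations)
    are sampled on a relative grid around each simulated switch and
    averaged across switches (NaN-aware near span edges).
    """
    rel = np.arange(-span_s, span_s + step_s / 2, step_s)
    new_rows, old_rows = [], []
    for trace, fold in zip(traces, folds):
        ev = trace.p if evidence == "p" else trace.r
        for si, t_switch in enumerate(fold.switch_times_s):
            new_target = int(fold.truth[si + 1])
            idx = np.searchsorted(trace.times_s, t_switch + rel - 1e-9)
            valid = (idx >= 0) & (idx < trace.times_s.size)
            row_new = np.full(rel.size, np.nan)
            row_old = np.full(rel.size, np.nan)
            row_new[valid] = ev[new_target][idx[valid]]
            row_old[valid] = ev[1 - new_target][idx[valid]]
            new_rows.append(row_new)
            old_rows.append(row_old)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg_new = np.nanmean(np.asarray(new_rows), axis=0)
        avg_old = np.nanmean(np.asarray(old_rows), axis=0)
    return rel, avg_new, avg_old, len(new_rows)


def switch_latency(
    rel_times_s: np.ndarray, avg_new: np.ndarray, avg_old: np.ndarray
) -> float:
    """First post-switch time at which the new target's average evidence
    exceeds the old target's; +inf if it never crosses in the span.

    An exact-equality run immediately preceding the first strict
    exceedance counts as part of the crossing (so a trace that touches
    the old evidence exactly at +2 s and exceeds it thereafter reports
    2 s), but equality alone never counts as a detected switch.
    """
    after = rel_times_s > 0
    strict = after & (avg_new > avg_old)
    if not np.any(strict):
        return float("inf")
    k = int(np.argmax(strict))
    while k > 0 and after[k - 1] and avg_new[k - 1] == avg_old[k - 1]:
        k -= 1
    return float(rel_times_s[k])


def stability_intervals(trace: DecodingTrace) -> np.ndarray:
    """How long each decoded target was held before the decision changed.

    Any decision change counts as a decoded switch (correct or not).  The
    initial hold — from the first defined decision to the first switch —
    is included; the final, unterminated segment is not.  A constant
    decision stream therefore yields no intervals.
    """
    defined = trace.decision >= 0
    dec = trace.decision[defined]
    t = trace.times_s[defined]
    if dec.size < 2:
        return np.array([])
    change_t = t[np.flatnonzero(np.diff(dec) != 0) + 1]
    if change_t.size == 0:
        return np.array([])
    return np.diff(np.concatenate([[t[0]], change_t]))


def switch_report(
    session: Session,
    method: str = "erpc-hold",
    duration_s: float = 4.0,
    n_folds: int = 5,
    step_s: float = 0.1,
    span_s: float = 8.0,
    cfg: ClassifierConfig | None = None,
) -> SwitchReport:
    """Full simulated-switching analysis for one method and duration."""
    cfg = cfg or ClassifierConfig()
    folds = make_folds(session.spec.n_trials, n_folds)
    trials = session.trials()
    traces, sfolds, intervals = [], [], []
    for fold in folds:
        train_trials = [trials[i] for i in range(len(trials)) if i not in set(fold)]
        models = _train_fold(session, train_trials, duration_s, (method,), cfg)
        sfold = simulate_switching(session, fold)
        view = _fold_view(session, sfold)
        trace = decode_fold(
            session, models, sfold.span_f, duration_s, method, step_s, fold_view=view
        )
        traces.append(trace)
        sfolds.append(sfold)
        intervals.append(stability_intervals(trace))
    evidence = "r" if method == "cca" else "p"
    rel, avg_new, avg_old, n_switches = average_switch_course(
        traces, sfolds, evidence, span_s, step_s
    )
    return SwitchReport(
        rel_times_s=rel,
        avg_new=avg_new,
        avg_old=avg_old,
        latency_s=switch_latency(rel, avg_new, avg_old),
        intervals_s=np.concatenate(intervals) if intervals else np.array([]),
        ideal_latency_s=duration_s / 2.0,
        ideal_intervals_s=session.trial_durations_s.copy(),
        n_switches=n_switches,
    )


# ---------------------------------------------------------------------------
# method comparison


def compare_methods(acc_a: np.ndarray, acc_b: np.ndarray) -> np.ndarray:
    """Bonferroni-corrected paired t-tests per duration.

    ``acc_a``/``acc_b`` are (n_subjects, n_durations) accuracy matrices
    paired across methods; p-values are multiplied by the number of
    durations and clipped at 1.  Identical vectors give t = 0, p = 1.
    """
    acc_a = np.atleast_2d(np.asarray(acc_a, dtype=float))
    acc_b = np.atleast_2d(np.asarray(acc_b, dtype=float))
    if acc_a.shape != acc_b.shape:
        raise ValueError("accuracy matrices must have matching shapes")
    if acc_a.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 subjects/replicates")
    n_dur = acc_a.shape[1]
    ps = np.empty(n_dur)
    for j in range(n_dur):
        d = acc_a[:, j] - acc_b[:, j]
        if np.allclose(d, 0):
            ps[j] = 1.0
            continue
        ps[j] = stats.ttest_rel(acc_a[:, j], acc_b[:, j]).pvalue
    return np.minimum(ps * n_dur, 1.0)
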