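"""ERPC classifier, decision rules, and the CCA baseline."""

import numpy as np
import pytest
from scipy import linalg

from aaderp.decoders import (
    ClassifierConfig,
    LagConfig,
    _lag_matrix,
    combine_type_probs,
    decode_cca_window,
    decode_trace,
    erpc_decide,
    fit_cca,
    tile_windows,
    train_erpc,
)
from aaderp.neural import NeuralEnvelope


def _toy_training_session(rng, separation, n_trials=12, trial_s=10.0, n_ch=3):
    """A session whose two talkers' events evoke Gaussian ERP classes with
    a controllable centroid separation (in units of the noise SD)."""
    rate = 100.0
    total = n_trials * trial_s
    n_frames = int(total * rate)
    vals = rng.normal(0.0, 1.0, (n_ch, n_frames))
    trials = [(i * trial_s, trial_s, i % 2) for i in range(n_trials)]
    pattern = rng.normal(size=(n_ch, 51))
    pattern /= np.linalg.norm(pattern) / np.sqrt(pattern.size)
    events = {0: {"glimpsed": [], "masked": [], "all": []}, 1: {"glimpsed": [], "masked": [], "all": []}}
    for t0, dur, target in trials:
        for talker in (0, 1):
            frames = (np.arange(t0 + 0.5 + 0.25 * talker, t0 + dur - 0.9, 0.5) * rate).astype(int)
            sign = 1.0 if talker == target else -1.0
            for f in frames:
                vals[:, f : f + 51] += sign * 0.5 * separation * pattern
            events[talker]["glimpsed"].append(frames[::2])
            events[talker]["masked"].append(frames[1::2])
            events[talker]["all"].append(frames)
    for talker in (0, 1):
        for typ in events[talker]:
            events[talker][typ] = np.sort(np.concatenate(events[talker][typ]))
    return NeuralEnvelope(vals), events, trials


class TestTraining:
    def test_separable_classes_reach_perfect_heldout_accuracy(self, rng):
        """With centroid separation 10x the noise SD, held-out windows are
        classified perfectly.  Oracle: a nearest-centroid rule on the same
        features is itself perfect, so the SVM must match it."""
        env, events, trials = _toy_training_session(rng, separation=10.0)
        train_trials, test_trials = trials[:8], trials[8:]
        model = train_erpc(env, events, train_trials, 2.0, "all")
        X, y = [], []
        from aaderp.neural import erp_matrix

        for s, e, target in tile_windows(test_trials, 2.0):
            for talker in (0, 1):
                fr = events[talker]["all"]
                fr = fr[(fr > s) & (fr <= e)]
                X.append(erp_matrix(env, fr).mean(axis=0).ravel())
                y.append(1 if talker == target else 0)
        p = model.predict_target_proba(np.asarray(X))
        y = np.asarray(y)
        assert np.mean((p > 0.5) == y) == 1.0
        # nearest-centroid oracle agrees
        X = np.asarray(X)
        c1, c0 = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
        nc = np.linalg.norm(X - c1, axis=1) < np.linalg.norm(X - c0, axis=1)
        assert np.mean(nc == y) == 1.0

    def test_identical_classes_stay_at_chance(self, rng):
        env, events, trials = _toy_training_session(rng, separation=0.0, n_trials=16)
        model = train_erpc(env, events, trials[:10], 2.0, "all")
        from aaderp.neural import erp_matrix

        X, y = [], []
        for s, e, target in tile_windows(trials[10:], 2.0):
            for talker in (0, 1):
                fr = events[talker]["all"]
                fr = fr[(fr > s) & (fr <= e)]
                X.append(erp_matrix(env, fr).mean(axis=0).ravel())
                y.append(1 if talker == target else 0)
        p = model.predict_target_proba(np.asarray(X))
        acc = np.mean((p > 0.5) == np.asarray(y))
        se = np.sqrt(0.25 / len(y))
        assert abs(acc - 0.5) < 3 * se + 1e-9

    @pytest.mark.parametrize("n_ch", [1, 4])
    def test_feature_dimension_contract(self, rng, n_ch):
        env, events, trials = _toy_training_session(rng, separation=5.0, n_ch=n_ch)
        model = train_erpc(env, events, trials[:8], 2.0, "glimpsed")
        assert model.n_channels * model.n_lags == n_ch * 51
        with pytest.raises(ValueError):
            model.predict_target_proba(np.zeros((1, n_ch * 51 + 1)))

    def test_single_class_training_raises(self, rng):
        env, events, trials = _toy_training_session(rng, separation=5.0)
        one_sided = [(t0, d, 0) for t0, d, _ in trials[:6]]
        # remove talker 1's events so only class-1 samples would exist
        events_one = {0: events[0], 1: {k: np.array([], int) for k in events[1]}}
        with pytest.raises(ValueError):
            train_erpc(env, events_one, one_sided, 2.0, "all")

    def test_label_swap_flips_probabilities(self, rng):
        env, events, trials = _toy_training_session(rng, separation=6.0)
        swapped = [(t0, d, 1 - tgt) for t0, d, tgt in trials]
        m = train_erpc(env, events, trials[:8], 2.0, "all")
        m_swap = train_erpc(env, events, swapped[:8], 2.0, "all")
        from aaderp.neural import erp_matrix

        X = []
        for s, e, _ in tile_windows(trials[8:], 2.0):
            fr = events[0]["all"]
            fr = fr[(fr > s) & (fr <= e)]
            X.append(erp_matrix(env, fr).mean(axis=0).ravel())
        p = m.predict_target_proba(np.asarray(X))
        q = m_swap.predict_target_proba(np.asarray(X))
        assert np.allclose(p, 1 - q, atol=0.15)  # up to calibration refit noise


class TestDecisionRules:
    def test_joint_probability_is_mean_of_both_classifiers(self):
        assert combine_type_probs(0.9, 0.7) == pytest.approx(0.8)

    def test_single_type_uses_that_classifier(self):
        assert combine_type_probs(0.6, None) == pytest.approx(0.6)
        assert combine_type_probs(None, 0.3) == pytest.approx(0.3)

    def test_no_events_gives_no_decision(self):
        assert combine_type_probs(None, None) is None

    def test_both_talkers_present_higher_wins(self):
        assert erpc_decide(0.7, 0.4) == 0

    def test_single_talker_against_half(self):
        assert erpc_decide(None, 0.3) == 0  # non-target below 50% -> target
        assert erpc_decide(None, 0.8) == 1
        assert erpc_decide(0.6, None) == 0
        assert erpc_decide(0.2, None) == 1

    def test_both_absent_holds_previous(self):
        assert erpc_decide(None, None, previous_decision=1) == 1
        assert erpc_decide(None, None, previous_decision=-1) == -1

    def test_exact_tie_breaks_to_lower_index(self):
        assert erpc_decide(0.6, 0.6) == 0


class TestCca:
    def test_delayed_copy_reaches_unit_correlation(self, rng):
        """One neural channel equal to the envelope delayed by 200 ms (a
        lag inside [-500, 0] ms) must give canonical correlation ~1."""
        env_sig = rng.normal(size=4000).cumsum() * 0.01
        env_sig -= env_sig.min()
        delay = 20
        neural = np.roll(env_sig, delay)[None, :]
        model = fit_cca(NeuralEnvelope(neural), env_sig)
        assert model.canonical_correlation >= 0.999

    def test_matches_generalized_eigenvalue_oracle(self, rng):
        """Top canonical correlation agrees to 1e-6 with an independent
        generalized-eigenvalue solution of the CCA normal equations."""
        n, ch = 2000, 5
        X = rng.normal(size=(n, ch))
        env_sig = rng.normal(size=n)
        model = fit_cca(NeuralEnvelope(X.T), env_sig, ridge=1e-10)
        L = LagConfig().n_lags
        Y = _lag_matrix(env_sig, L)[L - 1 :]
        Xv = X[L - 1 :]
        Xc = Xv - Xv.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        m = Xc.shape[0]
        Sxx = Xc.T @ Xc / m
        Syy = Yc.T @ Yc / m
        Sxy = Xc.T @ Yc / m
        A = Sxy @ linalg.solve(Syy, Sxy.T, assume_a="pos")
        rho2 = linalg.eigh(A, Sxx, eigvals_only=True)[-1]
        assert model.canonical_correlation == pytest.approx(np.sqrt(rho2), abs=1e-6)

    def test_envelope_feature_length_is_51(self):
        assert LagConfig().n_lags == 51

    def test_invariant_to_channel_rescaling(self, rng):
        """The correlation objective is affine-invariant per channel (the
        tiny stabilizing ridge is sent to 0 to expose the exact
        invariance)."""
        X = rng.normal(size=(5, 3000))
        env_sig = rng.normal(size=3000)
        r1 = fit_cca(NeuralEnvelope(X), env_sig, ridge=1e-12).canonical_correlation
        X2 = X * np.array([3.0, 0.2, 7.0, 1.0, 0.01])[:, None]
        r2 = fit_cca(NeuralEnvelope(X2), env_sig, ridge=1e-12).canonical_correlation
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_window_decoding_prefers_matching_talker(self, rng):
        env_t = np.abs(rng.normal(size=6000).cumsum() * 0.01)
        env_nt = np.abs(rng.normal(size=6000).cumsum() * 0.01)
        neural = (env_t + 0.1 * rng.normal(size=6000))[None, :]
        model = fit_cca(NeuralEnvelope(neural), env_t)
        wins = 0
        windows = [(s, s + 400) for s in range(100, 5500, 400)]
        for w in windows:
            dec, (r_t, r_nt) = decode_cca_window(model, NeuralEnvelope(neural), [env_t, env_nt], w)
            wins += dec == 0 and r_t > r_nt
        assert wins / len(windows) > 0.95

    def test_tie_breaks_low_and_short_window_raises(self, rng):
        env_sig = np.abs(rng.normal(size=2000))
        neural = rng.normal(size=(2, 2000))
        model = fit_cca(NeuralEnvelope(neural), env_sig)
        dec, rs = decode_cca_window(model, NeuralEnvelope(neural), [env_sig, env_sig], (100, 500))
        assert dec == 0 and rs[0] == rs[1]
        with pytest.raises(ValueError):
            decode_cca_window(model, NeuralEnvelope(neural), [env_sig, env_sig], (100, 102))

    def test_zero_variance_window_gives_zero_correlation(self, rng):
        env_sig = np.abs(rng.normal(size=2000))
        neural = rng.normal(size=(2, 2000))
        model = fit_cca(NeuralEnvelope(neural), env_sig)
        flat = np.zeros(2000)
        _, rs = decode_cca_window(model, NeuralEnvelope(neural), [flat, env_sig], (100, 500))
        assert rs[0] == 0.0


class TestTraces:
    def test_fallback_differs_from_hold_only_on_eventless_windows(self, rng, small_session):
        from aaderp.evaluation import _fold_span, _train_fold, make_folds

        s = small_session
        trials = s.trials()
        fold = make_folds(s.spec.n_trials, 2)[1]
        train = [trials[i] for i in range(len(trials)) if i not in set(fold)]
        models = _train_fold(s, train, 4.0, ("erpc-hold", "erpc-fallback"), ClassifierConfig())
        span = _fold_span(s, fold)
        common = dict(
            model_g=models["glimpsed"],
            model_m=models["masked"],
            cca_model=models["cca"],
            events_by_talker=s.event_frames(),
            talker_envelopes=[e.values for e in s.envelopes],
        )
        hold = decode_trace(s.neural, span, 4.0, mode="erpc-hold", **common)
        fb = decode_trace(s.neural, span, 4.0, mode="erpc-fallback", **common)
        has_events = (
            (hold.n_events[(0, "glimpsed")] + hold.n_events[(0, "masked")]
             + hold.n_events[(1, "glimpsed")] + hold.n_events[(1, "masked")]) > 0
        )
        np.testing.assert_array_equal(hold.decision[has_events], fb.decision[has_events])
        diff = hold.decision != fb.decision
        assert not np.any(diff & has_events)

    def test_hold_semantics_piecewise_constant(self, small_session):
        from aaderp.evaluation import _fold_span, _train_fold, make_folds

        s = small_session
        trials = s.trials()
        fold = make_folds(s.spec.n_trials, 2)[0]
        train = [trials[i] for i in range(len(trials)) if i not in set(fold)]
        models = _train_fold(s, train, 4.0, ("erpc-hold",), ClassifierConfig())
        trace = decode_trace(
            s.neural,
            _fold_span(s, fold),
            4.0,
            mode="erpc-hold",
            model_g=models["glimpsed"],
            model_m=models["masked"],
            events_by_talker=s.event_frames(),
        )
        changes = np.sum(np.diff(trace.decision[trace.decision >= 0]) != 0)
        assert changes <= np.sum(trace.evidence_updated)
        # between updates the decision never changes
        const = np.diff(trace.decision) == 0
        assert np.all(const | trace.evidence_updated[1:])

    def test_probabilities_lie_in_unit_interval(self, small_session):
        from aaderp.evaluation import _fold_span, _train_fold, make_folds

        s = small_session
        trials = s.trials()
        fold = make_folds(s.spec.n_trials, 2)[1]
        train = [trials[i] for i in range(len(trials)) if i not in set(fold)]
        models = _train_fold(s, train, 4.0, ("erpc-hold",), ClassifierConfig())
        trace = decode_trace(
            s.neural,
            _fold_span(s, fold),
            4.0,
            mode="erpc-hold",
            model_g=models["glimpsed"],
            model_m=models["masked"],
            events_by_talker=s.event_frames(),
        )
        p = trace.p[np.isfinite(trace.p)]
        assert np.all((p > 0) & (p < 1))
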