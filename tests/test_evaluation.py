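"""Performance curves, switching simulation, latency, stability, comparisons."""

import numpy as np
import pytest

from aaderp.decoders import DecodingTrace
from aaderp.evaluation import (
    average_switch_course,
    compare_methods,
    make_folds,
    simulate_switching,
    stability_intervals,
    switch_latency,
    trace_accuracy,
)


def _trace(times, decision, p=None):
    n = times.size
    return DecodingTrace(
        times_s=times,
        p=p if p is not None else np.full((2, n), np.nan),
        r=np.full((2, n), np.nan),
        decision=decision,
        evidence_updated=np.ones(n, bool),
    )


class TestFolds:
    def test_35_trials_give_5_folds_of_7(self):
        folds = make_folds(35, 5)
        assert [len(f) for f in folds] == [7] * 5
        assert np.array_equal(np.concatenate(folds), np.arange(35))

    def test_too_few_trials_raise(self):
        with pytest.raises(ValueError):
            make_folds(3, 5)


class TestSwitchCounts:
    def test_fold_of_7_trials_has_6_switches(self, small_session):
        # small_session has 10 trials; use a synthetic 7-trial fold index
        fold = np.arange(7)
        sw = simulate_switching(small_session, fold)
        assert sw.switch_times_s.size == 6
        # targets alternate in the presented coordinates
        assert np.all(np.abs(np.diff(sw.truth)) == 1)

    def test_single_trial_fold_has_no_switches(self, small_session):
        sw = simulate_switching(small_session, np.array([2]))
        assert sw.switch_times_s.size == 0

    def test_full_session_5x7_gives_30_switches(self):
        from aaderp import SessionSpec, generate_session

        s = generate_session(SessionSpec(n_trials=35, n_channels=2, seed=3))
        total = sum(
            simulate_switching(s, fold).switch_times_s.size for fold in make_folds(35, 5)
        )
        assert total == 30


class TestAccuracy:
    def test_oracle_decoder_scores_one(self):
        times = np.arange(100) * 0.1
        truth = (times // 2).astype(int) % 2
        trace = _trace(times, truth.copy())
        acc, excluded = trace_accuracy(trace, truth)
        assert acc == 1.0 and excluded == 0

    def test_coin_flip_decoder_near_chance(self, rng):
        n = 1000
        times = np.arange(n) * 0.1
        decision = rng.integers(0, 2, n)
        truth = rng.integers(0, 2, n)
        acc, _ = trace_accuracy(_trace(times, decision), truth)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_undefined_prefix_excluded_from_denominator(self):
        times = np.arange(10) * 0.1
        decision = np.array([-1, -1, 0, 0, 1, 1, 0, 0, 1, 1])
        truth = np.array([1, 1, 0, 0, 1, 1, 0, 0, 1, 1])
        acc, excluded = trace_accuracy(_trace(times, decision), truth)
        assert acc == 1.0 and excluded == 2

    def test_label_swapped_accuracies_sum_to_one(self, rng):
        n = 500
        times = np.arange(n) * 0.1
        decision = rng.integers(0, 2, n)
        truth = rng.integers(0, 2, n)
        a, _ = trace_accuracy(_trace(times, decision), truth)
        b, _ = trace_accuracy(_trace(times, 1 - decision), truth)
        assert a + b == pytest.approx(1.0)


class TestSwitchLatency:
    def test_instant_step_detected_after_one_sample(self):
        rel = np.arange(-5, 5, 0.1)
        new = (rel >= 0).astype(float)
        old = 1.0 - new
        lat = switch_latency(rel, new, old)
        assert 0 < lat <= 0.1 + 1e-9

    def test_constructed_crossing_at_two_seconds(self):
        rel = np.arange(-50, 51) / 10.0  # exact decimal grid
        new = 0.5 + 0.125 * (rel - 2.0)  # touches 0.5 exactly at +2.0 s
        old = np.full(rel.size, 0.5)
        assert switch_latency(rel, new, old) == pytest.approx(2.0)

    def test_moving_average_of_step_crosses_at_half_window(self):
        """A decoder that averages a step signal over a window W crosses
        at W/2 — the 'ideal' latency for that window size."""
        step = 0.01
        rel = np.arange(-10, 10, step)
        for W in (2.0, 4.0):
            k = int(W / step)
            sig = (rel >= 0).astype(float)
            ma = np.convolve(sig, np.ones(k) / k, mode="full")[: rel.size]
            lat = switch_latency(rel, ma, 1 - ma)
            assert lat == pytest.approx(W / 2, abs=step + 1e-9)

    def test_never_crossing_returns_infinity(self):
        rel = np.arange(-2, 2, 0.1)
        assert switch_latency(rel, np.zeros(rel.size), np.ones(rel.size)) == np.inf

    def test_shift_equivariance(self):
        rel = np.arange(-50, 51) / 10.0
        new = 0.5 + 0.125 * (rel - 2.0)
        old = np.full(rel.size, 0.5)
        base = switch_latency(rel, new, old)
        shifted = switch_latency(rel, 0.5 + 0.125 * (rel - 3.0), old)
        assert shifted - base == pytest.approx(1.0)

    def test_average_course_aligns_switches(self):
        # two identical traces with a known evidence step at each switch
        times = np.arange(0, 60, 0.1)
        p = np.zeros((2, times.size))
        switch_t = 30.0
        p[1] = (times >= switch_t).astype(float)
        p[0] = 1 - p[1]
        trace = _trace(times, np.zeros(times.size, int), p=p)
        from aaderp.evaluation import SwitchFold

        fold = SwitchFold(
            trial_idx=np.array([0, 1]),
            swap=np.array([False, True]),
            truth=np.array([0, 1]),
            switch_times_s=np.array([switch_t]),
            span_f=(0, 600),
        )
        rel, avg_new, avg_old, n = average_switch_course([trace], [fold], span_s=5.0)
        assert n == 1
        lat = switch_latency(rel, avg_new, avg_old)
        assert 0 < lat <= 0.2


class TestStability:
    def test_constant_decision_gives_no_intervals(self):
        times = np.arange(100) * 0.1
        trace = _trace(times, np.zeros(100, int))
        assert stability_intervals(trace).size == 0

    def test_alternating_every_second_for_20s(self):
        times = np.arange(0, 20, 0.1)
        decision = (times // 1.0).astype(int) % 2
        intervals = stability_intervals(_trace(times, decision))
        assert intervals.size == 19
        np.testing.assert_allclose(intervals, 1.0)


class TestSwitchDynamics:
    def test_erpc_holds_decisions_longer_than_cca(self):
        """On a simulated-switch session, CCA produces many more decoded
        switches with short hold durations than ERPC-hold — the decoding
        stability contrast between the two methods."""
        from aaderp import SessionSpec, generate_session, switch_report

        s = generate_session(SessionSpec(n_trials=21, n_channels=6, seed=3))
        erpc = switch_report(s, "erpc-hold", 4.0, n_folds=3)
        cca = switch_report(s, "cca", 4.0, n_folds=3)
        assert cca.intervals_s.size > erpc.intervals_s.size
        short_cca = np.mean(cca.intervals_s < 4.0)
        short_erpc = np.mean(erpc.intervals_s < 4.0) if erpc.intervals_s.size else 0.0
        assert short_cca > short_erpc
        # perfect tracking would reproduce the trial-duration distribution
        assert np.median(erpc.ideal_intervals_s) > 4.0


class TestCompareMethods:
    def test_identical_curves_give_p_one(self):
        acc = np.random.default_rng(0).random((6, 4))
        np.testing.assert_array_equal(compare_methods(acc, acc.copy()), np.ones(4))

    def test_consistent_offset_significant_after_bonferroni(self, rng):
        """A +0.1 accuracy advantage with tiny jitter over 8 replicates is
        significant at every duration even after multiplying by the
        5-duration family.  Oracle: the closed-form paired t statistic."""
        b = 0.6 + 0.01 * rng.normal(size=(8, 5))
        a = b + 0.1 + 0.001 * rng.normal(size=(8, 5))
        ps = compare_methods(a, b)
        assert np.all(ps < 0.05)
        d = (a - b)[:, 0]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        p_manual = 2 * stats.t.sf(abs(t), len(d) - 1) * 5
        assert ps[0] == pytest.approx(min(p_manual, 1.0), rel=1e-9)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            compare_methods(np.array([[0.7, 0.8]]), np.array([[0.6, 0.7]]))
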