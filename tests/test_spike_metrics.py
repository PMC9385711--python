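"""Spike detection, relay scoring, fitness and parameter error."""

import numpy as np
import pytest

from tcfit import (
    FitnessWeights,
    RelayReport,
    SpikeFeatures,
    SpikeTrain,
    classify_relay,
    classify_state,
    detect_spikes,
    extract_features,
    fitness,
    log_parameter_error,
    parameter_error,
)
from tcfit.spike_metrics import DegenerateTraceError

from conftest import make_trace_result

THR = -25.0


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        res = make_trace_result(np.arange(0, 100, 0.1), np.full(1000, -65.0))
        assert len(detect_spikes(res, THR)) == 0

    def test_three_triangles_at_apices(self, triangle_trace):
        res, apices = triangle_trace
        spikes = detect_spikes(res, THR)
        assert len(spikes) == 3
        assert spikes.times == pytest.approx(apices, abs=0.051)
        assert spikes.peaks == pytest.approx([10.0, 10.0, 10.0], abs=0.5)

    def test_touching_threshold_counts(self):
        times = np.arange(0, 10, 0.1)
        v = np.full_like(times, -60.0)
        v[50] = THR  # exactly one sample at threshold
        res = make_trace_result(times, v)
        spikes = detect_spikes(res, THR)
        assert len(spikes) == 1
        assert spikes.peaks[0] == THR

    def test_t_min_crops_early_spikes(self, triangle_trace):
        res, _ = triangle_trace
        spikes = detect_spikes(res, THR, t_min=40.0)
        assert len(spikes) == 2


def _brute_force_relay(spike_times, onsets, window):
    """Independent per-window recount used as an oracle."""
    missed = bad = 0
    onsets = list(onsets)
    for i, onset in enumerate(onsets):
        end = onset + window
        if i + 1 < len(onsets):
            end = min(end, onsets[i + 1])
        n = sum(1 for t in spike_times if onset <= t < end)
        if n == 0:
            missed += 1
        elif n >= 2:
            bad += 1
    return missed, bad


class TestClassifyRelay:
    def test_perfect_relay(self):
        onsets = np.arange(0.0, 250.0, 25.0)
        spikes = SpikeTrain(times=onsets + 3.0, peaks=np.zeros(10))
        rep = classify_relay(spikes, onsets, window=25.0)
        assert (rep.missed, rep.bad, rep.ri) == (0, 0, 1.0)

    def test_total_failure(self):
        onsets = np.arange(0.0, 250.0, 25.0)
        spikes = SpikeTrain(times=np.empty(0), peaks=np.empty(0))
        rep = classify_relay(spikes, onsets, window=25.0)
        assert rep.missed == 10
        assert rep.ri == 0.0

    def test_mixed_fixture(self):
        # 10 onsets: windows 0 and 1 doubled, 2-4 empty, rest single
        onsets = np.arange(0.0, 250.0, 25.0)
        times = []
        for k in (0, 1):
            times += [onsets[k] + 3.0, onsets[k] + 8.0]
        for k in range(5, 10):
            times.append(onsets[k] + 3.0)
        spikes = SpikeTrain(times=np.sort(times), peaks=np.zeros(len(times)))
        rep = classify_relay(spikes, onsets, window=25.0)
        assert (rep.missed, rep.bad) == (3, 2)
        assert rep.error_index == pytest.approx(0.5)
        assert rep.ri == pytest.approx(0.5)

    def test_overlapping_windows_warn_and_truncate(self):
        onsets = np.array([0.0, 10.0])
        spikes = SpikeTrain(times=np.array([12.0]), peaks=np.zeros(1))
        with pytest.warns(UserWarning, match="truncated"):
            rep = classify_relay(spikes, onsets, window=25.0)
        # spike at 12 belongs to the second window only
        assert rep.missed == 1

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n_on = rng.integers(2, 12)
            onsets = np.sort(rng.uniform(0, 500, n_on))
            onsets = onsets[np.r_[True, np.diff(onsets) > 1e-6]]
            n_sp = rng.integers(0, 30)
            times = np.unique(rng.uniform(0, 550, n_sp))
            spikes = SpikeTrain(times=times, peaks=np.zeros(len(times)))
            window = rng.uniform(1.0, 60.0)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = classify_relay(spikes, onsets, window=window)
            missed, bad = _brute_force_relay(times, onsets, window)
            assert (rep.missed, rep.bad) == (missed, bad)
            assert rep.error_index + rep.ri == pytest.approx(1.0)

    def test_orphan_strict_mode(self):
        onsets = np.array([0.0, 100.0])
        # one prompt spike, then an orphan between windows
        spikes = SpikeTrain(times=np.array([3.0, 60.0]), peaks=np.zeros(2))
        lenient = classify_relay(spikes, onsets, window=25.0)
        strict = classify_relay(spikes, onsets, window=25.0, orphans_are_bad=True)
        assert lenient.bad == 0
        assert strict.bad == 1


class TestClassifyState:
    @pytest.mark.parametrize(
        "ri, state",
        [(0.95, "normal"), (0.3, "parkinsonian"), (0.7, "indeterminate"),
         (0.9, "indeterminate"), (0.5, "indeterminate")],
    )
    def test_thresholds(self, ri, state):
        assert classify_state(ri) == state

    def test_domain_error(self):
        with pytest.raises(ValueError):
            classify_state(1.2)


class TestExtractFeatures:
    def test_flat_trace_sentinels(self):
        res = make_trace_result(np.arange(0, 100, 0.1), np.full(1000, -65.0))
        spikes = detect_spikes(res, THR)
        relay = RelayReport(total_inputs=4, missed=4, bad=0)
        f = extract_features(res, spikes, relay, threshold=THR)
        assert (f.n, f.st) == (0, -65.0)
        assert f.pk == THR  # zero-spike sentinel

    def test_pk_is_mean_peak(self):
        spikes = SpikeTrain(times=np.array([1.0, 2.0]), peaks=np.array([10.0, 20.0]))
        res = make_trace_result(np.arange(0, 10, 0.1), np.full(100, -65.0))
        relay = RelayReport(total_inputs=2, missed=0, bad=0)
        f = extract_features(res, spikes, relay, threshold=THR)
        assert f.pk == pytest.approx(15.0)

    def test_st_hand_computed_mean(self):
        times = np.arange(5)
        v = np.array([-60.0, -30.0, -20.0, -40.0, -65.0])
        res = make_trace_result(times, v)
        spikes = SpikeTrain(times=np.array([2.0]), peaks=np.array([-20.0]))
        relay = RelayReport(total_inputs=1, missed=0, bad=0)
        f = extract_features(res, spikes, relay, threshold=THR)
        # strictly-below-threshold samples: -60, -30, -40, -65
        assert f.st == pytest.approx(np.mean([-60.0, -30.0, -40.0, -65.0]))

    def test_degenerate_trace_raises(self):
        res = make_trace_result(np.arange(3), np.full(3, 0.0))
        spikes = SpikeTrain(times=np.array([1.0]), peaks=np.array([0.0]))
        relay = RelayReport(total_inputs=1, missed=0, bad=0)
        with pytest.raises(DegenerateTraceError):
            extract_features(res, spikes, relay, threshold=THR)


class TestFitness:
    def _feat(self, ri=0.5, n=10, pk=5.0, st=-60.0):
        return SpikeFeatures(ri=ri, n=n, pk=pk, st=st)

    def test_identity_is_zero(self):
        f = self._feat()
        assert fitness(f, f, FitnessWeights.unit()) == 0.0

    def test_worked_example(self):
        ori = self._feat(ri=0.5, n=10, pk=5.0, st=-60.0)
        rec = self._feat(ri=0.6, n=12, pk=6.5, st=-59.5)
        q = fitness(rec, ori, FitnessWeights.unit())
        assert q == pytest.approx(0.01 + 4.0 + 2.25 + 0.25)

    def test_linear_in_weights(self):
        ori, rec = self._feat(), self._feat(ri=0.6, n=12, pk=6.0, st=-59.0)
        q1 = fitness(rec, ori, FitnessWeights(1, 1, 1, 1))
        q2 = fitness(rec, ori, FitnessWeights(2, 2, 2, 2))
        assert q2 == pytest.approx(2 * q1)

    def test_trial_sum_and_order_invariance(self):
        a, b = self._feat(ri=0.2), self._feat(ri=0.8)
        ori = [self._feat(), self._feat()]
        q_ab = fitness([a, b], ori, FitnessWeights.unit())
        q_single = fitness(a, ori[0]) + fitness(b, ori[1])
        assert q_ab == pytest.approx(q_single)

    def test_trial_mismatch_raises(self):
        with pytest.raises(ValueError, match="trial-count"):
            fitness([self._feat()], [self._feat(), self._feat()])

    def test_positive_iff_any_weighted_difference(self):
        ori = self._feat()
        rec = self._feat(st=-59.0)
        assert fitness(rec, ori, FitnessWeights(1, 1, 1, 0)) == 0.0
        assert fitness(rec, ori, FitnessWeights(1, 1, 1, 1)) > 0.0

    def test_scaled_weights_order_unity(self):
        ref = self._feat(ri=0.0, n=48, pk=-9.6, st=-55.0)
        w = FitnessWeights.from_reference(ref)
        terms = w.as_array() * ref.as_array() ** 2
        assert np.all(terms <= 1.0 + 1e-9)


class TestParameterError:
    def test_identity_zero(self):
        assert parameter_error([-3.5, 3, 120], [-3.5, 3, 120]) == 0.0

    def test_matches_naive_sum_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b = rng.normal(size=3), rng.normal(size=3)
            naive = sum((x - y) ** 2 for x, y in zip(a, b))
            assert parameter_error(a, b) == pytest.approx(naive, rel=1e-15)

    def test_published_error_magnitudes(self):
        truth = [-3.5, 3.0, 120.0]
        assert log_parameter_error([-3.4977, 3.0033, 129.6313], truth) == pytest.approx(
            4.53, abs=0.005
        )
        ln_improved = log_parameter_error([-3.4991, 3.0215, 119.6532], truth)
        assert ln_improved == pytest.approx(-2.11, abs=0.005)
        assert ln_improved < -2.0
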