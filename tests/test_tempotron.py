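import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latency_readout.spikeio import Dataset, SpikeTrain, TrialPattern
from latency_readout.tempotron import (
    DepressionParams,
    LearnState,
    PSPKernel,
    TempotronModel,
    classify,
    depression_factors,
    learn_step,
    peak_voltage,
    psp_kernel,
    smooth_error_curve,
    train,
)

from .conftest import grid_peak_oracle, random_model, random_pattern


class TestKernel:
    def test_causality_and_limits(self, kernel):
        assert psp_kernel(0.0, kernel) == 0.0
        assert psp_kernel(-5.0, kernel) == 0.0
        assert psp_kernel(1000.0, kernel) < 1e-10

    def test_peak_location_and_height(self, kernel):
        # closed-form argmax of the double exponential
        t_star = 10.0 * 2.5 / 7.5 * math.log(4.0)
        assert kernel.t_peak == pytest.approx(t_star)
        assert kernel.t_peak == pytest.approx(4.6210, abs=1e-4)
        assert psp_kernel(kernel.t_peak, kernel) == pytest.approx(1.0, abs=1e-10)
        # dense grid confirms nothing exceeds the analytic peak
        grid = np.linspace(0.0, 100.0, 200001)
        assert psp_kernel(grid, kernel).max() <= 1.0 + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(
        tau_m=st.floats(1.0, 100.0),
        ratio=st.floats(0.05, 0.95),
    )
    def test_unit_peak_any_time_constants(self, tau_m, ratio):
        k = PSPKernel(tau_m=tau_m, tau_s=tau_m * ratio)
        assert psp_kernel(k.t_peak, k) == pytest.approx(1.0, abs=1e-10)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            PSPKernel(tau_m=2.0, tau_s=2.0)


class TestDepression:
    def test_first_spike_full_resource(self):
        R = depression_factors(SpikeTrain(0, (10.0, 20.0, 30.0)), U=0.5, tau_d=100.0)
        assert R[0] == 1.0
        assert np.all(np.diff(R) < 0)

    def test_maximal_depression_closed_form(self):
        # U=1, ISI 5 ms, tau_d 500 ms: R2 = 1 - exp(-0.01)
        R = depression_factors(SpikeTrain(0, (10.0, 15.0)), U=1.0, tau_d=500.0)
        assert R[1] == pytest.approx(1.0 - math.exp(-0.01), abs=1e-12)
        assert R[1] < 0.02

    def test_instant_recovery_limit(self):
        R = depression_factors(SpikeTrain(0, (10.0, 10.5, 11.0)), U=1.0, tau_d=1e-9)
        assert np.allclose(R, 1.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            depression_factors((10.0, 5.0), U=0.5, tau_d=100.0)


class TestPeakVoltage:
    def test_single_spike_normalization(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)),))
        m = TempotronModel(np.array([0.8]), kernel=kernel)
        v, t = peak_voltage(p, m)
        assert v == pytest.approx(0.8, abs=1e-12)
        assert t == pytest.approx(20.0 + kernel.t_peak, abs=1e-9)

    def test_synchronous_spikes_sum(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)), SpikeTrain(1, (20.0,))))
        m = TempotronModel(np.array([0.6, 0.6]), kernel=kernel)
        assert peak_voltage(p, m)[0] == pytest.approx(1.2, abs=1e-12)

    def test_distant_spikes_give_larger_weight(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (10.0,)), SpikeTrain(1, (510.0,))))
        m = TempotronModel(np.array([0.7, 0.9]), kernel=kernel)
        assert peak_voltage(p, m, horizon=600.0)[0] == pytest.approx(0.9, abs=1e-9)

    def test_all_empty_pattern(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, ()), SpikeTrain(1, ())))
        m = TempotronModel(np.zeros(2), kernel=kernel)
        assert peak_voltage(p, m) == (0.0, None)

    def test_matches_grid_oracle(self, rng):
        for _ in range(30):
            p = random_pattern(rng)
            m = random_model(rng)
            v, _ = peak_voltage(p, m)
            v_oracle, _ = grid_peak_oracle(p, m)
            assert v == pytest.approx(v_oracle, abs=1e-6)

    def test_time_translation_invariance(self, rng):
        p = random_pattern(rng, window=100.0)
        m = random_model(rng)
        shifted = TrialPattern(
            0,
            tuple(
                SpikeTrain(tr.afferent_id, tuple(t + 17.0 for t in tr.times))
                for tr in p.trains
            ),
        )
        v1, t1 = peak_voltage(p, m)
        v2, t2 = peak_voltage(shifted, m)
        assert v2 == pytest.approx(v1, abs=1e-9)
        assert t2 == pytest.approx(t1 + 17.0, abs=1e-6)


class TestClassify:
    def test_crossing_precedes_peak(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)), SpikeTrain(1, (20.0,))))
        m = TempotronModel(np.array([0.6, 0.6]), kernel=kernel)
        fired, t_spike = classify(p, m)
        v, t_vmax = peak_voltage(p, m)
        assert fired and t_spike < t_vmax
        # V at the reported crossing equals threshold
        from latency_readout.tempotron import voltage_trace

        assert voltage_trace(p, m, [t_spike])[0] == pytest.approx(1.0, abs=1e-8)

    def test_strict_threshold(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)),))
        m = TempotronModel(np.array([0.99]), kernel=kernel)
        assert classify(p, m) == (False, None)

    def test_empty_pattern_silent(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, ()),))
        m = TempotronModel(np.array([5.0]), kernel=kernel)
        assert classify(p, m) == (False, None)

    def test_scale_invariance(self, rng):
        for _ in range(10):
            p = random_pattern(rng)
            m = random_model(rng)
            scaled = TempotronModel(m.weights * 3.7, threshold=3.7, kernel=m.kernel)
            assert classify(p, m)[0] == classify(p, scaled)[0]


class TestLearnStep:
    def test_correct_trial_no_change(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)),))
        m = TempotronModel(np.array([1.5]), kernel=kernel)
        state = LearnState(0.01, 0.0, np.zeros(1))
        err = learn_step(p, 1, m, state)  # fires, target: correct
        assert not err and m.weights[0] == 1.5

    def test_miss_update_is_lambda_times_kernel(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)),))
        m = TempotronModel(np.array([0.5]), kernel=kernel)
        state = LearnState(0.01, 0.0, np.zeros(1))
        _, t_vmax = peak_voltage(p, m)
        err = learn_step(p, 1, m, state)
        assert err
        expected = 0.5 + 0.01 * psp_kernel(t_vmax - 20.0, kernel)
        assert m.weights[0] == pytest.approx(expected, abs=1e-12)
        assert m.weights[0] > 0.5

    def test_false_alarm_decreases_weights(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, (20.0,)),))
        m = TempotronModel(np.array([1.5]), kernel=kernel)
        state = LearnState(0.01, 0.0, np.zeros(1))
        learn_step(p, 0, m, state)
        assert m.weights[0] < 1.5

    def test_depression_discounts_second_spike(self, kernel):
        # with U=1 the second spike of a train contributes ~nothing
        p = TrialPattern(0, (SpikeTrain(0, (20.0, 25.0)),))
        dep = DepressionParams(U=1.0, tau_d=500.0)
        m_dep = TempotronModel(np.array([0.5]), kernel=kernel, depression=dep)
        m_static = TempotronModel(np.array([0.5]), kernel=kernel)
        s_dep = LearnState(0.01, 0.0, np.zeros(1))
        s_static = LearnState(0.01, 0.0, np.zeros(1))
        learn_step(p, 1, m_dep, s_dep)
        learn_step(p, 1, m_static, s_static)
        dw_dep = m_dep.weights[0] - 0.5
        dw_static = m_static.weights[0] - 0.5
        assert dw_dep < dw_static  # second spike discounted

    def test_update_reduces_to_static_when_depression_off(self, kernel, rng):
        p = random_pattern(rng)
        w0 = rng.normal(0, 0.3, 5)
        m_none = TempotronModel(w0.copy(), kernel=kernel)
        m_weak = TempotronModel(
            w0.copy(), kernel=kernel, depression=DepressionParams(U=1e-9, tau_d=1e-6)
        )
        s1 = LearnState(0.01, 0.0, np.zeros(5))
        s2 = LearnState(0.01, 0.0, np.zeros(5))
        learn_step(p, 1, m_none, s1)
        learn_step(p, 1, m_weak, s2)
        assert np.allclose(m_none.weights, m_weak.weights, atol=1e-7)

    def test_spikeless_target_no_update(self, kernel):
        p = TrialPattern(0, (SpikeTrain(0, ()),))
        m = TempotronModel(np.array([0.5]), kernel=kernel)
        state = LearnState(0.01, 0.0, np.zeros(1))
        err = learn_step(p, 1, m, state)
        assert err and m.weights[0] == 0.5


def synchrony_task(n_trials=20, seed=0):
    """2-afferent task: targets fire together, nulls 40 ms apart."""
    rng = np.random.default_rng(seed)
    trials, labels = [], []
    for i in range(n_trials):
        t0 = float(rng.uniform(20.0, 80.0))
        if i % 2 == 0:
            trains = (SpikeTrain(0, (t0,)), SpikeTrain(1, (t0,)))
            labels.append(1)
        else:
            if i % 4 == 1:
                trains = (SpikeTrain(0, (t0,)), SpikeTrain(1, (t0 + 40.0,)))
            else:
                trains = (SpikeTrain(0, (t0 + 40.0,)), SpikeTrain(1, (t0,)))
            labels.append(0)
        trials.append(TrialPattern(i, trains))
    return Dataset(tuple(trials)), np.array(labels)


class TestTrain:
    def test_synchrony_task_solved(self):
        # a feasible weight pair exists (equal excitatory weights fire only
        # near synchrony); verify by grid search, then check learning finds it
        data, labels = synchrony_task()
        feasible = False
        for w in np.linspace(0.55, 0.95, 9):
            m = TempotronModel(np.array([w, w]))
            preds = [classify(t, m)[0] for t in data.trials]
            if np.array_equal(np.array(preds, dtype=int), labels):
                feasible = True
                break
        assert feasible
        # best-of-runs: an all-inhibitory initialization is a fixed point of
        # the error-driven rule, so several seeded runs are standard
        best = min(
            (
                train(data, labels, step_size=5e-3, cycles=500, init_sd=0.05, seed=s)
                for s in range(4)
            ),
            key=lambda r: r.error_curve.min(),
        )
        assert best.error_curve.min() == 0.0

    def test_zero_step_size_keeps_initialization(self):
        data, labels = synchrony_task()
        res = train(data, labels, step_size=0.0, cycles=30, init_sd=0.05, seed=7)
        rng = np.random.default_rng(7)
        assert np.allclose(res.model.weights, rng.normal(0.0, 0.05, 2))
        assert np.ptp(res.error_curve) == 0.0

    def test_reproducible(self):
        data, labels = synchrony_task()
        r1 = train(data, labels, step_size=5e-3, cycles=50, seed=11)
        r2 = train(data, labels, step_size=5e-3, cycles=50, seed=11)
        assert np.array_equal(r1.model.weights, r2.model.weights)
        assert np.array_equal(r1.error_curve, r2.error_curve)

    def test_needs_both_classes(self):
        data, labels = synchrony_task()
        with pytest.raises(ValueError):
            train(data, np.ones_like(labels), step_size=1e-3, cycles=10)


def test_smoothing_bounds_single_cycle_spike():
    flat = np.zeros(300)
    spiked = flat.copy()
    spiked[150] = 0.8
    s_flat = smooth_error_curve(flat, 50)
    s_spiked = smooth_error_curve(spiked, 50)
    assert np.max(np.abs(s_spiked - s_flat)) <= 0.8 / 50 + 1e-12
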