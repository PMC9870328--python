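"""Spike detection, ISI statistics, bursts, and response-curve experiments."""

import numpy as np
import pytest

from pqnsim.analysis import (
    ISISequence,
    SpikeTrain,
    StatisticError,
    compute_prc,
    cv_stat,
    detect_spikes,
    graded_response_curve,
    isi_transition_experiment,
    lv_stat,
    mse_points,
    poisson_spike_train,
    segment_bursts,
)
from pqnsim.dynamics import StimulusProgram, Trace, simulate


def _trace_from_v(v, dt=1.0):
    v = np.asarray(v, dtype=float)
    t = np.arange(len(v)) * dt
    return Trace(times=t, v=v, n=np.zeros_like(v), q=None, u=None,
                 stimulus=np.zeros_like(v), meta={"dt": dt})


class TestDetectSpikes:
    def test_subthreshold_trace_has_no_spikes(self):
        assert len(detect_spikes(_trace_from_v([-1.0] * 10))) == 0

    def test_interpolated_crossing_time(self):
        # crossing between samples 1 and 2: t = 1 + 0.5/0.7
        train = detect_spikes(_trace_from_v([-1.0, -0.5, 0.2, 0.8, -0.3]))
        assert len(train) == 1
        assert train.times[0] == pytest.approx(1 + 0.5 / 0.7)

    def test_square_wave_counts_every_wide_crossing(self):
        v = np.tile([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0], 5)
        assert len(detect_spikes(_trace_from_v(v))) == 5

    def test_debounce_suppresses_rapid_recrossings(self):
        # second upward crossing lands 1.83 dt after the first: debounced
        v = np.array([-1.0, 1.0, -0.5, 1.0, -1.0])
        assert len(detect_spikes(_trace_from_v(v))) == 1
        # with the debounce disabled both crossings count
        assert len(detect_spikes(_trace_from_v(v), min_separation=0.0)) == 2

    def test_upsampled_trace_agrees_exactly(self):
        """Linear 2x upsampling preserves the spike count."""
        rng = np.random.default_rng(5)
        v = np.cumsum(rng.normal(size=400))
        v -= np.linspace(0, v[-1], len(v))  # bridge back to 0: many crossings
        coarse = detect_spikes(_trace_from_v(v, dt=1.0), min_separation=0.0)
        t2 = np.arange(0, len(v) - 1 + 0.5, 0.5)
        v2 = np.interp(t2, np.arange(len(v)), v)
        fine = detect_spikes(_trace_from_v(v2, dt=0.5), min_separation=0.0)
        assert len(coarse) == len(fine)


class TestIsiStatistics:
    def test_constant_isis_give_zero_cv_and_lv(self):
        # exactly equal intervals: both statistics are exactly zero
        isis = ISISequence((0.125,) * 10)
        assert cv_stat(isis) == 0.0
        assert lv_stat(isis) == 0.0
        # and via a spike train with exactly representable times
        train = SpikeTrain(tuple(float(i) for i in range(11)))
        assert cv_stat(train.isis()) == 0.0
        assert lv_stat(train.isis()) == 0.0

    def test_two_interval_hand_values(self):
        isis = ISISequence((1.0, 2.0))
        assert cv_stat(isis) == pytest.approx(np.sqrt(0.5) / 1.5)
        assert lv_stat(isis) == pytest.approx(1.0 / 3.0)

    def test_single_interval_is_undefined(self):
        with pytest.raises(StatisticError):
            cv_stat(ISISequence((1.0,)))
        with pytest.raises(StatisticError):
            lv_stat(ISISequence((1.0,)))

    def test_poisson_train_calibrates_both_statistics_to_one(self):
        """10^5 exponential intervals: CV and LV in [0.98, 1.02]."""
        train = poisson_spike_train(rate=10.0, n_intervals=100_000, seed=12345)
        isis = train.isis()
        assert 0.98 <= cv_stat(isis) <= 1.02
        assert 0.98 <= lv_stat(isis) <= 1.02

    def test_time_rescaling_invariance(self):
        """CV and LV are dimensionless: scaling all ISIs changes neither."""
        rng = np.random.default_rng(9)
        base = tuple(rng.gamma(2.0, 0.05, size=500))
        for scale in (0.001, 3.7):
            scaled = ISISequence(tuple(t * scale for t in base))
            assert cv_stat(scaled) == pytest.approx(cv_stat(ISISequence(base)))
            assert lv_stat(scaled) == pytest.approx(lv_stat(ISISequence(base)))


class TestPoissonFixture:
    def test_interval_count(self):
        assert len(poisson_spike_train(5.0, 1, seed=0)) == 2

    def test_seed_reproducibility(self):
        a = poisson_spike_train(5.0, 100, seed=42)
        b = poisson_spike_train(5.0, 100, seed=42)
        assert a.times == b.times

    def test_mean_interval_matches_rate(self):
        train = poisson_spike_train(10.0, 100_000, seed=7)
        assert np.mean(np.diff(train.times)) == pytest.approx(0.1, abs=0.002)


class TestMse:
    def test_identical_lists_give_zero(self):
        assert mse_points([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_value(self):
        assert mse_points([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mse_points(a, b) == pytest.approx(mse_points(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_points([1.0], [1.0, 2.0])


class TestSegmentBursts:
    def test_single_burst_when_no_gap_exceeds_threshold(self):
        train = SpikeTrain(tuple(np.arange(6) * 0.01))
        b = segment_bursts(train, gap_threshold=0.1)
        assert b.spikes_per_burst == (6,)
        assert b.interburst_intervals == ()

    def test_hand_segmentation(self):
        # ISIs [.01,.01,.01,.5,.01,.01] with threshold 0.1 -> bursts 4 and 3
        times = (0.0, 0.01, 0.02, 0.03, 0.53, 0.54, 0.55)
        b = segment_bursts(SpikeTrain(times), gap_threshold=0.1)
        assert b.spikes_per_burst == (4, 3)
        assert b.interburst_intervals == pytest.approx((0.5,))

    def test_spike_conservation(self):
        rng = np.random.default_rng(2)
        times = tuple(np.cumsum(rng.exponential(0.05, size=200)))
        b = segment_bursts(SpikeTrain(times), gap_threshold=0.08)
        assert sum(b.spikes_per_burst) == len(times)

    def test_default_threshold_is_five_median_isis(self):
        times = (0.0, 0.01, 0.02, 0.03, 1.0, 1.01, 1.02, 1.03)
        b = segment_bursts(SpikeTrain(times))
        assert b.gap_threshold == pytest.approx(5 * 0.01)
        assert b.spikes_per_burst == (4, 4)


class TestResponseCurves:
    def test_zero_pulse_prc_is_flat(self, toy_oscillator):
        """No perturbation, no phase shift (to spike-timing resolution)."""
        prc = compute_prc(toy_oscillator, I_base=0.4, pulse_amp=0.0,
                          pulse_dur=0.002, n_phases=8, t_settle=1.0)
        tol = 2 * toy_oscillator.dt / prc.period
        assert max(abs(s) for s in prc.shifts) <= tol

    def test_prc_matches_independent_resimulation(self, toy_oscillator):
        """Delta at one phase equals an oracle run with the pulse hard-coded."""
        from pqnsim.analysis import detect_spikes

        p = toy_oscillator
        prc = compute_prc(p, I_base=0.4, pulse_amp=0.15, pulse_dur=0.002,
                          n_phases=2, t_settle=1.0)
        # oracle: rebuild the same protocol for theta=0.5 by hand
        base = StimulusProgram.constant(0.4)
        tr = simulate(p, base, t_max=1.0)
        train = [t for t in detect_spikes(tr).times if t >= 0.2 * 1.0]
        T = float(np.mean(np.diff(train[-11:])))
        t_s = train[-3]
        stim = base.overlay(StimulusProgram.pulse(t_s + 0.5 * T, 0.002, 0.15))
        pert = simulate(p, stim, t_max=1.0 + 3 * T)
        after = [t for t in detect_spikes(pert).times if t > t_s + p.dt]
        delta_oracle = (T - (after[0] - t_s)) / T
        assert prc.shifts[1] == pytest.approx(delta_oracle, abs=1e-9)

    def test_no_oscillation_raises(self, toy2var_eq):
        with pytest.raises(StatisticError):
            compute_prc(toy2var_eq, I_base=0.0, pulse_amp=0.1, pulse_dur=0.002,
                        n_phases=4, t_settle=0.5)

    def test_zero_amplitude_pulse_leaves_peak_at_rest(self, toy_oscillator):
        peaks = graded_response_curve(toy_oscillator, [0.0], pulse_t0=0.02,
                                      pulse_dur=0.002, t_max=0.1)
        from pqnsim.dynamics import find_equilibrium

        rest = find_equilibrium(toy_oscillator)
        assert peaks[0] == pytest.approx(rest.v, abs=1e-9)

    def test_duplicated_amplitudes_give_duplicated_peaks(self, toy_oscillator):
        peaks = graded_response_curve(toy_oscillator, [0.3, 0.3], pulse_t0=0.02,
                                      pulse_dur=0.002, t_max=0.1)
        assert peaks[0] == peaks[1]

    def test_subrheobase_step_yields_empty_isi_list(self, toy_oscillator):
        out = isi_transition_experiment(toy_oscillator, [0.01], t_on=0.02, t_max=0.3)
        assert out[0.01] == []
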