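import numpy as np
import pytest

from purkinje_ca.analysis import (
    ap_metrics,
    ap_metrics_all,
    biphasic_transient,
    ca_metrics,
    detect_events,
    detect_sparks_iterative,
    detect_sparks_simple,
    spark_frequency,
)
from purkinje_ca.fixtures import alpha_transient, flux_with_sparks, voltage_with_events


def square_ap(duration_ms=50.0, dt=0.1, baseline=-80.0, peak=20.0, total=400.0):
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, baseline)
    up = (t >= 50.0) & (t < 50.0 + 0.5)
    v[up] = baseline + (peak - baseline) * (t[up] - 50.0) / 0.5
    high = (t >= 50.5) & (t < 50.5 + duration_ms)
    v[high] = peak
    return t, v


class TestApMetrics:
    def test_square_pulse_apd90(self):
        t, v = square_ap(duration_ms=50.0)
        m = ap_metrics(v, t)
        # plateau holds until 50 ms after the upstroke, then drops through
        # every repolarization level at once
        assert m.apd90 == pytest.approx(50.0, abs=0.5)
        assert m.apd50 == pytest.approx(50.0, abs=0.5)
        assert m.amplitude == pytest.approx(100.0, abs=1.0)

    def test_linear_ramp_dvdt(self):
        dt = 0.1
        t = np.arange(0.0, 300.0, dt)
        v = np.full_like(t, -80.0)
        ramp = (t >= 100.0) & (t < 112.0)
        v[ramp] = -80.0 + 10.0 * (t[ramp] - 100.0)  # 10 mV/ms
        v[t >= 112.0] = -80.0
        m = ap_metrics(v, t)
        assert m.dvdt_max == pytest.approx(10.0, rel=0.01)

    def test_apd_ordering(self):
        from purkinje_ca import Model, simulate

        tr, _ = simulate(Model(), 900.0, np.array([50.0]), seed=2)
        for m in ap_metrics_all(tr.v, tr.t):
            assert m.apd50 <= m.apd70 <= m.apd90

    def test_no_ap_raises(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(ValueError):
            ap_metrics(np.full_like(t, -80.0), t)


class TestCaMetrics:
    def test_alpha_function_recovery(self):
        t, ca, truth = alpha_transient(t0=50.0, amplitude=1.3, tau=25.0)
        m = ca_metrics(ca, t, stim_time=50.0)
        assert m.peak_amplitude == pytest.approx(truth["peak_amplitude"], rel=0.01)
        assert m.time_to_peak == pytest.approx(truth["time_to_peak"], rel=0.01)

    def test_flat_trace_zero_amplitude(self):
        t = np.arange(0.0, 500.0, 0.1)
        m = ca_metrics(np.full_like(t, 0.2), t, stim_time=10.0)
        assert m.peak_amplitude == 0.0

    def test_exponential_decay_tau(self):
        t = np.arange(0.0, 2000.0, 0.1)
        tau = 80.0
        ca = 0.1 + 1.0 * np.where(t >= 100.0, np.exp(-(t - 100.0) / tau), 0.0)
        ca[t < 100.0] = 0.1
        m = ca_metrics(ca, t, stim_time=99.0)
        assert m.decay_tau == pytest.approx(tau, rel=0.05)
        # 90% recovery of a monoexponential takes ln(10)·tau
        assert m.decay_time == pytest.approx(np.log(10.0) * tau, rel=0.02)


class TestEventDetection:
    def test_flat_trace_no_events(self):
        t = np.arange(0.0, 5000.0, 0.1)
        rec = detect_events(np.full_like(t, -80.0), t, (0.0, 5000.0))
        assert rec.n_dads == 0 and rec.n_triggered == 0

    def test_fixture_round_trip(self):
        t, v, truth = voltage_with_events(
            dad_times=(1000.0, 2500.0), ap_times=(4000.0,), dad_amplitude=5.0
        )
        rec = detect_events(v, t, (0.0, 5000.0))
        assert rec.n_dads == 2
        assert rec.n_triggered == 1
        for (found, _), expected in zip(sorted(rec.dads), truth["dads"]):
            assert found == pytest.approx(expected[0], abs=5.0)

    def test_subthreshold_bump_ignored(self):
        t, v, _ = voltage_with_events(dad_times=(1000.0,), dad_amplitude=1.0, ap_times=())
        rec = detect_events(v, t, (0.0, 5000.0))
        assert rec.n_dads == 0

    def test_paced_aps_excluded(self):
        t, v, _ = voltage_with_events(dad_times=(), ap_times=(2000.0,))
        rec = detect_events(v, t, (0.0, 5000.0), stim_times=np.array([2000.0]))
        assert rec.n_triggered == 0

    def test_classification_exclusive(self):
        t, v, _ = voltage_with_events(dad_times=(1000.0,), ap_times=(3000.0,))
        rec = detect_events(v, t, (0.0, 5000.0))
        assert rec.n_dads == 1 and rec.n_triggered == 1


class TestSimpleSparkDetector:
    def test_three_pulses_found(self):
        t, flux, truth = flux_with_sparks()
        events = detect_sparks_simple(flux, t)
        assert len(events) == 3
        for ev, (disc, t0, w) in zip(events, truth["sparks"]):
            assert ev.disc == disc
            assert ev.t_start == pytest.approx(t0, abs=0.2)
            assert ev.duration >= 1.0

    def test_short_pulse_rejected(self):
        t, flux, _ = flux_with_sparks(events=[(2, 500.0, 0.5)])
        assert detect_sparks_simple(flux, t) == []

    def test_zero_flux_no_events(self):
        t = np.arange(0.0, 1000.0, 0.1)
        assert detect_sparks_simple(np.zeros((len(t), 10)), t) == []


class TestIterativeSparkDetector:
    @pytest.mark.parametrize("k", range(0, 11))
    def test_exact_recovery_noise_free(self, k):
        events = [(i % 10, 200.0 + 150.0 * i, 2.0) for i in range(k)]
        t, flux, _ = flux_with_sparks(duration=2200.0, events=events)
        found = detect_sparks_iterative(flux, t)
        assert len(found) == k

    def test_noise_matches_brute_force_oracle(self, rng):
        """On pure noise the fast detector equals an independent
        straightforward re-implementation of the two-pass 2-SD rule."""
        t = np.arange(0.0, 1000.0, 0.1)
        flux = rng.normal(0.0, 0.3, size=(len(t), 2))

        def oracle(f):
            d = np.diff(f)
            a = np.abs(d)
            flag1 = a > a.mean() + 2 * a.std()
            rest = a[~flag1]
            thr = rest.mean() + 2 * rest.std()
            flags = flag1 | (a > thr)
            events = []
            start = None
            for i in range(len(d)):
                if flags[i] and d[i] > 0:
                    if start is None or f[i] <= f[start] + thr:
                        start = i
                elif flags[i] and d[i] < 0 and start is not None:
                    if f[i + 1] >= f[start] + thr:
                        continue  # still elevated: not the event end
                    if (i - start) * 0.1 >= 1.0 and f[start + 1 : i + 1].min() >= f[start] + thr:
                        events.append((start, i))
                    start = None
            if start is not None and (len(d) - 1 - start) * 0.1 >= 1.0:
                if f[start + 1 :].min() >= f[start] + thr:
                    events.append((start, len(d) - 1))
            return events

        expected = sum(len(oracle(flux[:, j])) for j in range(2))
        found = detect_sparks_iterative(flux, t)
        assert len(found) == expected

    def test_noise_plus_pulses(self):
        t = np.arange(0.0, 2000.0, 0.1)
        flux = np.random.default_rng(1234).normal(0.0, 0.05, size=(len(t), 1))
        injected = [300.0, 600.0, 1000.0, 1400.0, 1800.0]
        for t0 in injected:
            flux[(t >= t0) & (t < t0 + 2.0), 0] += 5.0
        found = detect_sparks_iterative(flux, t)
        assert len(found) == 5

    def test_deterministic(self, rng):
        t, flux, _ = flux_with_sparks(noise_sd=0.1, seed=4)
        a = detect_sparks_iterative(flux, t)
        b = detect_sparks_iterative(flux, t)
        assert a == b

    def test_short_window_rejected(self):
        t = np.arange(0.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            detect_sparks_iterative(np.zeros((len(t), 1)), t)


class TestSparkFrequency:
    def test_normalization(self):
        events = [object()] * 18
        assert spark_frequency(events, 129.0, 15.0) == pytest.approx(18 / (1.29 * 15.0))

    def test_zero_events(self):
        assert spark_frequency([], 129.0, 15.0) == 0.0

    def test_window_scaling(self):
        events = [object()] * 10
        f1 = spark_frequency(events, 129.0, 10.0)
        f2 = spark_frequency(events, 129.0, 20.0)
        assert f1 == pytest.approx(2.0 * f2)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            spark_frequency([], 129.0, 0.0)


class TestBiphasic:
    def test_synthetic_biphasic_shape(self):
        t = np.arange(0.0, 300.0, 0.1)
        sl = (
            1.0 * np.exp(-0.5 * ((t - 30.0) / 8.0) ** 2)
            + 1.4 * np.exp(-0.5 * ((t - 90.0) / 20.0) ** 2)
        )
        sr = 3.0 * np.exp(-0.5 * ((t - 70.0) / 15.0) ** 2)
        out = biphasic_transient(sl, sr, t, 0.0, 300.0)
        assert out["biphasic"]
        assert out["sr_before_second_sl_peak"]
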