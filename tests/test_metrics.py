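"""Activity metrics: rates, CoV ISI, sliding counts, oscillation detection
(against a brute-force Gaussian-bump oracle), phase occupancy, and the
neuron-connectivity index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikelesion as sl
from spikelesion.dynamics import SpikeRaster
from spikelesion.metrics import detect_oscillations, phase_occupancy, windowed_counts

from conftest import make_topology


def raster_from(times, ids, duration, n_neurons):
    order = np.argsort(times, kind="stable")
    return SpikeRaster(np.asarray(times, dtype=float)[order],
                       np.asarray(ids, dtype=np.int64)[order],
                       float(duration), np.arange(n_neurons, dtype=np.int64))


class TestFiringRate:
    def test_one_hertz_train(self):
        r = raster_from(np.arange(300) * 1000.0, np.zeros(300), 300_000.0, 2)
        rates, mean = sl.firing_rate(r)
        assert rates[0] == pytest.approx(1.0)
        assert rates[1] == 0.0                    # silent neuron included
        assert mean == pytest.approx(0.5)

    def test_empty_window_rejected(self):
        r = raster_from([], [], 1000.0, 1)
        with pytest.raises(ValueError):
            sl.firing_rate(r, (5.0, 5.0))


class TestCovIsi:
    def test_periodic_train_is_zero(self):
        r = raster_from(np.arange(50) * 20.0, np.zeros(50), 1000.0, 1)
        cov, mean = sl.cov_isi(r)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_near_one(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.exponential(10.0, 20_000))
        r = raster_from(t, np.zeros(len(t)), t[-1] + 1, 1)
        _, mean = sl.cov_isi(r)
        assert mean == pytest.approx(1.0, abs=0.05)

    def test_sparse_neurons_skipped(self):
        r = raster_from([10.0, 20.0, 30.0, 500.0], [0, 0, 0, 1], 1000.0, 3)
        cov, mean = sl.cov_isi(r)
        assert np.isnan(cov[1]) and np.isnan(cov[2])
        assert mean == cov[0]

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 50.0))
    def test_time_scale_invariance(self, scale):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 1000.0, 40))
        base = sl.cov_isi(raster_from(t, np.zeros(40), 1001.0, 1))[1]
        scaled = sl.cov_isi(raster_from(t * scale, np.zeros(40), 1001.0 * scale, 1))[1]
        assert scaled == pytest.approx(base, rel=1e-9)


class TestWindowedCounts:
    def test_empty_raster_zero_trace(self):
        trace, _ = windowed_counts(raster_from([], [], 100.0, 1))
        assert len(trace) > 0 and np.all(trace == 0)

    def test_simultaneous_spikes_counted_together(self):
        r = raster_from([50.0] * 7, np.arange(7), 100.0, 7)
        trace, centers = windowed_counts(r)
        assert trace.max() == 7
        covering = (centers > 45.0) & (centers < 55.0)
        assert np.all(trace[covering] == 7)

    def test_partition_identity(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 1000.0, 500)
        r = raster_from(t, np.zeros(500), 1000.0, 1)
        trace, _ = windowed_counts(r, window_ms=10.0, stride_ms=10.0)
        assert trace.sum() == 500

    def test_window_below_stride_rejected(self):
        with pytest.raises(ValueError):
            windowed_counts(raster_from([], [], 100.0, 1), window_ms=1.0, stride_ms=5.0)


def gaussian_bump_trace(peaks, amps, sigmas, duration_ms, stride_ms=0.2):
    t = np.arange(0, duration_ms, stride_ms)
    trace = np.zeros_like(t)
    for p, a, s in zip(peaks, amps, sigmas):
        trace += a * np.exp(-0.5 * ((t - p) / s) ** 2)
    return trace, t


class TestOscillationDetection:
    def test_flat_trace_yields_nothing(self):
        events, freq = detect_oscillations(np.full(5000, 3.0), 0.2, 100)
        assert events == [] and freq == 0.0

    def test_gaussian_bump_oracle(self):
        # known peak times and widths; FWHM of a Gaussian = 2.355 sigma
        peaks = [200.0, 500.0, 800.0]
        sigmas = [8.0, 12.0, 6.0]
        amps = [40.0, 60.0, 30.0]
        trace, t = gaussian_bump_trace(peaks, amps, sigmas, 1000.0)
        events, freq = detect_oscillations(trace, 0.2, 1000, t_centers=t)
        assert len(events) == 3
        for ev, p, a, s in zip(events, peaks, amps, sigmas):
            assert abs(ev.t_peak_ms - p) <= 0.2           # within one stride
            assert ev.magnitude == pytest.approx(a, rel=0.01)
            assert ev.fwhm_ms == pytest.approx(2.3548 * s, rel=0.10)
            lo, hi = ev.interval
            assert hi - lo == pytest.approx(1.4 * ev.fwhm_ms)
        assert freq == pytest.approx(3.0, rel=0.01)

    def test_synchronized_volley_raster(self):
        # 10 volleys per second, 100 neurons per volley
        times, ids = [], []
        for k in range(10):
            t = 50.0 + 100.0 * k
            times.extend([t + 0.001 * j for j in range(100)])
            ids.extend(range(100))
        r = raster_from(times, ids, 1000.0, 100)
        trace, centers = windowed_counts(r)
        events, freq = detect_oscillations(trace, 0.2, 100, t_centers=centers)
        assert freq == pytest.approx(10.0, abs=0.5)
        assert events[0].magnitude == pytest.approx(100.0)
        assert events[0].magnitude_frac == pytest.approx(1.0)

    def test_prominence_threshold_scales_with_network(self):
        trace, t = gaussian_bump_trace([500.0], [8.0], [10.0], 1000.0)
        small, _ = detect_oscillations(trace, 0.2, 100, t_centers=t)
        large, _ = detect_oscillations(trace, 0.2, 5000, t_centers=t)
        assert len(small) == 1 and len(large) == 0   # 8 spikes < 1 % of 5000


class TestPhaseOccupancy:
    def _event(self, t_peak, fwhm):
        half = 1.4 * fwhm / 2
        return sl.OscillationEvent(t_peak, 10.0, 0.1, fwhm,
                                   (t_peak - half, t_peak + half))

    def test_peak_concentration(self):
        r = raster_from([100.0] * 20, np.arange(20), 200.0, 20)
        occ = phase_occupancy(r, [self._event(100.0, 10.0)], n_bins=5)
        assert occ["all"][2] == 1.0

    def test_uniform_spikes_flat_occupancy(self):
        ev = self._event(100.0, 50.0)
        lo, hi = ev.interval
        t = np.linspace(lo, hi - 1e-9, 7000)
        r = raster_from(t, np.zeros(7000), 200.0, 1)
        occ = phase_occupancy(r, [ev], n_bins=10)
        assert occ["all"] == pytest.approx(np.full(10, 0.1), abs=0.01)

    def test_outside_spikes_excluded_and_groups_normalized(self):
        ev = self._event(100.0, 10.0)
        r = raster_from([100.0, 100.0, 190.0], [0, 1, 0], 200.0, 2)
        occ = phase_occupancy(r, [ev], n_bins=5,
                              groups={"a": np.array([0]), "b": np.array([1])})
        assert occ["a"].sum() == pytest.approx(1.0)
        assert occ["b"].sum() == pytest.approx(1.0)
        assert occ["a"][2] == 1.0  # the 190 ms spike fell outside the interval

    def test_requires_events(self):
        r = raster_from([], [], 100.0, 1)
        with pytest.raises(ValueError):
            phase_occupancy(r, [], n_bins=5)


class TestConnectivityIndex:
    def test_boundary_and_symmetric_cases(self):
        # 0 -> 1 -> 2: neuron 0 sends only (-1), 2 receives only (+1),
        # 1 has equal in/out strength (0)
        topo = make_topology("EEE", [(0, 1, 2.0, 1.0), (1, 2, 2.0, 1.0)])
        idx = sl.connectivity_index(topo)
        assert idx[0] == -1.0 and idx[2] == 1.0 and idx[1] == 0.0

    def test_isolated_neuron_undefined(self):
        topo = make_topology("EE", [])
        idx = sl.connectivity_index(topo)
        assert np.isnan(idx).all()

    def test_inhibitory_strength_uses_absolute_weight(self):
        topo = make_topology("IE", [(0, 1, -14.0, 1.0), (1, 0, 7.0, 1.0)])
        idx = sl.connectivity_index(topo)
        assert idx[0] == pytest.approx((7 - 14) / 21)
        assert idx[1] == pytest.approx((14 - 7) / 21)
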