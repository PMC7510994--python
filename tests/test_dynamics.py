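"""Integration semantics: Euler step, synapse decay, desensitization,
background drive, delays and reproducibility of full network runs."""

import math

import numpy as np
import pytest

import spikelesion as sl
from spikelesion.dynamics import (
    decay_synapses,
    deliver_spike,
    izhikevich_step,
    update_desensitization,
)

from conftest import make_topology, forced_spike_sim

RS = (0.02, 0.2, -65.0, 8.0)


class TestIzhikevichStep:
    def test_threshold_reset(self):
        v, u, spiked = izhikevich_step(30.0, 0.0, 0.0, *RS)
        assert spiked and v == -65.0
        # u jumps by d on top of the Euler-updated recovery value
        u_euler = 0.0 + 0.2 * 0.02 * (0.2 * 30.0 - 0.0)
        assert u == pytest.approx(u_euler + 8.0)

    def test_hand_evaluated_euler_step(self):
        # 0.04*65^2 = 169; RHS = 169 - 325 + 140 + 13 + 10 = 7 -> dv = 1.4
        v, u, spiked = izhikevich_step(-65.0, -13.0, 10.0, *RS)
        assert not spiked
        assert v == pytest.approx(-63.6)
        assert u == pytest.approx(-13.0)

    def test_resting_fixed_point_is_stationary(self):
        # v* solves 0.04 v^2 + 5 v + 140 - 0.2 v = 0 (u on its nullcline)
        vstar = (-4.8 - math.sqrt(4.8**2 - 4 * 0.04 * 140)) / (2 * 0.04)
        ustar = 0.2 * vstar
        v, u, spiked = izhikevich_step(vstar, ustar, 0.0, *RS)
        assert not spiked
        assert abs(v - vstar) < 1e-9 and abs(u - ustar) < 1e-9

    def test_nan_input_raises(self):
        with pytest.raises(sl.NumericStateError):
            izhikevich_step(float("nan"), 0.0, 0.0, *RS)


class TestSynapses:
    def test_decay_closed_form(self):
        ge, gi = decay_synapses(np.array(1.0), np.array(-1.0), dt=5.0, tau=5.0)
        assert ge == pytest.approx(math.exp(-1))
        assert gi == pytest.approx(-math.exp(-1))

    def test_zero_is_absorbing(self):
        ge, gi = decay_synapses(np.array(0.0), np.array(0.0))
        assert ge == 0 and gi == 0

    def test_exponent_additivity_over_steps(self):
        g = np.array(1.0)
        for _ in range(25):
            g, _ = decay_synapses(g, np.array(0.0), dt=0.2, tau=5.0)
        assert g == pytest.approx(math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("weight,s,dexc,dinh", [
        (4.0, 1.0, 4.0, 0.0),
        (-14.0, 1.0, 0.0, -14.0),
        (4.0, 0.6, 2.4, 0.0),
    ])
    def test_delivery_scaled_by_desensitization(self, weight, s, dexc, dinh):
        ge, gi = np.zeros(2), np.zeros(2)
        deliver_spike(ge, gi, 1, weight, s)
        assert ge[1] == pytest.approx(dexc) and gi[1] == pytest.approx(dinh)


class TestDesensitization:
    def test_spike_sets_floor(self):
        assert update_desensitization(1.0, True) == 0.6

    def test_full_recovery_is_fixed_point(self):
        assert update_desensitization(1.0, False) == pytest.approx(1.0)

    def test_closed_form_after_150ms(self):
        s = 0.6
        for _ in range(750):  # 150 ms at 0.2 ms
            s = update_desensitization(s, False)
        assert s == pytest.approx(1 - 0.4 * math.exp(-1), rel=1e-9)


class TestBackground:
    def test_zero_rate_gives_no_events(self):
        nrn, t, amp = sl.background_events(100, 1000.0, sl.StimulusModel(rate_hz=0.0), seed=1)
        assert len(nrn) == 0

    def test_poisson_count_and_gamma_mean(self):
        stim = sl.StimulusModel()
        nrn, t, amp = sl.background_events(1000, 60_000.0, stim, seed=2)
        lam = 60_000.0
        assert abs(len(nrn) - lam) <= 3 * math.sqrt(lam)
        # raw gamma amplitudes (before gain) have mean k*theta = 1
        assert np.mean(amp / stim.amplitude_gain) == pytest.approx(1.0, abs=0.05)
        assert np.all(np.diff(t) >= 0)


class TestRunSimulation:
    def test_zero_duration_noop(self):
        topo = make_topology("EE", [(0, 1, 2.0, 1.0)])
        state = sl.init_state(topo)
        v0 = state.v.copy()
        raster, state = sl.run_simulation(topo, state, 0.0, seed=1)
        assert raster.n_spikes == 0 and np.array_equal(state.v, v0)

    def test_isolated_neuron_without_drive_is_silent(self):
        topo = make_topology("E", [])
        state = sl.init_state(topo)
        raster, _ = sl.run_simulation(
            topo, state, 1000.0, sl.StimulusModel(rate_hz=0.0), seed=1)
        assert raster.n_spikes == 0

    def test_single_background_event_fires_resting_neuron(self):
        # amplitude_gain * mean gamma draw, delivered on the decaying drive
        topo = make_topology("E", [])
        stim = sl.StimulusModel()
        state = sl.init_state(topo)
        raster, _ = sl.run_simulation(
            topo, state, 20.0, sl.StimulusModel(rate_hz=0.0), seed=1,
            extra_events=(np.array([0]), np.array([1.0]),
                          np.array([stim.amplitude_gain * 1.0])))
        assert raster.n_spikes >= 1

    @pytest.mark.parametrize("delay_ms", [0.2, 2.0, 8.0])
    def test_event_ordering_two_neuron_chain(self, delay_ms):
        # the post neuron's drive changes exactly `delay` after the pre spike
        topo = make_topology("EE", [(0, 1, 3.0, delay_ms)])
        sim = sl.SimConfig()
        stim = sl.StimulusModel(rate_hz=0.0, mode="impulse")
        state = sl.init_state(topo, sim)
        spike_t = None
        drive_t = None
        force = (np.array([0]), np.array([5.0]), np.array([2000.0]))
        for step in range(100):
            raster, state = sl.run_simulation(
                topo, state, 0.2, stim, sim, seed=1,
                extra_events=(force[0], force[1] - step * 0.2, force[2]))
            if raster.n_spikes and spike_t is None and raster.ids[0] == 0:
                spike_t = step * 0.2
            if state.g_exc[1] > 0 and drive_t is None:
                drive_t = step * 0.2
        assert spike_t is not None and drive_t is not None
        assert drive_t - spike_t == pytest.approx(delay_ms)

    def test_reproducibility_identical_config(self):
        cfg = sl.NetworkConfig(n=80, mean_degree=20)
        rasters = []
        for _ in range(2):
            topo = sl.build_network(cfg, seed=3)
            state = sl.init_state(topo)
            r, _ = sl.run_simulation(topo, state, 2000.0, seed=7)
            rasters.append(r)
        assert np.array_equal(rasters[0].times_ms, rasters[1].times_ms)
        assert np.array_equal(rasters[0].ids, rasters[1].ids)

    def test_membrane_below_threshold_after_every_step(self):
        topo = make_topology("EEE", [(0, 1, 4.0, 0.2), (1, 2, 4.0, 0.2)])
        sim = sl.SimConfig()
        state = sl.init_state(topo, sim)
        for step in range(200):
            _, state = sl.run_simulation(
                topo, state, 0.2, sl.StimulusModel(rate_hz=5000.0), sim, seed=step)
            assert np.all(state.v < sim.spike_threshold_mv)
            assert np.all(state.g_exc >= 0) and np.all(state.g_inh <= 0)
            assert np.all((state.s > 0) & (state.s <= 1))
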