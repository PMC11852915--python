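"""Neuron/synapse unit dynamics, network assembly, attack, simulation loop."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comsnn.dynamics import (
    AttackSpec,
    ExternalDrive,
    PlasticityParams,
    SimConfig,
    apply_attack,
    apply_spike_plasticity,
    apply_weight_decay,
    build_network,
    gating_drive,
    simulate,
    step_gating,
    step_neuron,
    stdp_window_ex,
    stdp_window_in,
    synaptic_current,
)
from comsnn.errors import ConfigurationError

from conftest import make_isolated_network, make_two_neuron_network

P = PlasticityParams()


class TestNeuron:
    def test_resting_fixed_point(self):
        # 0.04 v^2 + 5v + 140 - u = 0 and bv = u at (v, u) = (-70, -14)
        v, u, fired = step_neuron(-70.0, -14.0, 0.02, 0.2, -65.0, 8.0, 0.0, 0.1)
        assert v == pytest.approx(-70.0, abs=1e-12)
        assert u == pytest.approx(-14.0, abs=1e-12)
        assert not fired

    def test_reset_branch(self):
        v, u, fired = step_neuron(31.0, -14.0, 0.02, 0.2, -65.0, 8.0, 0.0, 0.1)
        assert fired
        assert v == -65.0
        assert u == -6.0

    def test_post_step_reset_invariant(self):
        # from just below the cut-off a strong current crosses it within one
        # step and the completed step leaves v at the reset value
        v, u, fired = step_neuron(29.0, -14.0, 0.02, 0.2, -65.0, 8.0, 50.0, 0.1)
        assert fired and v == -65.0

    def test_tonic_spiking_matches_high_resolution_reference(self):
        # independent reference integration at dt = 0.01 ms
        def reference_spike_count(dt, duration=1000.0, i_ext=10.0):
            v, u = -65.0, -13.0
            count = 0
            for _ in range(int(round(duration / dt))):
                dv = 0.04 * v * v + 5 * v + 140 - u + i_ext
                du = 0.02 * (0.2 * v - u)
                v, u = v + dt * dv, u + dt * du
                if v >= 30.0:
                    v, u = -65.0, u + 8.0
                    count += 1
            return count

    # oracle at dt=0.01; implementation via simulate at dt=0.1
        oracle = reference_spike_count(0.01)
        net = make_isolated_network(1)
        cfg = SimConfig(
            duration=1000.0,
            drive=ExternalDrive(kind="constant", amplitude_ex=10.0, amplitude_in=10.0),
            seed=0,
        )
        res = simulate(net, cfg)
        count = len(res.spike_times[0])
        assert count >= 2
        assert abs(count - oracle) <= max(1, 0.02 * oracle)

    def test_dt_halving_changes_rate_by_under_two_percent(self):
        net = make_isolated_network(1)
        counts = {}
        for dt in (0.1, 0.05):
            cfg = SimConfig(
                duration=1000.0, dt=dt,
                drive=ExternalDrive(kind="constant", amplitude_ex=10.0,
                                    amplitude_in=10.0),
                seed=0,
            )
            counts[dt] = len(simulate(net, cfg).spike_times[0])
        assert abs(counts[0.1] - counts[0.05]) <= 0.02 * counts[0.05] + 1e-9


class TestSynapseUnits:
    def test_gating_drive_logistic(self):
        assert gating_drive(0.0) == pytest.approx(0.5)
        assert gating_drive(500.0) == pytest.approx(1.0)
        assert gating_drive(-500.0) == pytest.approx(0.0)
        assert gating_drive(30.0) == pytest.approx(1 / (1 + math.exp(-30)), rel=1e-12)

    def test_gating_steady_states(self):
        # dr/dt = 0 at r* = alpha H / (alpha H + beta)
        for alpha, beta, expected in ((2.0, 1.0, 2 / 3), (0.9, 0.1, 0.9)):
            r = 0.0
            for _ in range(20000):
                r = step_gating(r, 1.0, alpha, beta, 0.1)
            assert r == pytest.approx(expected, abs=1e-6)

    def test_gating_absorbing_at_zero_drive(self):
        assert step_gating(0.0, 0.0, 2.0, 1.0, 0.1) == 0.0

    def test_synaptic_current_cases(self):
        assert synaptic_current(0.015, 0.0, 0.0, -70.0) == 0.0
        assert synaptic_current(0.015, 1.0, 0.0, -70.0) == pytest.approx(1.05)
        assert synaptic_current(0.015, 1.0, -70.0, -70.0) == 0.0

    def test_stdp_window_boundaries(self):
        assert stdp_window_ex(-1e-12) == pytest.approx(0.1)
        assert stdp_window_ex(0.0) == pytest.approx(-0.105)
        assert stdp_window_in(-1e-12) == pytest.approx(-0.02)
        assert stdp_window_in(0.0) == pytest.approx(0.03)

    def test_stdp_window_exponential_decay(self):
        assert stdp_window_ex(-20.0) == pytest.approx(0.1 * math.exp(-1), rel=1e-12)
        assert stdp_window_in(20.0) == pytest.approx(0.03 * math.exp(-1), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dt=st.floats(-200, 200))
    def test_stdp_sign_structure(self, dt):
        # pre-before-post (dt < 0) strengthens excitatory, weakens inhibitory
        if dt < 0:
            assert stdp_window_ex(dt) > 0
            assert stdp_window_in(dt) < 0
        else:
            assert stdp_window_ex(dt) < 0
            assert stdp_window_in(dt) > 0

    def test_weight_decay_closed_form(self):
        assert apply_weight_decay(0.015, 3.0, 3.0) == pytest.approx(
            0.015 * math.exp(-1), rel=1e-12
        )
        assert apply_weight_decay(0.0, 3.0, 0.1) == 0.0
        assert apply_weight_decay(1e-9, 5.0, 0.1) > 0

    def test_spike_plasticity_clamps(self):
        # potentiation at saturation stays at the ceiling
        g = apply_spike_plasticity(P.g_max, -1e-9, True, P)
        assert g == P.g_max
        # depression below zero clamps at zero
        g = apply_spike_plasticity(0.0001, 0.0, True, P)
        assert g == 0.0
        # plain arithmetic case
        g = apply_spike_plasticity(0.010, -1e-12, True, P)
        assert g == pytest.approx(0.010 + 0.1 * 0.015)


class TestBuildNetwork:
    def test_counts_and_delays(self, tiny_graph, tiny_config):
        net = build_network(tiny_graph, tiny_config, P, seed=0)
        assert net.n_synapses == 2 * tiny_graph.n_edges
        assert int(net.is_inhibitory.sum()) == round(0.2 * tiny_graph.n_nodes)
        assert np.all(net.delay_ms >= 0.1) and np.all(net.delay_ms <= 40.0)
        # synapse class follows the presynaptic cell
        assert np.array_equal(net.is_es, ~net.is_inhibitory[net.pre])

    def test_stratified_inhibitory_count_at_scale(self):
        from comsnn.topology import TopologyConfig, generate

        g = generate(TopologyConfig("bbv", 100, m0=4, me=3, seed=1))
        net = build_network(g, SimConfig(duration=10.0), P, seed=5)
        assert int(net.is_inhibitory.sum()) == 20


class TestAttack:
    def test_removal_count_and_determinism(self, tiny_network):
        a = apply_attack(tiny_network, AttackSpec(0.25, seed=3))
        b = apply_attack(tiny_network, AttackSpec(0.25, seed=3))
        assert len(a.removed) == round(0.25 * tiny_network.n)
        assert a.removed == b.removed

    def test_zero_proportion_noop(self, tiny_network):
        a = apply_attack(tiny_network, AttackSpec(0.0, seed=3))
        assert a.removed == frozenset()

    def test_extreme_proportion_guarded(self, tiny_network):
        with pytest.raises(ConfigurationError):
            apply_attack(tiny_network, AttackSpec(0.9, seed=0))
        a = apply_attack(tiny_network, AttackSpec(0.9, seed=0), allow_extreme=True)
        assert len(a.removed) == round(0.9 * tiny_network.n)

    def test_removed_neurons_are_silent(self, tiny_network, tiny_config):
        att = apply_attack(tiny_network, AttackSpec(0.25, seed=1))
        res = simulate(att, tiny_config)
        for i in att.removed:
            assert len(res.spike_times[i]) == 0

    def test_full_removal_yields_no_spikes_and_pure_decay(self, tiny_network):
        cfg = SimConfig(duration=50.0, seed=1)
        att = apply_attack(tiny_network, AttackSpec(1.0, seed=0), allow_extreme=True)
        res = simulate(att, cfg)
        assert sum(len(s) for s in res.spike_times) == 0
        assert np.all(np.isnan(res.msw_values))  # no alive synapses to average


class TestSimulate:
    def test_bit_identical_determinism(self, tiny_network, tiny_config):
        r1 = simulate(tiny_network, tiny_config)
        r2 = simulate(tiny_network, tiny_config)
        assert np.concatenate(r1.spike_times).tobytes() == np.concatenate(
            r2.spike_times
        ).tobytes()
        assert r1.v_traces.tobytes() == r2.v_traces.tobytes()
        assert np.array_equal(r1.final_g, r2.final_g)

    def test_weight_and_gating_bounds_throughout(self, tiny_network):
        cfg = SimConfig(duration=200.0, seed=3, record_g=True)
        res = simulate(tiny_network, cfg)
        assert np.all(res.g_snapshots >= 0.0)
        assert np.all(res.g_snapshots <= P.g_max + 1e-12)

    def test_spike_times_strictly_increasing(self, tiny_run):
        for s in tiny_run.spike_times:
            assert np.all(np.diff(s) > 0)

    def test_dt_exceeding_min_delay_rejected(self):
        net = make_two_neuron_network(delay_ms=0.1)
        with pytest.raises(ConfigurationError, match="delay"):
            simulate(net, SimConfig(duration=10.0, dt=0.2))

    @pytest.mark.parametrize("delay", [0.1, 5.0, 40.0])
    def test_delay_causality(self, delay):
        # perturbing the presynaptic neuron changes the postsynaptic
        # potential no earlier than the spike time plus the delay
        net = make_two_neuron_network(delay_ms=delay)
        cfg = SimConfig(duration=80.0, drive=ExternalDrive(kind="none"), seed=0)
        n_steps = cfg.n_steps
        quiet = np.zeros((n_steps, 2))
        pulse = quiet.copy()
        t_pulse = 100  # step index; 10 ms
        pulse[t_pulse : t_pulse + 20, 0] = 30.0  # drives the presynaptic cell
        r_quiet = simulate(net, cfg, i_ext_override=quiet)
        r_pulse = simulate(net, cfg, i_ext_override=pulse)
        assert len(r_pulse.spike_times[0]) > 0
        diff = np.flatnonzero(r_pulse.v_traces[:, 1] != r_quiet.v_traces[:, 1])
        assert diff.size > 0
        first_change_ms = (diff[0] + 1) * cfg.dt
        t_pulse_ms = (t_pulse + 1) * cfg.dt
        assert first_change_ms >= t_pulse_ms + delay - 1e-9

    def test_stdp_direction_under_forced_timing(self):
        # pre firing ~4 ms before post potentiates the excitatory synapse;
        # the reversed order depresses it
        def run(order):
            pl = replace(P, mu_ex=1e6, mu_in=1e6)  # isolate the STDP effect
            net = make_two_neuron_network(delay_ms=0.1, plasticity=pl)
            net = replace(net, g_init=np.array([pl.g_max / 2]))
            cfg = SimConfig(duration=400.0, drive=ExternalDrive(kind="none"), seed=0)
            drive = np.zeros((cfg.n_steps, 2))
            for k in range(8):
                t0 = 400 + 400 * k  # every 40 ms
                if order == "pre_first":
                    drive[t0 : t0 + 12, 0] = 30.0
                    drive[t0 + 40 : t0 + 52, 1] = 30.0
                else:
                    drive[t0 : t0 + 12, 1] = 30.0
                    drive[t0 + 40 : t0 + 52, 0] = 30.0
            res = simulate(net, cfg, i_ext_override=drive)
            assert len(res.spike_times[0]) >= 8
            assert len(res.spike_times[1]) >= 8
            return res.final_g[0]

        assert run("pre_first") > P.g_max / 2
        assert run("post_first") < P.g_max / 2

    def test_noise_drive_is_seed_reproducible(self, tiny_network):
        cfg = SimConfig(
            duration=100.0, seed=9,
            drive=ExternalDrive(kind="noise", amplitude_ex=5, amplitude_in=2),
        )
        r1 = simulate(tiny_network, cfg)
        r2 = simulate(tiny_network, cfg)
        assert r1.v_traces.tobytes() == r2.v_traces.tobytes()


def test_sim_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(duration=100.0, dt=0.3)  # not an integer multiple
    with pytest.raises(ConfigurationError):
        SimConfig(duration=100.0, msw_sample_interval=0.05)
    with pytest.raises(ConfigurationError):
        AttackSpec(1.5)
    with pytest.raises(ConfigurationError):
        ExternalDrive(kind="wibble")
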