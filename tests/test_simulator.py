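"""Exact integration, spiking semantics, external drive, determinism."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from synquant.network import PopulationSpec, SynapseTable
from synquant.simulator import (
    NeuronParams,
    SimState,
    SimulationConfig,
    exact_propagator,
    initialize_membranes,
    poisson_external_input,
    run,
    step,
)

def empty_table():
    return SynapseTable(
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty(0),
        np.empty(0),
        np.empty(0, object),
    )


def single_pop(v0=-65.0, v0_std=0.0, n=1, k_ext=0):
    return [PopulationSpec("X", n, k_ext, v0_mean=v0, v0_std=v0_std)]


class TestExactPropagator:
    def test_current_decay_is_scalar_exponential(self):
        p = NeuronParams()
        prop = exact_propagator(p, 0.1)
        assert prop.p_ii == pytest.approx(math.exp(-0.1 / 0.5), rel=1e-15)

    def test_leak_only_voltage_decay(self):
        p = NeuronParams()
        prop = exact_propagator(p, 0.1)
        assert prop.p_vv == pytest.approx(math.exp(-0.1 / 10.0), rel=1e-15)

    def test_one_step_map_matches_adaptive_ode_solver(self, rng):
        """Independent oracle: high-accuracy numerical integration."""
        p = NeuronParams()
        h = 0.1
        prop = exact_propagator(p, h)
        for _ in range(20):
            v0 = rng.uniform(-80, -50)
            i0 = rng.uniform(-500, 500)

            def rhs(t, y):
                i_syn, v = y
                return [
                    -i_syn / p.synaptic_time_constant,
                    (-(v - p.leak_reversal) / p.membrane_time_constant)
                    + i_syn / p.membrane_capacitance,
                ]

            sol = solve_ivp(
                rhs, (0, h), [i0, v0], rtol=1e-12, atol=1e-12, dense_output=True
            )
            i_exact, v_exact = sol.y[:, -1]
            v_map = (
                p.leak_reversal
                + prop.p_vv * (v0 - p.leak_reversal)
                + prop.p_vi * i0
            )
            assert abs(v_map - v_exact) <= 1e-10
            assert abs(prop.p_ii * i0 - i_exact) <= 1e-10

    def test_subthreshold_trajectory_closed_form_over_100_steps(self, rng):
        p = NeuronParams()
        h = 0.1
        prop = exact_propagator(p, h)
        state = SimState(
            v=np.array([-70.0]), i_syn=np.array([300.0]), refractory=np.zeros(1, int)
        )
        el, tm, ts, cm = (
            p.leak_reversal,
            p.membrane_time_constant,
            p.synaptic_time_constant,
            p.membrane_capacitance,
        )
        v0, i0 = state.v[0], state.i_syn[0]
        for k in range(1, 101):
            step(state, p, prop, np.zeros(1), h)
            t = k * h
            i_cf = i0 * math.exp(-t / ts)
            v_cf = (
                el
                + (v0 - el) * math.exp(-t / tm)
                + i0
                * (math.exp(-t / ts) - math.exp(-t / tm))
                * tm
                * ts
                / ((ts - tm) * cm)
            )
            assert abs(state.v[0] - v_cf) <= 1e-9
            assert abs(state.i_syn[0] - i_cf) <= 1e-12

    def test_degenerate_time_constants_rejected(self):
        p = NeuronParams(membrane_time_constant=5.0, synaptic_time_constant=5.0)
        with pytest.raises(ValueError, match="tau_m == tau_s"):
            exact_propagator(p, 0.1)


class TestStepSemantics:
    def test_single_delivery_jumps_current_by_weight(self):
        p = NeuronParams()
        prop = exact_propagator(p, 0.1)
        state = SimState(
            v=np.array([-65.0]), i_syn=np.array([0.0]), refractory=np.zeros(1, int)
        )
        step(state, p, prop, np.array([123.0]), 0.1)
        # jump applied before propagation: I(h) = J * exp(-h/tau_s)
        assert state.i_syn[0] == pytest.approx(123.0 * prop.p_ii)

    def test_subthreshold_start_never_spikes_without_input(self):
        p = NeuronParams()
        prop = exact_propagator(p, 0.1)
        state = SimState(
            v=np.array([p.threshold - 1e-9]),
            i_syn=np.array([0.0]),
            refractory=np.zeros(1, int),
        )
        for _ in range(1000):
            spikes = step(state, p, prop, np.zeros(1), 0.1)
            assert not spikes.any()
        assert state.v[0] == pytest.approx(p.leak_reversal, abs=1e-2)

    def test_refractory_clamps_v_while_current_decays(self):
        p = NeuronParams(refractory_period=1.0)
        prop = exact_propagator(p, 0.1)
        state = SimState(
            v=np.array([p.threshold + 1.0]),
            i_syn=np.array([200.0]),
            refractory=np.zeros(1, int),
        )
        spikes = step(state, p, prop, np.zeros(1), 0.1)
        assert spikes[0]
        i_after = state.i_syn[0]
        for _ in range(5):
            step(state, p, prop, np.zeros(1), 0.1)
            assert state.v[0] == p.reset
            assert state.i_syn[0] < i_after  # current keeps decaying
            i_after = state.i_syn[0]


class TestExternalInput:
    def test_mean_rate_matches_poisson_law(self, rng):
        """K_ext = 2000 sources at 8/s -> 16,000 input spikes per second."""
        k_ext, nu, h, n_steps = np.array([2000.0]), 8.0, 0.1, 50_000
        total = sum(
            c[0]
            for c in poisson_external_input(k_ext, nu, 1.0, n_steps, h, rng)
        )
        expected = k_ext[0] * nu * n_steps * h * 1e-3
        assert abs(total - expected) <= 4 * math.sqrt(expected)

    def test_zero_rate_produces_no_events(self, rng):
        counts = list(
            poisson_external_input(np.array([100.0]), 0.0, 1.0, 100, 0.1, rng)
        )
        assert sum(c[0] for c in counts) == 0

    def test_count_dispersion_is_poisson(self, rng):
        k_ext, nu, h = np.array([500.0]), 8.0, 0.1
        counts = np.array(
            [c[0] for c in poisson_external_input(k_ext, nu, 1.0, 20_000, h, rng)]
        )
        lam = k_ext[0] * nu * h * 1e-3
        # index of dispersion ~ 1 +- 4*sqrt(2/n)
        iod = counts.var() / counts.mean()
        assert abs(iod - 1.0) <= 4 * math.sqrt(2 / len(counts))
        assert counts.mean() == pytest.approx(lam, rel=0.05)


class TestInitialMembranes:
    def test_population_statistics_reproduced(self, rng):
        pops = [PopulationSpec("L2/3E", 200_000, 0, v0_mean=-68.28, v0_std=5.36)]
        v = initialize_membranes(pops, rng)
        assert abs(v.mean() - -68.28) <= 4 * 5.36 / math.sqrt(len(v))
        assert v.std() == pytest.approx(5.36, rel=0.02)

    def test_zero_std_degenerate(self, rng):
        v = initialize_membranes([PopulationSpec("X", 50, 0, -60.0, 0.0)], rng)
        assert np.all(v == -60.0)


class TestRun:
    def test_quiescent_network_stays_silent(self):
        cfg = SimulationConfig(duration=100.0, transient=0.0, external_rate=0.0)
        rec = run(empty_table(), NeuronParams(), cfg, single_pop(v0=-60.0))
        assert len(rec.times) == 0

    def test_initial_v_above_threshold_spikes_first_step(self):
        cfg = SimulationConfig(duration=10.0, transient=0.0, external_rate=0.0)
        rec = run(empty_table(), NeuronParams(), cfg, single_pop(v0=-45.0))
        assert rec.times[0] == pytest.approx(cfg.resolution)

    def test_constant_drive_matches_analytic_schedule(self):
        """Closed-form LIF firing times under DC drive, on the grid."""
        p = NeuronParams()
        i_dc = 450.0
        cfg = SimulationConfig(
            duration=500.0, transient=0.0, external_rate=0.0, dc_current=i_dc
        )
        rec = run(empty_table(), p, cfg, single_pop(v0=p.leak_reversal))
        r = p.membrane_resistance
        drive = r * i_dc  # 18 mV asymptote above rest
        gap = p.threshold - p.leak_reversal
        t_star = p.membrane_time_constant * math.log(drive / (drive - gap))
        h = cfg.resolution
        # first spike: first grid point at/after the crossing
        first = math.ceil(t_star / h - 1e-9) * h
        assert rec.times[0] == pytest.approx(first)
        # steady ISI: refractory period + crossing time, grid-quantized
        isi = np.diff(rec.times)
        expected_isi = p.refractory_period + first
        assert np.all(np.abs(isi - expected_isi) <= h + 1e-9)

    def test_all_spike_times_on_grid_and_isi_respects_refractoriness(self):
        cfg = SimulationConfig(
            duration=2000.0, transient=0.0, seed=5, external_rate=8.0,
            external_weight=87.81,
        )
        rec = run(empty_table(), NeuronParams(), cfg, single_pop(n=50, k_ext=1500))
        assert len(rec.times) > 100
        mult = rec.times / cfg.resolution
        np.testing.assert_allclose(mult, np.round(mult), atol=1e-9)
        for nid in range(50):
            t = rec.times[rec.senders == nid]
            if len(t) > 1:
                assert np.diff(t).min() >= NeuronParams().refractory_period - 1e-9

    def test_same_seed_byte_identical_records(self):
        cfg = SimulationConfig(duration=1000.0, transient=0.0, seed=9, external_rate=8.0)
        pops = single_pop(n=20, k_ext=1200)
        r1 = run(empty_table(), NeuronParams(), cfg, pops)
        r2 = run(empty_table(), NeuronParams(), cfg, pops)
        np.testing.assert_array_equal(r1.senders, r2.senders)
        np.testing.assert_array_equal(r1.times, r2.times)

    def test_spike_transmission_is_causal_with_delay(self):
        """Every postsynaptic spike traces back to a presynaptic one."""
        delay = 2.0
        pops = [
            PopulationSpec("A", 1, 1500, v0_mean=-58.0),
            PopulationSpec("B", 1, 0, v0_mean=-65.0),
        ]
        table = SynapseTable(
            source_id=np.array([0]),
            target_id=np.array([1]),
            weight=np.array([20000.0]),  # strong: one EPSC drives B over threshold
            delay=np.array([delay]),
            projection=np.array(["A->B"], object),
        )
        cfg = SimulationConfig(duration=3000.0, transient=0.0, seed=1, external_rate=8.0)
        rec = run(table, NeuronParams(), cfg, pops)
        t_a = rec.times[rec.senders == 0]
        t_b = rec.times[rec.senders == 1]
        assert len(t_a) > 3 and len(t_b) > 0
        for tb in t_b:
            # B fires one step after a delivery from A
            lags = tb - (t_a + delay)
            assert np.any((lags >= 0) & (lags <= 0.5))

    def test_spike_record_round_trips_through_event_file(self, tmp_path):
        cfg = SimulationConfig(duration=500.0, transient=100.0, seed=2, external_rate=8.0)
        rec = run(empty_table(), NeuronParams(), cfg, single_pop(n=5, k_ext=1500))
        path = tmp_path / "spikes.tsv"
        rec.to_tsv(path)
        clone = type(rec).from_tsv(path)
        np.testing.assert_array_equal(clone.senders, rec.senders)
        np.testing.assert_allclose(clone.times, rec.times)
        assert clone.observation_window == rec.observation_window
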