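"""Neuron dynamics: decay, refractoriness, noise, delivery and determinism."""

import numpy as np
import pytest

from protomap.architecture import (
    LayerGeometry,
    Network,
    NetworkGeometry,
    SynapseTable,
    WiringConfig,
    build_input_to_lgn,
)
from protomap.dynamics import (
    NeuronParams,
    SimConfig,
    SimulationState,
    noise_step,
    run_presentation,
    step_cortex,
    step_lgn,
)
from protomap.stimulus import EventStream

from conftest import smoke_bar

PARAMS = NeuronParams()


def make_state(n_lgn=1, n_ctx=1):
    s = SimulationState.fresh(n_lgn, n_ctx, PARAMS)
    s.noise[:] = 0.0
    return s


class TestLgnStep:
    def test_voltage_decay_closed_form(self):
        s = make_state()
        s.v_lgn[0] = 1.0
        # threshold is 0 mV, so decay is only observable below it;
        # verify the update rule directly over 10 ms in one step
        fired = step_lgn(s, 10.0, PARAMS, np.zeros(1))
        # V=1.0 decays then crosses threshold (still > 0) -> spike
        assert list(fired) == [0]

    def test_subthreshold_decay(self):
        # with a -1 bias (never spiking) the decay factor is exact
        s = make_state()
        s.v_lgn[0] = -1.0
        step_lgn(s, 10.0, PARAMS, np.zeros(1))
        assert s.v_lgn[0] == pytest.approx(-np.exp(-1.0))

    def test_single_delivery_fires(self):
        s = make_state()
        fired = step_lgn(s, 0.1, PARAMS, np.array([1.0]))
        assert list(fired) == [0]
        assert s.v_lgn[0] == 0.0
        assert s.ref_lgn[0] == 100  # 10 ms at dt=0.1

    def test_delivery_during_refractory_ignored(self):
        s = make_state()
        step_lgn(s, 0.1, PARAMS, np.array([1.0]))
        for _ in range(50):  # 5 ms into the 10 ms refractory period
            fired = step_lgn(s, 0.1, PARAMS, np.array([1.0]))
            assert len(fired) == 0
        assert s.v_lgn[0] == 0.0


class TestCortexStep:
    def test_voltage_decay_closed_form(self):
        s = make_state()
        s.v_ctx[0] = 0.8
        step_cortex(s, 5.0, PARAMS, np.array([10.0]), np.zeros(1), np.zeros(1), None)
        assert s.v_ctx[0] == pytest.approx(0.8 * np.exp(-1.0))

    def test_steady_state_is_total_drive(self):
        s = make_state()
        s.g_e[0] = 0.0
        thresholds = np.array([10.0])
        for _ in range(10_000):
            # clamp a constant drive via the noise term
            s.noise[:] = 0.9
            step_cortex(s, 0.1, PARAMS, thresholds, np.zeros(1), np.zeros(1), None)
        assert s.v_ctx[0] == pytest.approx(0.9, abs=1e-9)

    def test_conductance_additivity(self):
        s = make_state()
        step_cortex(
            s, 0.1, PARAMS, np.array([10.0]), np.array([0.35]), np.zeros(1), None
        )
        before = s.g_e[0]
        assert before == pytest.approx(0.35)
        # a second instant delivery adds on top of the decayed value
        step_cortex(
            s, 0.1, PARAMS, np.array([10.0]), np.array([0.35]), np.zeros(1), None
        )
        assert s.g_e[0] == pytest.approx(0.35 * np.exp(-0.1 / 5.0) + 0.35)

    def test_sign_conservation(self, rng):
        s = make_state(n_ctx=4)
        for _ in range(200):
            we = rng.uniform(0, 0.4, 4)
            wi = rng.uniform(-0.4, 0, 4)
            step_cortex(s, 0.1, PARAMS, np.full(4, 10.0), we, wi, None)
            assert np.all(s.g_e >= 0)
            assert np.all(s.g_i <= 0)

    def test_voltages_decay_monotonically_without_input(self):
        s = make_state(n_ctx=3)
        s.v_ctx[:] = [0.9, 0.5, 0.2]
        prev = s.v_ctx.copy()
        for _ in range(100):
            step_cortex(
                s, 0.1, PARAMS, np.full(3, 10.0), np.zeros(3), np.zeros(3), None
            )
            assert np.all(s.v_ctx <= prev)
            prev = s.v_ctx.copy()
        assert np.all(np.abs(s.v_ctx) < 0.2)


class TestNoise:
    def test_deterministic_fixed_point(self):
        p = NeuronParams(noise_sd=0.0)
        assert noise_step(0.7, 0.1, p, 0.0) == pytest.approx(0.7)

    def test_stationary_mean(self, rng):
        n = np.full(1000, PARAMS.noise_mean)
        total = 0.0
        steps = 2000
        for _ in range(steps):
            n = noise_step(n, 0.1, PARAMS, rng.standard_normal(1000))
            total += n.mean()
        # the clip at zero keeps N positive but biases the stationary mean
        # upward of the nominal 0.7 (empirically ~0.77 for sd=0.5)
        assert total / steps == pytest.approx(0.7, abs=0.1)

    def test_never_negative(self, rng):
        n = np.zeros(100)
        for _ in range(500):
            n = noise_step(n, 0.1, PARAMS, rng.standard_normal(100))
            assert np.all(n >= 0)


def _toy_network(lateral_entries, thresholds, geometry=None):
    """Small hand-wired network: 2x2 LGN relays to a hand-set cortex."""
    geom = geometry or NetworkGeometry(
        input=LayerGeometry("input", 8, 8),
        lgn=LayerGeometry("lgn", 2, 2),
        cortex=LayerGeometry("cortex", 1, len(thresholds)),
    )
    lateral_entries = np.asarray(lateral_entries, dtype=np.float64).reshape(-1, 4)
    aff = SynapseTable(
        projection="lgn->cortex",
        pre=np.zeros(1, dtype=np.int64),
        post=np.zeros(1, dtype=np.int64),
        weight=np.array([4.0]),
        delay_ms=np.array([0.1]),
    )
    lat = SynapseTable(
        projection="cortex->cortex",
        pre=lateral_entries[:, 0].astype(np.int64),
        post=lateral_entries[:, 1].astype(np.int64),
        weight=lateral_entries[:, 2],
        delay_ms=lateral_entries[:, 3],
    )
    return Network(
        geometry=geom,
        wiring=WiringConfig(),
        inhibitory=np.zeros(geom.cortex.n, dtype=bool),
        v_thresh_cortex=np.asarray(thresholds, dtype=np.float64),
        input_to_lgn=build_input_to_lgn(geom),
        lgn_to_cortex=aff,
        lateral=lat,
    )


def _one_event():
    return EventStream(x=[0], y=[0], polarity=[1], t=[0])


class TestPresentation:
    def test_empty_stream_noise_off_is_silent(self, smoke_network):
        empty = EventStream(x=[], y=[], polarity=[], t=[])
        with pytest.warns(UserWarning, match="empty"):
            log = run_presentation(
                smoke_network,
                empty,
                SimConfig(noise_on=False, duration_ms=50.0, engine="python"),
            )
        assert len(log.lgn_neuron) == 0
        assert len(log.cortex_neuron) == 0

    def test_single_event_single_lgn_spike(self, smoke_network):
        log = run_presentation(
            smoke_network,
            _one_event(),
            SimConfig(noise_on=False, duration_ms=50.0, engine="python"),
        )
        assert len(log.lgn_neuron) == 1
        assert log.lgn_neuron[0] == 0  # relay target of pixel (0, 0)

    def test_full_tile_still_one_lgn_spike(self, smoke_network):
        """16 simultaneous events in one 4x4 tile relay as a single spike."""
        xs, ys = np.meshgrid(np.arange(4), np.arange(4))
        stream = EventStream(
            x=xs.ravel(),
            y=ys.ravel(),
            polarity=np.ones(16, dtype=int),
            t=np.zeros(16, dtype=int),
        )
        log = run_presentation(
            smoke_network,
            stream,
            SimConfig(noise_on=False, duration_ms=50.0, engine="python"),
        )
        assert len(log.lgn_neuron) == 1

    def test_lgn_refractory_rate_limit(self, smoke_network):
        """A 16-event tile spread over 25 ms yields ceil(25/10)=3 LGN spikes."""
        t = np.linspace(0, 25_000, 16).astype(int)
        stream = EventStream(
            x=np.tile(np.arange(4), 4),
            y=np.repeat(np.arange(4), 4),
            polarity=np.ones(16, dtype=int),
            t=t,
        )
        log = run_presentation(
            smoke_network,
            stream,
            SimConfig(noise_on=False, duration_ms=60.0, engine="python"),
        )
        assert len(log.lgn_neuron) == 3
        assert np.all(np.diff(np.sort(log.lgn_t_ms)) >= 10.0)

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_refractory_limits_per_layer(self, smoke_network, engine):
        stream = smoke_bar("E", seed=8)
        from protomap.stimulus import generate_bar_events

        log = run_presentation(
            smoke_network, generate_bar_events(stream), SimConfig(seed=2, engine=engine)
        )
        for neurons, times, ref in [
            (log.lgn_neuron, log.lgn_t_ms, 10.0),
            (log.cortex_neuron, log.cortex_t_ms, 5.0),
        ]:
            for n in np.unique(neurons)[:50]:
                tt = np.sort(times[neurons == n])
                if len(tt) > 1:
                    assert np.diff(tt).min() >= ref

    def test_engines_agree_exactly(self, smoke_network):
        from protomap.stimulus import generate_bar_events

        stream = generate_bar_events(smoke_bar("NE", seed=8))
        logs = [
            run_presentation(smoke_network, stream, SimConfig(seed=3, engine=e))
            for e in ("numba", "python")
        ]
        assert np.array_equal(logs[0].cortex_neuron, logs[1].cortex_neuron)
        assert np.array_equal(logs[0].cortex_t_ms, logs[1].cortex_t_ms)
        assert np.array_equal(logs[0].lgn_neuron, logs[1].lgn_neuron)

    def test_bit_identical_replay(self, smoke_network):
        from protomap.stimulus import generate_bar_events

        stream = generate_bar_events(smoke_bar("S", seed=8))
        a = run_presentation(smoke_network, stream, SimConfig(seed=7))
        b = run_presentation(smoke_network, stream, SimConfig(seed=7))
        assert np.array_equal(a.cortex_neuron, b.cortex_neuron)
        assert np.array_equal(a.cortex_t_ms, b.cortex_t_ms)

    def test_timestep_convergence_toy_circuit(self):
        """Spike times of a 3-neuron chain are stable under dt halving."""
        # cortex 0 -> 1 -> 2 chain with strong weights and 1 ms delays
        net = _toy_network(
            [[0, 1, 4.0, 1.0], [1, 2, 4.0, 1.0]],
            thresholds=[1.0, 1.0, 1.0],
        )
        times = {}
        for dt in (0.025, 0.0125):
            log = run_presentation(
                net,
                _one_event(),
                SimConfig(dt_ms=dt, duration_ms=40.0, noise_on=False, engine="python"),
            )
            assert len(log.cortex_neuron) == 3
            times[dt] = log.cortex_t_ms[np.argsort(log.cortex_neuron)]
        assert np.all(np.abs(times[0.025] - times[0.0125]) < 0.05)
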