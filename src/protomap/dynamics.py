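"""Clock-driven simulation of the LGN relay and cortical CUBA LIF dynamics.

Neuron models
-------------
LGN neurons are plain leaky integrators, tau_L dV/dt = -V, with spikes from
the input layer injected as instantaneous voltage jumps V <- V + w (w = 1.0).
With a 0 mV threshold and a 10 ms refractory period, the first input spike of
a 4x4 tile fires the LGN cell and further input within the refractory window
is absorbed — each tile relays at most 100 Hz.

Cortical neurons follow the current-based (CUBA) Vogels–Abbott form

    tau_m dV/dt = -V + g_e + g_i + N,

where g_e >= 0 and g_i <= 0 are exponentially decaying synaptic drive terms
(tau_syn = 5 ms; a presynaptic spike adds its weight to the matching term
after the synaptic delay) and N is a positive background-noise term evolving
as a mean-reverting (Ornstein–Uhlenbeck-type) process with mean 0.7, sd 0.5
and tau 5 ms, clipped at zero.  Spiking resets V to 0 with a 5 ms refractory
period; thresholds are per-neuron (about 1.0–1.3 mV).

Integration is exponential-Euler on a fixed clock (default dt = 0.1 ms),
exact for the linear decays between deliveries.  Delayed deliveries run
through a ring buffer keyed by arrival step.  Two engines share the same
update order: a numba kernel for production runs and a pure-Python stepper
(`step_lgn` / `step_cortex`) used as the readable reference and for unit
tests; with noise disabled the two produce identical spike logs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .architecture import Network

__all__ = [
    "NeuronParams",
    "SimConfig",
    "SimulationState",
    "SpikeLog",
    "noise_step",
    "step_lgn",
    "step_cortex",
    "run_presentation",
]


@dataclass
class NeuronParams:
    """Membrane/synapse constants (voltages in mV, times in ms)."""

    v_reset: float = 0.0
    v_thresh_lgn: float = 0.0
    tau_m_lgn: float = 10.0
    tau_m_cortex: float = 5.0
    tau_syn_exc: float = 5.0
    tau_syn_inh: float = 5.0
    tau_noise: float = 5.0
    noise_mean: float = 0.7
    noise_sd: float = 0.5
    refractory_lgn: float = 10.0
    refractory_cortex: float = 5.0


@dataclass
class SimConfig:
    """Run-level knobs for one presentation."""

    dt_ms: float = 0.1
    duration_ms: float | None = None   # default: stream duration + tail
    tail_ms: float = 30.0              # lets delayed lateral activity play out
    seed: int = 0
    noise_on: bool = True
    engine: str = "numba"              # "numba" or "python"

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.engine not in ("numba", "python"):
            raise ValueError("engine must be 'numba' or 'python'")


@dataclass
class SpikeLog:
    """Spike times per layer for one presentation."""

    lgn_neuron: np.ndarray
    lgn_t_ms: np.ndarray
    cortex_neuron: np.ndarray
    cortex_t_ms: np.ndarray
    duration_ms: float
    n_lgn: int
    n_cortex: int

    def cortex_counts(self) -> np.ndarray:
        return np.bincount(self.cortex_neuron, minlength=self.n_cortex)

    def lgn_counts(self) -> np.ndarray:
        return np.bincount(self.lgn_neuron, minlength=self.n_lgn)

    def to_frame(self):
        """Columnar (neuron_id, layer, time_ms) table."""
        import pandas as pd

        return pd.DataFrame(
            {
                "neuron_id": np.concatenate([self.lgn_neuron, self.cortex_neuron]),
                "layer": ["lgn"] * len(self.lgn_neuron)
                + ["cortex"] * len(self.cortex_neuron),
                "time_ms": np.concatenate([self.lgn_t_ms, self.cortex_t_ms]),
            }
        )


def noise_step(
    n: np.ndarray | float,
    dt: float,
    params: NeuronParams,
    xi: np.ndarray | float,
) -> np.ndarray | float:
    """One mean-reverting update of the background-noise term, clipped at 0.

    N' = N + (dt/tau)(mu - N) + sd * sqrt(2 dt / tau) * xi,  xi ~ N(0, 1).
    """
    tau = params.tau_noise
    out = (
        n
        + (dt / tau) * (params.noise_mean - n)
        + params.noise_sd * math.sqrt(2.0 * dt / tau) * xi
    )
    return np.maximum(out, 0.0)


# --- reference (pure Python) engine ------------------------------------------


@dataclass
class SimulationState:
    """Mutable per-neuron state for the reference stepper."""

    v_lgn: np.ndarray
    ref_lgn: np.ndarray       # remaining refractory steps
    v_ctx: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    noise: np.ndarray
    ref_ctx: np.ndarray

    @classmethod
    def fresh(cls, n_lgn: int, n_ctx: int, params: NeuronParams) -> "SimulationState":
        return cls(
            v_lgn=np.zeros(n_lgn),
            ref_lgn=np.zeros(n_lgn, dtype=np.int64),
            v_ctx=np.zeros(n_ctx),
            g_e=np.zeros(n_ctx),
            g_i=np.zeros(n_ctx),
            noise=np.full(n_ctx, NeuronParams().noise_mean),
            ref_ctx=np.zeros(n_ctx, dtype=np.int64),
        )


def step_lgn(
    state: SimulationState,
    dt: float,
    params: NeuronParams,
    arrivals: np.ndarray,
) -> np.ndarray:
    """Advance all LGN neurons by one step; returns indices that spiked.

    Non-refractory neurons decay (V *= exp(-dt/tau)), absorb this step's
    delivered weights, and fire when V exceeds the 0 mV threshold.
    Refractory neurons hold V at reset and ignore deliveries.
    """
    active = state.ref_lgn <= 0
    state.ref_lgn[~active] -= 1
    state.v_lgn[active] *= math.exp(-dt / params.tau_m_lgn)
    state.v_lgn[active] += arrivals[active]
    fired = np.flatnonzero(active & (state.v_lgn > params.v_thresh_lgn))
    state.v_lgn[fired] = params.v_reset
    state.ref_lgn[fired] = int(round(params.refractory_lgn / dt))
    return fired


def step_cortex(
    state: SimulationState,
    dt: float,
    params: NeuronParams,
    thresholds: np.ndarray,
    arrivals_e: np.ndarray,
    arrivals_i: np.ndarray,
    xi: np.ndarray | None,
) -> np.ndarray:
    """Advance all cortical neurons by one step; returns indices that spiked.

    Synaptic terms decay then absorb deliveries (conductances evolve even
    during the refractory period); the membrane integrates
    tau_m dV/dt = -V + g_e + g_i + N by exponential Euler; refractory
    neurons hold V at reset.
    """
    state.g_e *= math.exp(-dt / params.tau_syn_exc)
    state.g_i *= math.exp(-dt / params.tau_syn_inh)
    state.g_e += arrivals_e
    state.g_i += arrivals_i
    if xi is not None:
        state.noise = noise_step(state.noise, dt, params, xi)
    drive = state.g_e + state.g_i + state.noise
    active = state.ref_ctx <= 0
    state.ref_ctx[~active] -= 1
    decay = math.exp(-dt / params.tau_m_cortex)
    state.v_ctx[active] = drive[active] + (state.v_ctx[active] - drive[active]) * decay
    fired = np.flatnonzero(active & (state.v_ctx >= thresholds))
    state.v_ctx[fired] = params.v_reset
    state.ref_ctx[fired] = int(round(params.refractory_cortex / dt))
    return fired


# --- shared preparation -------------------------------------------------------


def _csr(pre: np.ndarray, n_pre: int, *cols: np.ndarray):
    """Sort synapses by presynaptic index into CSR form."""
    order = np.argsort(pre, kind="stable")
    ptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=n_pre), out=ptr[1:])
    return (ptr,) + tuple(np.ascontiguousarray(c[order]) for c in cols)


def _prepare(network: Network, stream, cfg: SimConfig):
    """Quantize delays, bucket input events by delivery step, build CSRs."""
    params = NeuronParams()
    dt = cfg.dt_ms
    n_lgn = network.geometry.lgn.n
    n_ctx = network.geometry.cortex.n

    if cfg.duration_ms is None:
        duration_ms = stream.duration_s * 1e3 + cfg.tail_ms
    else:
        duration_ms = cfg.duration_ms
    nsteps = int(round(duration_ms / dt))

    # Input events -> LGN deliveries one step after their timestamp.
    tab = network.input_to_lgn
    target_of_pixel = np.full(network.geometry.input.n, -1, dtype=np.int64)
    target_of_pixel[tab.pre] = tab.post
    pix = stream.y * network.geometry.input.cols + stream.x
    if len(pix) and (pix.max() >= network.geometry.input.n or pix.min() < 0):
        raise ValueError("event outside sensor bounds for this geometry")
    ev_step = (stream.t // int(round(dt * 1e3))).astype(np.int64) + 1
    keep = ev_step < nsteps
    ev_step = ev_step[keep]
    ev_lgn = target_of_pixel[pix[keep]]
    order = np.argsort(ev_step, kind="stable")
    ev_step, ev_lgn = ev_step[order], ev_lgn[order]
    ev_ptr = np.zeros(nsteps + 1, dtype=np.int64)
    np.cumsum(np.bincount(ev_step, minlength=nsteps), out=ev_ptr[1:])

    aff = network.lgn_to_cortex
    aff_ptr, aff_post, aff_w = _csr(aff.pre, n_lgn, aff.post, aff.weight)

    lat = network.lateral
    lat_steps = np.maximum(np.rint(lat.delay_ms / dt), 1).astype(np.int64)
    lat_ptr, lat_post, lat_w, lat_d = _csr(
        lat.pre, n_ctx, lat.post, lat.weight, lat_steps
    )

    nslots = int(lat_steps.max() if len(lat_steps) else 1) + 2
    return params, dt, nsteps, duration_ms, (ev_ptr, ev_lgn), (
        aff_ptr, aff_post, aff_w
    ), (lat_ptr, lat_post, lat_w, lat_d), nslots


# --- numba engine -------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    nsteps,
    dt,
    n_lgn,
    n_ctx,
    ev_ptr,
    ev_lgn,
    aff_ptr,
    aff_post,
    aff_w,
    lat_ptr,
    lat_post,
    lat_w,
    lat_d,
    nslots,
    thresholds,
    dec_lgn,
    dec_syn_e,
    dec_syn_i,
    dec_m,
    ref_steps_lgn,
    ref_steps_ctx,
    noise_on,
    noise_mu,
    noise_a,   # dt / tau_noise
    noise_b,   # sd * sqrt(2 dt / tau_noise)
    xi,        # (nsteps, n_ctx) float32 standard normals (unused if noise off)
):
    v_lgn = np.zeros(n_lgn)
    ref_lgn = np.zeros(n_lgn, dtype=np.int64)
    v = np.zeros(n_ctx)
    g_e = np.zeros(n_ctx)
    g_i = np.zeros(n_ctx)
    noise = np.full(n_ctx, noise_mu if noise_on else 0.0)
    ref = np.zeros(n_ctx, dtype=np.int64)
    ge_buf = np.zeros((nslots, n_ctx))
    gi_buf = np.zeros((nslots, n_ctx))
    lgn_buf = np.zeros((nslots, n_lgn))

    cap_lgn = n_lgn * (nsteps // max(ref_steps_lgn, 1) + 2)
    cap_ctx = n_ctx * (nsteps // max(ref_steps_ctx, 1) + 2)
    lgn_sp_n = np.empty(cap_lgn, dtype=np.int64)
    lgn_sp_t = np.empty(cap_lgn, dtype=np.int64)
    ctx_sp_n = np.empty(cap_ctx, dtype=np.int64)
    ctx_sp_t = np.empty(cap_ctx, dtype=np.int64)
    n_sp_lgn = 0
    n_sp_ctx = 0

    for step in range(nsteps):
        slot = step % nslots

        # ---- LGN layer
        for k in range(ev_ptr[step], ev_ptr[step + 1]):
            lgn_buf[slot, ev_lgn[k]] += 1.0
        for i in range(n_lgn):
            if ref_lgn[i] > 0:
                ref_lgn[i] -= 1
                lgn_buf[slot, i] = 0.0
                continue
            v_lgn[i] = v_lgn[i] * dec_lgn + lgn_buf[slot, i]
            lgn_buf[slot, i] = 0.0
            if v_lgn[i] > 0.0:
                v_lgn[i] = 0.0
                ref_lgn[i] = ref_steps_lgn
                lgn_sp_n[n_sp_lgn] = i
                lgn_sp_t[n_sp_lgn] = step
                n_sp_lgn += 1
                nxt = (step + 1) % nslots
                for s in range(aff_ptr[i], aff_ptr[i + 1]):
                    ge_buf[nxt, aff_post[s]] += aff_w[s]

        # ---- cortical layer
        for j in range(n_ctx):
            g_e[j] = g_e[j] * dec_syn_e + ge_buf[slot, j]
            g_i[j] = g_i[j] * dec_syn_i + gi_buf[slot, j]
            ge_buf[slot, j] = 0.0
            gi_buf[slot, j] = 0.0
            if noise_on:
                nn = (
                    noise[j]
                    + noise_a * (noise_mu - noise[j])
                    + noise_b * xi[step, j]
                )
                noise[j] = nn if nn > 0.0 else 0.0
            if ref[j] > 0:
                ref[j] -= 1
                continue
            drive = g_e[j] + g_i[j] + noise[j]
            v[j] = drive + (v[j] - drive) * dec_m
            if v[j] >= thresholds[j]:
                v[j] = 0.0
                ref[j] = ref_steps_ctx
                ctx_sp_n[n_sp_ctx] = j
                ctx_sp_t[n_sp_ctx] = step
                n_sp_ctx += 1
                for s in range(lat_ptr[j], lat_ptr[j + 1]):
                    tgt = (step + lat_d[s]) % nslots
                    w = lat_w[s]
                    if w > 0.0:
                        ge_buf[tgt, lat_post[s]] += w
                    else:
                        gi_buf[tgt, lat_post[s]] += w

    return (
        lgn_sp_n[:n_sp_lgn],
        lgn_sp_t[:n_sp_lgn],
        ctx_sp_n[:n_sp_ctx],
        ctx_sp_t[:n_sp_ctx],
    )


def _run_python(
    nsteps, dt, n_lgn, n_ctx, ev, aff, lat, nslots, thresholds, params, cfg, xi
):
    """Reference engine: same update order as the kernel, via the step fns."""
    ev_ptr, ev_lgn = ev
    aff_ptr, aff_post, aff_w = aff
    lat_ptr, lat_post, lat_w, lat_d = lat
    state = SimulationState.fresh(n_lgn, n_ctx, params)
    if not cfg.noise_on:
        state.noise[:] = 0.0
    ge_buf = np.zeros((nslots, n_ctx))
    gi_buf = np.zeros((nslots, n_ctx))
    lgn_buf = np.zeros((nslots, n_lgn))
    lgn_sp, ctx_sp = [], []
    for step in range(nsteps):
        slot = step % nslots
        np.add.at(lgn_buf[slot], ev_lgn[ev_ptr[step]: ev_ptr[step + 1]], 1.0)
        fired = step_lgn(state, dt, params, lgn_buf[slot])
        lgn_buf[slot] = 0.0
        if len(fired):
            nxt = (step + 1) % nslots
            for i in fired:
                lgn_sp.append((i, step))
                sl = slice(aff_ptr[i], aff_ptr[i + 1])
                np.add.at(ge_buf[nxt], aff_post[sl], aff_w[sl])
        fired = step_cortex(
            state, dt, params, thresholds, ge_buf[slot], gi_buf[slot],
            xi[step] if cfg.noise_on else None,
        )
        ge_buf[slot] = 0.0
        gi_buf[slot] = 0.0
        for j in fired:
            ctx_sp.append((j, step))
            sl = slice(lat_ptr[j], lat_ptr[j + 1])
            for s in range(sl.start, sl.stop):
                tgt = (step + lat_d[s]) % nslots
                if lat_w[s] > 0:
                    ge_buf[tgt, lat_post[s]] += lat_w[s]
                else:
                    gi_buf[tgt, lat_post[s]] += lat_w[s]
    lgn_sp = np.array(lgn_sp, dtype=np.int64).reshape(-1, 2)
    ctx_sp = np.array(ctx_sp, dtype=np.int64).reshape(-1, 2)
    return lgn_sp[:, 0], lgn_sp[:, 1], ctx_sp[:, 0], ctx_sp[:, 1]


def run_presentation(network: Network, stream, cfg: SimConfig | None = None) -> SpikeLog:
    """Present one event stream to a network and return the full spike log.

    Events are injected as input-layer spikes at their timestamps, relayed
    through the 4x4 tiling to the LGN, and propagated to the cortex with all
    synaptic delays honoured.  The run is fully determined by
    ``(network, stream, cfg.seed)``.
    """
    cfg = cfg or SimConfig()
    if len(stream) == 0:
        warnings.warn("empty event stream: simulating background activity only")
    params, dt, nsteps, duration_ms, ev, aff, lat, nslots = _prepare(
        network, stream, cfg
    )
    n_lgn = network.geometry.lgn.n
    n_ctx = network.geometry.cortex.n
    thresholds = np.asarray(network.v_thresh_cortex, dtype=np.float64)

    # Background-noise increments are drawn up front from the run seed; both
    # engines consume the identical array, so they agree spike for spike.
    if cfg.noise_on:
        rng = np.random.default_rng(cfg.seed)
        xi = rng.standard_normal((nsteps, n_ctx), dtype=np.float32)
    else:
        xi = np.zeros((1, n_ctx), dtype=np.float32)

    if cfg.engine == "python":
        ln, lt, cn, ct = _run_python(
            nsteps, dt, n_lgn, n_ctx, ev, aff, lat, nslots, thresholds, params,
            cfg, xi
        )
    else:
        ln, lt, cn, ct = _run_kernel(
            nsteps,
            dt,
            n_lgn,
            n_ctx,
            ev[0],
            ev[1],
            aff[0],
            aff[1],
            aff[2],
            lat[0],
            lat[1],
            lat[2],
            lat[3],
            nslots,
            thresholds,
            math.exp(-dt / params.tau_m_lgn),
            math.exp(-dt / params.tau_syn_exc),
            math.exp(-dt / params.tau_syn_inh),
            math.exp(-dt / params.tau_m_cortex),
            int(round(params.refractory_lgn / dt)),
            int(round(params.refractory_cortex / dt)),
            cfg.noise_on,
            params.noise_mean,
            dt / params.tau_noise,
            params.noise_sd * math.sqrt(2.0 * dt / params.tau_noise),
            xi,
        )
    return SpikeLog(
        lgn_neuron=ln,
        lgn_t_ms=lt * dt,
        cortex_neuron=cn,
        cortex_t_ms=ct * dt,
        duration_ms=duration_ms,
        n_lgn=n_lgn,
        n_cortex=n_ctx,
    )
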