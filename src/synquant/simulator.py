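"""Grid-based simulation of current-based LIF neurons with exponential PSCs.

The subthreshold system per neuron is linear,

    dI/dt = -I / tau_s
    C_m dV/dt = -C_m (V - E_L) / tau_m + I + I_dc,

and is propagated exactly from grid point to grid point (exact integration):
the one-step map is evaluated in closed form, and synaptic events add jumps
of size w (pA) to I at grid points.  Spikes are detected after propagation
(V >= V_theta), the membrane is reset and clamped for the refractory period
while the synaptic current keeps decaying and accumulating, and the spike
time is recorded at the post-step grid point.  All spike times are therefore
integer multiples of the resolution h.

External drive is an independent Poisson input per neuron: in each step a
Poisson count with mean K_ext * nu_ext * h is drawn and delivered (with a
one-step delay) as count * w_ext jumps to I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SynapseTable

__all__ = [
    "NeuronParams",
    "SimulationConfig",
    "SpikeRecord",
    "exact_propagator",
    "SimState",
    "step",
    "poisson_external_input",
    "initialize_membranes",
    "run",
]


@dataclass(frozen=True)
class NeuronParams:
    """Current-based LIF neuron with exponentially decaying PSCs.

    Units: capacitance pF, times ms, potentials mV, currents pA.
    """

    membrane_capacitance: float = 250.0
    membrane_time_constant: float = 10.0
    leak_reversal: float = -65.0
    threshold: float = -50.0
    reset: float = -65.0
    refractory_period: float = 2.0
    synaptic_time_constant: float = 0.5

    def __post_init__(self) -> None:
        if min(
            self.membrane_time_constant,
            self.synaptic_time_constant,
            self.membrane_capacitance,
        ) <= 0 or self.refractory_period < 0:
            raise ValueError("time constants and capacitance must be positive")
        if self.reset >= self.threshold:
            raise ValueError("reset potential must lie below threshold")

    @property
    def membrane_resistance(self) -> float:
        """R_m = tau_m / C_m in GOhm (mV per pA)."""
        return self.membrane_time_constant / self.membrane_capacitance


@dataclass(frozen=True)
class SimulationConfig:
    duration: float  # T_sim, ms
    resolution: float = 0.1  # h, ms
    transient: float = 1000.0  # T_trans, ms; discarded by the statistics layer
    seed: int = 0
    external_rate: float = 8.0  # nu_ext per external synapse, 1/s
    external_weight: float = 87.81  # w_ext, pA
    dc_current: float = 0.0  # constant input current, pA

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not self.transient < self.duration:
            raise ValueError("transient must be shorter than the duration")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.resolution))


@dataclass
class SpikeRecord:
    """Grid-aligned spike events over the full simulated interval.

    ``senders``/``times`` cover [0, T_sim); events before the startup
    transient remain in the record and are excluded by the statistics layer
    through the stored observation window.
    """

    senders: np.ndarray
    times: np.ndarray
    n_neurons: int
    resolution: float
    duration: float
    transient: float
    seed: int = 0

    @property
    def observation_window(self) -> tuple:
        return (self.transient, self.duration)

    def spike_trains(self, observed_only: bool = True) -> list:
        """Per-neuron sorted spike-time arrays."""
        t, s = self.times, self.senders
        if observed_only:
            keep = t >= self.transient
            t, s = t[keep], s[keep]
        order = np.lexsort((t, s))
        s, t = s[order], t[order]
        bounds = np.searchsorted(s, np.arange(self.n_neurons + 1))
        return [t[bounds[i] : bounds[i + 1]] for i in range(self.n_neurons)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.senders, "time_ms": self.times})

    def to_tsv(self, path) -> None:
        """Two-column event file with a commented metadata header."""
        with open(path, "w") as fh:
            fh.write(
                f"# n_neurons={self.n_neurons} resolution_ms={self.resolution} "
                f"duration_ms={self.duration} transient_ms={self.transient} "
                f"seed={self.seed}\n"
            )
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpikeRecord":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            df = pd.read_csv(fh, sep="\t")
        return cls(
            senders=df["neuron_id"].to_numpy(np.int64),
            times=df["time_ms"].to_numpy(float),
            n_neurons=int(meta["n_neurons"]),
            resolution=float(meta["resolution_ms"]),
            duration=float(meta["duration_ms"]),
            transient=float(meta["transient_ms"]),
            seed=int(meta["seed"]),
        )


@dataclass(frozen=True)
class Propagator:
    """Coefficients of the exact one-step map of the subthreshold system.

    I(t+h)        = p_ii * I(t)
    V(t+h) - E_L  = p_vv * (V(t) - E_L) + p_vi * I(t) + p_dc * I_dc
    """

    p_ii: float
    p_vv: float
    p_vi: float
    p_dc: float


def exact_propagator(params: NeuronParams, h: float) -> Propagator:
    """Closed-form one-step propagator; exact between current jumps.

    The degenerate case tau_m == tau_s (the propagator expression has a
    removable singularity there) is not supported.
    """
    tm, ts, cm = (
        params.membrane_time_constant,
        params.synaptic_time_constant,
        params.membrane_capacitance,
    )
    if tm == ts:
        raise ValueError("tau_m == tau_s is not supported by this propagator")
    p_ii = np.exp(-h / ts)
    p_vv = np.exp(-h / tm)
    p_vi = (p_ii - p_vv) * tm * ts / ((ts - tm) * cm)
    p_dc = params.membrane_resistance * (1.0 - p_vv)
    return Propagator(float(p_ii), float(p_vv), float(p_vi), float(p_dc))


@dataclass
class SimState:
    """Mutable per-neuron state advanced by :func:`step`."""

    v: np.ndarray  # membrane potential, mV
    i_syn: np.ndarray  # synaptic current, pA
    refractory: np.ndarray  # remaining refractory steps (int)


def step(
    state: SimState,
    params: NeuronParams,
    prop: Propagator,
    delivered: np.ndarray,
    h: float,
    dc_current: float = 0.0,
) -> np.ndarray:
    """Advance the network by one grid step; returns the spike mask.

    ``delivered`` holds the summed weights (pA) of all synaptic events due
    at this grid point, per neuron; they jump I before propagation.
    Refractory neurons keep V clamped at reset (the current still decays
    and accumulates), threshold is checked after propagation, and reset is
    applied within the same step.
    """
    state.i_syn += delivered
    active = state.refractory == 0
    el = params.leak_reversal
    v_new = el + prop.p_vv * (state.v - el) + prop.p_vi * state.i_syn
    if dc_current != 0.0:
        v_new += prop.p_dc * dc_current
    state.v = np.where(active, v_new, params.reset)
    state.i_syn *= prop.p_ii
    spikes = active & (state.v >= params.threshold)
    if spikes.any():
        state.v[spikes] = params.reset
        state.refractory[spikes] = _refractory_steps(params, h)
    state.refractory[state.refractory > 0] -= 1
    return spikes


def _refractory_steps(params: NeuronParams, h: float) -> int:
    return int(round(params.refractory_period / h))


def poisson_external_input(
    k_ext: np.ndarray,
    nu_ext: float,
    w_ext: float,
    n_steps: int,
    h: float,
    rng: np.random.Generator,
):
    """Generator of per-step external current jumps (pA) per neuron.

    Each neuron receives k_ext independent Poisson spike trains of rate
    nu_ext (1/s); per step the pooled count is Poisson(k_ext * nu_ext * h).
    """
    lam = np.asarray(k_ext, dtype=float) * nu_ext * h * 1e-3
    if np.any(lam < 0):
        raise ValueError("external rate must be >= 0")
    for _ in range(n_steps):
        yield rng.poisson(lam) * w_ext


def initialize_membranes(
    populations, rng: np.random.Generator
) -> np.ndarray:
    """Initial V per neuron, normal per population (reduces startup transients)."""
    parts = [
        rng.normal(p.v0_mean, p.v0_std, size=p.size) if p.v0_std > 0
        else np.full(p.size, p.v0_mean)
        for p in populations
    ]
    return np.concatenate(parts)


def _csr_by_source(table: SynapseTable, n_neurons: int, h: float):
    """Synapses grouped by source id for fast spike delivery."""
    order = np.argsort(table.source_id, kind="stable")
    src = table.source_id[order]
    indptr = np.searchsorted(src, np.arange(n_neurons + 1))
    targets = table.target_id[order].astype(np.int64)
    weights = table.weight[order].astype(float)
    dsteps = np.maximum(np.rint(table.delay[order] / h).astype(np.int64), 1)
    return indptr, targets, weights, dsteps


def run(
    table: SynapseTable,
    params: NeuronParams,
    config: SimulationConfig,
    populations,
) -> SpikeRecord:
    """Simulate the network over [0, T_sim) and record all spikes.

    Spike transmission uses a ring buffer of future current jumps indexed by
    delay (delays are rounded to the grid, minimum one step).  Randomness
    (initial membrane potentials, external Poisson input) derives from
    ``config.seed`` via independent substreams, so identical inputs yield
    identical records.
    """
    n = sum(p.size for p in populations)
    if len(table) and (table.target_id.max() >= n or table.source_id.max() >= n):
        raise ValueError("synapse table references neurons outside the populations")
    h = config.resolution
    n_steps = config.n_steps
    prop = exact_propagator(params, h)
    ref_steps = _refractory_steps(params, h)

    ss_init, ss_ext = np.random.SeedSequence(config.seed).spawn(2)
    rng_init = np.random.default_rng(ss_init)
    rng_ext = np.random.default_rng(ss_ext)

    state = SimState(
        v=initialize_membranes(populations, rng_init),
        i_syn=np.zeros(n),
        refractory=np.zeros(n, dtype=np.int64),
    )

    indptr, tgt, wgt, dsteps = _csr_by_source(table, n, h)
    max_delay = int(dsteps.max()) if len(dsteps) else 1
    buf_len = max_delay + 1
    buffer = np.zeros((buf_len, n))

    k_ext = np.concatenate(
        [np.full(p.size, p.external_in_degree, dtype=float) for p in populations]
    )
    lam = k_ext * config.external_rate * h * 1e-3
    has_ext = config.external_rate > 0 and np.any(lam > 0)

    el = params.leak_reversal
    p_vv, p_vi, p_ii, p_dc = prop.p_vv, prop.p_vi, prop.p_ii, prop.p_dc
    dc = config.dc_current
    v_th, v_reset = params.threshold, params.reset

    sender_chunks, time_chunks = [], []
    refr = state.refractory
    v = state.v
    i_syn = state.i_syn
    # external Poisson counts are drawn in blocks to amortize RNG overhead;
    # the event stream is identical to per-step draws with the same generator
    ext_chunk = 2000
    ext_block, ext_pos = None, ext_chunk
    w_ext = config.external_weight
    for t in range(n_steps):
        slot = t % buf_len
        i_syn += buffer[slot]
        buffer[slot] = 0.0

        inactive = refr > 0
        v -= el
        v *= p_vv
        v += el
        v += p_vi * i_syn
        if dc != 0.0:
            v += p_dc * dc
        v[inactive] = v_reset
        i_syn *= p_ii

        spikes = v >= v_th
        if spikes.any():
            spikes &= ~inactive
            ids = np.nonzero(spikes)[0]
            if len(ids):
                v[ids] = v_reset
                # the decrement below only touches neurons refractory at the
                # start of the step, so R-1 remaining steps reproduces a
                # clamp of exactly tau_ref after the spike
                refr[ids] = max(ref_steps - 1, 0)
                sender_chunks.append(ids)
                time_chunks.append(np.full(len(ids), (t + 1) * h))
                for j in ids:
                    a, b = indptr[j], indptr[j + 1]
                    if a != b:
                        np.add.at(
                            buffer,
                            ((t + dsteps[a:b]) % buf_len, tgt[a:b]),
                            wgt[a:b],
                        )
        refr[inactive] -= 1

        if has_ext:
            if ext_pos == ext_chunk:
                m = min(ext_chunk, n_steps - t)
                ext_block = rng_ext.poisson(lam, size=(m, n))
                ext_pos = 0
            buffer[(t + 1) % buf_len] += ext_block[ext_pos] * w_ext
            ext_pos += 1

        if t % 100000 == 0 and not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite membrane potential at step {t}")
    state.v = v

    if not np.all(np.isfinite(state.v)):
        raise FloatingPointError("non-finite membrane potential at end of run")
    senders = (
        np.concatenate(sender_chunks) if sender_chunks else np.empty(0, np.int64)
    )
    times = np.concatenate(time_chunks) if time_chunks else np.empty(0, float)
    order = np.argsort(times, kind="stable")
    return SpikeRecord(
        senders=senders[order],
        times=times[order],
        n_neurons=n,
        resolution=h,
        duration=config.duration,
        transient=config.transient,
        seed=config.seed,
    )
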