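"""Expand the type-level connectome into neuron pools and run the simulation.

Each neuron type becomes a pool of identical conductance-based LIF neurons
(default 10).  A type-to-type synapse becomes an all-to-all projection with
the same per-contact maximal conductance, so the total conductance a
postsynaptic neuron receives from a pool is G_max times the sum of the
presynaptic gating variables — the engine therefore tracks one outgoing
gating variable per presynaptic neuron and aggregates at pool level, which
is exact for all-to-all projections with shared receptor kinetics.

The inner loop is compiled with numba.  Update order within a step:
external Poisson inputs -> gating (decay, then spike increments from the
previous step) -> synaptic currents -> membrane integration and threshold.
State units: mV, ms, uS, nA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

from ebpb.config import ModelConfig, default_config
from ebpb.connectome import Connectome, NeuronTypeSpec, RING_CLASSES

E_GABA_MV = -70.0
MAX_SPIKES_PER_S_PER_NEURON = 600.0  # capacity heuristic for spike buffers


@dataclass
class Population:
    type_spec: NeuronTypeSpec
    size: int
    C_m_nF: float
    tau_m_ms: float
    lo: int  # first flat neuron index
    hi: int  # one past last

    @property
    def name(self) -> str:
        return self.type_spec.name


@dataclass
class Network:
    connectome: Connectome
    populations: List[Population]
    config: ModelConfig
    pool_size: int
    # flat per-neuron arrays
    C_m: np.ndarray
    g_L: np.ndarray
    # pool-level weight matrices in uS: W[post_pool, pre_pool]
    W_nmda: np.ndarray
    W_gaba: np.ndarray
    out_decay: np.ndarray      # per-neuron gating decay factor placeholder tau
    out_tau: np.ndarray        # per-neuron output gating tau (ms)
    is_nmda_out: np.ndarray    # bool per neuron

    @property
    def n_neurons(self) -> int:
        return len(self.C_m)

    def pool_index(self, name: str) -> int:
        for i, p in enumerate(self.populations):
            if p.name == name:
                return i
        raise KeyError(name)

    def pools_of_class(self, neuron_class: str) -> List[Population]:
        return [p for p in self.populations
                if p.type_spec.neuron_class == neuron_class]


@dataclass
class SpikeData:
    """Spike record of one simulation: parallel (neuron_id, time) arrays."""

    neuron_ids: np.ndarray
    times_ms: np.ndarray
    T_total_ms: float
    pool_slices: Dict[str, Tuple[int, int]]
    pool_size: int
    seed: int
    meta: dict = field(default_factory=dict)

    def pool_times(self, pool_name: str) -> np.ndarray:
        """All spike times of a pool, sorted (per-pool aggregate)."""
        lo, hi = self.pool_slices[pool_name]
        m = (self.neuron_ids >= lo) & (self.neuron_ids < hi)
        return np.sort(self.times_ms[m])

    def neuron_times(self, neuron_id: int) -> np.ndarray:
        return np.sort(self.times_ms[self.neuron_ids == neuron_id])

    def total_spikes(self) -> int:
        return len(self.times_ms)

    def write(self, path_prefix: str) -> None:
        """Two-column text table plus a JSON sidecar."""
        with open(path_prefix + ".spikes.tsv", "w") as fh:
            fh.write("neuron_id\ttime_ms\n")
            for nid, t in zip(self.neuron_ids, self.times_ms):
                fh.write(f"{nid}\t{t:.3f}\n")
        sidecar = dict(seed=int(self.seed), T_total_ms=self.T_total_ms,
                       pool_size=self.pool_size,
                       pool_slices={k: list(v) for k, v in self.pool_slices.items()},
                       **{k: v for k, v in self.meta.items()
                          if isinstance(v, (int, float, str))})
        with open(path_prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def assemble_network(connectome: Connectome,
                     config: Optional[ModelConfig] = None,
                     pool_size: Optional[int] = None) -> Network:
    """Instantiate pools and pool-level weight matrices from a connectome."""
    cfg = config or default_config()
    size = cfg.pool_size if pool_size is None else pool_size
    if size < 1:
        raise ValueError("pool_size must be >= 1")

    pops: List[Population] = []
    lo = 0
    for t in connectome.types:
        params = cfg.neuron_params_for(t.neuron_class)
        pops.append(Population(t, size, params.C_m_nF, params.tau_m_ms,
                               lo, lo + size))
        lo += size
    n = lo
    n_pools = len(pops)

    C_m = np.empty(n)
    g_L = np.empty(n)
    out_tau = np.empty(n)
    is_nmda = np.zeros(n, dtype=np.bool_)
    tau_nmda = cfg.receptors["NMDA"].tau_ms
    tau_gaba = cfg.receptors["GABA_A"].tau_ms
    for p in pops:
        C_m[p.lo:p.hi] = p.C_m_nF
        g_L[p.lo:p.hi] = p.C_m_nF / p.tau_m_ms
        excitatory = p.type_spec.transmitter == "excitatory_NMDA"
        is_nmda[p.lo:p.hi] = excitatory
        out_tau[p.lo:p.hi] = tau_nmda if excitatory else tau_gaba

    pool_of_type = {(t.neuron_class, t.type_index): i
                    for i, t in enumerate(connectome.types)}
    Wn = np.zeros((n_pools, n_pools))
    Wg = np.zeros((n_pools, n_pools))
    for s in connectome.synapses:
        pre = pool_of_type[(s.pre.neuron_class, s.pre.type_index)]
        post = pool_of_type[(s.post.neuron_class, s.post.type_index)]
        g_uS = s.G_max_nS * 1e-3
        if s.receptor == "NMDA":
            Wn[post, pre] += g_uS * cfg.nmda_weight_scale
        elif s.receptor == "GABA_A":
            Wg[post, pre] += g_uS
        else:
            raise ValueError(f"unexpected internal receptor {s.receptor}")

    return Network(connectome, pops, cfg, size, C_m, g_L, Wn, Wg,
                   out_decay=np.exp(-cfg.dt_ms / out_tau),
                   out_tau=out_tau, is_nmda_out=is_nmda)


# ---------------------------------------------------------------------------
# external drive resolution
# ---------------------------------------------------------------------------

def poisson_drive(rate_hz: float, dt_ms: float, rng: np.random.Generator) -> int:
    """Event count in one step; long-run mean = rate * time."""
    if rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    return int(rng.poisson(rate_hz * dt_ms / 1000.0))


def _resolve_targets(network: Network, target: Tuple) -> np.ndarray:
    """Flat neuron indices selected by an epoch target spec."""
    kind = target[0]
    idx: List[int] = []
    for p in network.populations:
        t = p.type_spec
        if kind == "pb_region":
            if any(r.neuropil == "PB" and r.label == target[1]
                   for r in t.dendritic_regions):
                idx.extend(range(p.lo, p.hi))
        elif kind == "pb_side":
            if any(r.neuropil == "PB" and r.label.startswith(target[1])
                   for r in t.dendritic_regions):
                idx.extend(range(p.lo, p.hi))
        elif kind == "class":
            if t.neuron_class == target[1]:
                idx.extend(range(p.lo, p.hi))
        elif kind == "type":
            if t.neuron_class == target[1] and t.type_index == target[2]:
                idx.extend(range(p.lo, p.hi))
        else:
            raise ValueError(f"unknown target kind {kind!r}")
    return np.asarray(idx, dtype=np.int64)


# ---------------------------------------------------------------------------
# compiled core
# ---------------------------------------------------------------------------

@njit(cache=False)
def _run_core(n_steps, dt, N, n_pools, pool_of,
              V, C_m, g_L, V_L, V_th, V_reset, refr_ms, I_inj,
              out_decay, is_nmda_out, alpha, saturation_on,
              Wn, Wg, mg_on, mg_conc, e_gaba,
              ext_decay,
              ep_start_step, ep_end_step, ep_ptr, ep_targets, ep_lam, ep_g,
              seed,
              spike_nid, spike_t):
    np.random.seed(seed)
    n_ep = len(ep_start_step)
    s_out = np.zeros(N)
    c_ext = np.zeros(N)
    refr_until = np.full(N, -1.0)
    spiked = np.zeros(N, np.bool_)
    S = np.zeros(n_pools)
    gN = np.zeros(n_pools)
    gG = np.zeros(n_pools)
    n_spk = 0
    cap = len(spike_nid)

    for step in range(n_steps):
        t = step * dt
        # 1. external Poisson inputs
        for i in range(N):
            c_ext[i] *= ext_decay
        for e in range(n_ep):
            if ep_start_step[e] <= step < ep_end_step[e]:
                lam = ep_lam[e]
                g = ep_g[e]
                for j in range(ep_ptr[e], ep_ptr[e + 1]):
                    k = np.random.poisson(lam)
                    if k > 0:
                        c_ext[ep_targets[j]] += g * k
        # 2. gating: decay then increments from last step's spikes
        for i in range(N):
            s_out[i] *= out_decay[i]
            if spiked[i]:
                if is_nmda_out[i]:
                    if saturation_on:
                        s_out[i] += alpha * (1.0 - s_out[i])
                    else:
                        s_out[i] += alpha
                else:
                    s_out[i] += 1.0
        # 3. pool sums and input conductances
        for p in range(n_pools):
            S[p] = 0.0
        for i in range(N):
            S[pool_of[i]] += s_out[i]
        for p in range(n_pools):
            a = 0.0
            b = 0.0
            for q in range(n_pools):
                a += Wn[p, q] * S[q]
                b += Wg[p, q] * S[q]
            gN[p] = a
            gG[p] = b
        # 4-5. currents and membrane update
        for i in range(N):
            if t < refr_until[i]:
                V[i] = V_reset
                spiked[i] = False
                continue
            g_nm = gN[pool_of[i]]
            if mg_on:
                g_nm = g_nm / (1.0 + mg_conc * np.exp(-0.062 * V[i] / 3.57))
            I_syn = (g_nm + c_ext[i]) * V[i] + gG[pool_of[i]] * (V[i] - e_gaba)
            V[i] += dt / C_m[i] * (-g_L[i] * (V[i] - V_L) - I_syn + I_inj[i])
            if not np.isfinite(V[i]):
                return -2 - i  # numerical fault marker, neuron encoded
            if V[i] >= V_th:
                spiked[i] = True
                V[i] = V_reset
                refr_until[i] = t + dt + refr_ms
                if n_spk >= cap:
                    return -1  # buffer overflow
                spike_nid[n_spk] = i
                spike_t[n_spk] = t + dt
                n_spk += 1
            else:
                spiked[i] = False
    return n_spk


class SimulationFault(RuntimeError):
    pass


def run(network: Network, protocol, T_total_ms: Optional[float] = None,
        dt_ms: Optional[float] = None, seed: int = 0) -> SpikeData:
    """Run a protocol on an assembled network.

    Deterministic given (network, protocol, dt, seed).  Initial membrane
    potentials sit at the resting potential (optionally jittered via
    config).  Returns the full spike record.
    """
    cfg = network.config
    dt = cfg.dt_ms if dt_ms is None else dt_ms
    T = protocol.T_total_ms if T_total_ms is None else T_total_ms
    n_steps = int(round(T / dt))
    N = network.n_neurons
    n_pools = len(network.populations)

    params0 = cfg.neuron_params_for("default")
    V_L, V_th = params0.V_L_mV, params0.V_th_mV
    V_reset, refr = params0.V_reset_mV, params0.refractory_ms
    for p in network.populations:
        q = cfg.neuron_params_for(p.type_spec.neuron_class)
        if (q.V_L_mV, q.V_th_mV, q.V_reset_mV, q.refractory_ms) != \
           (V_L, V_th, V_reset, refr):
            raise NotImplementedError(
                "per-class V_L/V_th/V_reset/refractory not supported")

    pool_of = np.empty(N, dtype=np.int64)
    for i, p in enumerate(network.populations):
        pool_of[p.lo:p.hi] = i

    # lesions -> injected currents
    I_inj = np.zeros(N)
    for cls, cur in protocol.lesions.items():
        for p in network.populations:
            if p.type_spec.neuron_class == cls:
                I_inj[p.lo:p.hi] = cur

    # epochs -> flat arrays (targets resolved, rates per neuron and per step)
    starts, ends, ptr, targets, lams, gs = [], [], [0], [], [], []
    for e in protocol.epochs:
        tgt = _resolve_targets(network, e.target)
        if len(tgt) == 0:
            continue  # class absent from this circuit variant
        rate = e.rate_hz / network.pool_size if e.pool_total else e.rate_hz
        g_ns = e.g_max_ns
        if e.group in ("cue", "rotation"):
            g_ns = g_ns * cfg.ach_weight_scale
        starts.append(int(np.floor(e.t_start_ms / dt)))
        ends.append(int(np.ceil(e.t_end_ms / dt)))
        targets.extend(tgt.tolist())
        ptr.append(len(targets))
        lams.append(rate * dt / 1000.0)
        gs.append(g_ns * 1e-3)  # uS

    rng = np.random.default_rng(seed)
    V0 = np.full(N, V_L)
    if cfg.init_jitter_mV > 0:
        V0 += rng.uniform(-cfg.init_jitter_mV, cfg.init_jitter_mV, N)

    cap = int(MAX_SPIKES_PER_S_PER_NEURON * N * max(T, 1000.0) / 1000.0)
    spike_nid = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap)

    nmda = cfg.receptors["NMDA"]
    core_seed = int(rng.integers(0, 2**31 - 1))
    n_spk = _run_core(
        n_steps, dt, N, n_pools, pool_of,
        V0, network.C_m, network.g_L, V_L, V_th, V_reset, refr, I_inj,
        np.exp(-dt / network.out_tau), network.is_nmda_out,
        nmda.alpha, nmda.saturation_enabled,
        network.W_nmda, network.W_gaba,
        nmda.mg_block_enabled, nmda.Mg_conc, E_GABA_MV,
        float(np.exp(-dt / cfg.receptors["ACh"].tau_ms)),
        np.asarray(starts, np.int64), np.asarray(ends, np.int64),
        np.asarray(ptr, np.int64), np.asarray(targets, np.int64),
        np.asarray(lams), np.asarray(gs),
        core_seed, spike_nid, spike_t)

    if n_spk == -1:
        raise SimulationFault("spike buffer overflow (runaway activity)")
    if n_spk < -1:
        raise SimulationFault(f"non-finite state at neuron {-(n_spk + 2)}")

    order = np.argsort(spike_t[:n_spk], kind="stable")
    slices = {p.name: (p.lo, p.hi) for p in network.populations}
    return SpikeData(spike_nid[:n_spk][order].copy(),
                     spike_t[:n_spk][order].copy(), T, slices,
                     network.pool_size, seed,
                     meta={"dt_ms": dt, "label": getattr(protocol, "label", ""),
                           "circuit": getattr(protocol, "circuit", "")})
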