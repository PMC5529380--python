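"""Leaky integrate-and-fire neuron and synaptic receptor kinetics.

Units: potentials mV, time ms, capacitance nF, conductance uS (helpers accept
nS where noted), current nA.  With these units nF/ms = uS and uS*mV = nA, so
the membrane equation

    C_m dV/dt = -g_L (V - V_L) - sum_j I_j + I_inject

integrates without conversion factors.

The three receptor models:

* ACh and GABA_A: first-order gating, ds/dt = -s/tau + sum_k delta(t - t_k),
  i.e. +1 per presynaptic spike, no bound.
* NMDA: saturating gating ds/dt = -s/tau + alpha (1 - s) sum_k delta(t - t_k)
  with alpha = 0.63, and a voltage-dependent conductance implementing the
  magnesium block, g(V) = G / (1 + [Mg] exp(-0.062 V / 3.57)).

The functions here are scalar/ndarray pure functions; the simulation engine
replicates exactly this arithmetic in its compiled inner loop, and the test
suite holds the two implementations together.
"""

from __future__ import annotations

import math
from typing import Tuple, Union

import numpy as np

from ebpb.config import NeuronParams

ArrayLike = Union[float, np.ndarray]


def membrane_step(V: ArrayLike, params: NeuronParams, I_syn_total: ArrayLike,
                  dt: float, refractory: ArrayLike = False
                  ) -> Tuple[ArrayLike, ArrayLike]:
    """One forward-Euler step of the membrane equation.

    ``I_syn_total`` is the total synaptic current in nA with the convention
    that positive current is outward (it is subtracted); the injected
    current ``params.I_inject_nA`` enters with the opposite sign, so a
    negative injection hyperpolarizes.  Returns ``(V_next, spiked)``;
    a spiking neuron is reset to ``V_reset`` (the caller holds it there for
    the refractory period, signalled through ``refractory``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_L = params.g_L_uS
    dV = (dt / params.C_m_nF) * (-g_L * (np.asarray(V) - params.V_L_mV)
                                 - I_syn_total + params.I_inject_nA)
    V_next = np.where(refractory, params.V_reset_mV, V + dV)
    if not np.all(np.isfinite(V_next)):
        raise FloatingPointError("non-finite membrane potential")
    spiked = (V_next >= params.V_th_mV) & ~np.asarray(refractory, bool)
    V_next = np.where(spiked, params.V_reset_mV, V_next)
    if np.isscalar(V) or np.ndim(V) == 0:
        return float(V_next), bool(spiked)
    return V_next, spiked


def lif_isi_closed_form(params: NeuronParams, I0_nA: float) -> float:
    """Interspike interval (ms) of a LIF neuron under constant input current.

    Closed form T = t_ref + tau_m ln((V_inf - V_reset)/(V_inf - V_th)) with
    V_inf = V_L + I0/g_L; infinite if V_inf <= V_th.  Serves as the
    analytical oracle for the integrator.
    """
    V_inf = params.V_L_mV + I0_nA / params.g_L_uS
    if V_inf <= params.V_th_mV:
        return math.inf
    T = params.tau_m_ms * math.log(
        (V_inf - params.V_reset_mV) / (V_inf - params.V_th_mV))
    return T + params.refractory_ms


def gating_step_first_order(s: ArrayLike, tau: float, spikes_in_step: ArrayLike,
                            dt: float) -> ArrayLike:
    """Exponential decay over dt plus +1 per presynaptic spike (ACh/GABA_A)."""
    return np.asarray(s) * math.exp(-dt / tau) + spikes_in_step


def gating_step_nmda(s: ArrayLike, alpha: float, tau: float,
                     spikes_in_step: ArrayLike, dt: float,
                     saturation_enabled: bool = True) -> ArrayLike:
    """NMDA gating step: decay, then per-spike increment alpha*(1-s).

    Multiple spikes within one step are applied sequentially in arrival
    order, so k spikes take s to 1 - (1-alpha)^k (1-s).  With saturation
    disabled the (1-s) factor is dropped and each spike adds alpha.
    """
    s = np.asarray(s, dtype=float) * math.exp(-dt / tau)
    k = np.asarray(spikes_in_step)
    if saturation_enabled:
        out = 1.0 - (1.0 - alpha) ** k * (1.0 - s)
    else:
        out = s + alpha * k
    return float(out) if out.ndim == 0 else out


def nmda_conductance(G_max: ArrayLike, V: ArrayLike, Mg_conc: float = 1.0,
                     mg_block_enabled: bool = True) -> ArrayLike:
    """Voltage-dependent NMDA conductance g = G/(1 + [Mg] e^(-0.062 V/3.57)).

    With the block disabled (or [Mg] = 0) the full conductance passes.
    ``G_max`` and the result share whatever conductance unit is supplied.
    """
    if not mg_block_enabled:
        return np.asarray(G_max) if np.ndim(G_max) else G_max
    block = 1.0 + Mg_conc * np.exp(-0.062 * np.asarray(V) / 3.57)
    out = np.asarray(G_max) / block
    return float(out) if np.ndim(out) == 0 else out


def synaptic_current(g: ArrayLike, s: ArrayLike, V: ArrayLike,
                     E_rev: float) -> ArrayLike:
    """I = g * s * (V - E_rev); positive = outward (hyperpolarizing)."""
    out = np.asarray(g) * s * (np.asarray(V) - E_rev)
    return float(out) if np.ndim(out) == 0 else out
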