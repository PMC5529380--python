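"""Model configuration: neuron, receptor, wiring and simulation parameters.

All parameters carry the units stated in their field names (nF, ms, mV, nS,
Hz, nA).  The synaptic base weights are the free parameters of the model:
anatomy fixes only the wiring rule and the proportionality of each
connection to its region overlap, so the per-channel conductance scale is
found by calibration against the circuit-level contracts (bump persistence,
width, no-shift in the symmetric ring, rotation gain) and shipped here as the
package default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import yaml

# (pre_class, post_class) -> per-overlap conductance in nS.
# Calibrated defaults; see docs/methods.md for the calibration procedure.
DEFAULT_BASE_WEIGHTS: Dict[Tuple[str, str], float] = {
    ("EIP", "PEI"): 2.3,
    ("EIP", "PEN"): 2.2,
    ("PEI", "EIP"): 1.63,
    ("PEN", "EIP"): 3.5,
    ("EIP", "R_EIP"): 0.2,
    ("R_EIP", "EIP"): 7.0,
    ("R_PEI", "PEI"): 2.5,
    ("R_PEN", "PEN"): 2.5,
}


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire parameters for one neuron class."""

    C_m_nF: float = 0.1
    tau_m_ms: float = 15.0
    V_L_mV: float = -70.0
    V_th_mV: float = -50.0
    V_reset_mV: float = -70.0
    refractory_ms: float = 2.0
    I_inject_nA: float = 0.0

    @property
    def g_L_uS(self) -> float:
        """Leak conductance in uS (= nF / ms)."""
        return self.C_m_nF / self.tau_m_ms

    def __post_init__(self) -> None:
        if not (self.V_reset_mV <= self.V_L_mV < self.V_th_mV):
            raise ValueError("require V_reset <= V_L < V_th")
        if self.tau_m_ms <= 0:
            raise ValueError("tau_m must be positive")


@dataclass
class ReceptorParams:
    """Synaptic receptor kinetics.

    NMDA carries the voltage-dependent magnesium block and the saturating
    gating variable; ACh and GABA_A use plain first-order gating.
    """

    kind: str = "ACh"
    tau_ms: float = 20.0
    E_rev_mV: float = 0.0
    alpha: float = 0.63           # NMDA only
    Mg_conc: float = 1.0          # NMDA only, dimensionless factor as printed
    mg_block_enabled: bool = True
    saturation_enabled: bool = True


def default_receptors() -> Dict[str, ReceptorParams]:
    return {
        "ACh": ReceptorParams(kind="ACh", tau_ms=20.0, E_rev_mV=0.0),
        "NMDA": ReceptorParams(kind="NMDA", tau_ms=100.0, E_rev_mV=0.0),
        "GABA_A": ReceptorParams(kind="GABA_A", tau_ms=5.0, E_rev_mV=-70.0),
    }


@dataclass
class ModelConfig:
    """Complete parameter set for one simulation."""

    dt_ms: float = 0.1
    pool_size: int = 10
    base_weights: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS))
    neuron_params: Dict[str, NeuronParams] = field(default_factory=lambda: {
        "default": NeuronParams(C_m_nF=0.1),
        "R_EIP": NeuronParams(C_m_nF=0.01),
    })
    receptors: Dict[str, ReceptorParams] = field(default_factory=default_receptors)

    # NMDA variants used by the kinetics experiments
    nmda_weight_scale: float = 1.0
    ach_weight_scale: float = 1.0

    # connectome options
    dual_offset: int = 0          # tiling of the 8 dual regions (0 = R8L8 is a dual)

    # stimulus defaults
    cue_rate_hz: float = 50.0
    cue_g_ns: float = 2.1
    unilateral_rate_hz: float = 3150.0   # total over the pool's upstream group
    unilateral_g_ns: float = 0.3
    ring_drive_rate_hz: float = 200.0
    ring_drive_g_ns: float = 10.0
    r_eip_drive_rate_hz: float = 0.0     # R_EIP is driven by EIP feedback
    r_eip_drive_g_ns: float = 10.0
    lesion_current_nA: float = -0.5
    dim_cue_fraction: float = 0.6        # weaker cue rate, two-cue task
    pre_cessation_ms: float = 150.0
    rotation_speed_deg_s: float = 58.5

    # analysis defaults
    rate_kernel_d_ms: float = 721.5      # 500 ms half-life
    fit_interval_ms: float = 100.0
    bump_min_height: float = 1.0         # kernel-rate units, detection threshold
    bump_fit_baseline: bool = True
    loss_angle_deg: float = 45.0         # "lost track" when > this for > loss_time
    loss_time_ms: float = 1000.0

    # engine details
    init_jitter_mV: float = 0.0
    synaptic_delay_ms: float = 0.0

    def neuron_params_for(self, class_name: str) -> NeuronParams:
        return self.neuron_params.get(class_name, self.neuron_params["default"])

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_weights"] = {"%s->%s" % k: v for k, v in self.base_weights.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        bw = {}
        for k, v in d.pop("base_weights", {}).items():
            pre, post = k.split("->")
            bw[(pre, post)] = float(v)
        np_ = {name: NeuronParams(**p) for name, p in d.pop("neuron_params", {}).items()}
        rc = {name: ReceptorParams(**p) for name, p in d.pop("receptors", {}).items()}
        cfg = cls(**d)
        if bw:
            cfg.base_weights = bw
        if np_:
            cfg.neuron_params = np_
        if rc:
            cfg.receptors = rc
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config() -> ModelConfig:
    return ModelConfig()
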