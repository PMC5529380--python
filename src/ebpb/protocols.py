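"""Stimulus schedules: visual cues, simulated body rotation, ring-neuron
gating, lesions, and the random walk, together with the ground-truth
orientation trace.

Conventions
-----------
The 16 EB wedges map homogeneously onto 360 deg of azimuth; wedge ``w`` at
circular position ``p`` (see :mod:`ebpb.connectome`) is centered at
``22.5 * p`` degrees and owns the 22.5 deg arc around that center.  The
anchor: a cue at 40 deg falls in wedge R2 and is delivered to PB R5 and L3.

"Clockwise" motion decreases azimuth.  A counterclockwise body rotation is
simulated by unilateral input to the right PB (R0-R8) and moves the bump
clockwise; a clockwise rotation drives the left PB.  The ground-truth trace
stores the *expected bump azimuth* over time, so during a CCW body rotation
its slope is -58.5 deg/s and during CW it is +58.5 deg/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ebpb.config import ModelConfig, default_config
from ebpb.connectome import (EB_WEDGE_ORDER, N_WEDGES, RegionID,
                             dual_of_wedge, eb, pb, pei_dual_index)

WEDGE_DEG = 360.0 / N_WEDGES  # 22.5

CIRCUIT_CLASSES = {
    "c-ring": ("EIP", "PEI", "R_EIP"),
    "p-ring": ("EIP", "PEN", "R_EIP"),
    "full": ("EIP", "PEI", "PEN", "R_EIP", "R_PEI", "R_PEN"),
}


# ---------------------------------------------------------------------------
# azimuth <-> region mapping
# ---------------------------------------------------------------------------

def position_to_azimuth(position: int | float) -> float:
    """Azimuth (deg) of a circular wedge position.

    The map is anchored so that wedge R2 (position 2) owns the arc around
    45 deg (a cue at 40 deg falls in it), and oriented so that unilateral
    drive to the right PB moves the activity bump clockwise (toward
    decreasing azimuth), matching the simulated rotation response.
    """
    return (90.0 - WEDGE_DEG * position) % 360.0


def azimuth_to_position(angle_deg: float) -> int:
    return int(np.floor((90.0 - angle_deg) / WEDGE_DEG + 0.5)) % N_WEDGES


def azimuth_to_eb_region(angle_deg: float) -> RegionID:
    """EB wedge whose 22.5 deg receptive arc contains the azimuth."""
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    return eb(EB_WEDGE_ORDER[azimuth_to_position(angle_deg)])


def wedge_center_deg(wedge: RegionID) -> float:
    return position_to_azimuth(wedge.position)


def cue_to_pb_targets(wedge: RegionID, dual_offset: int = 0
                      ) -> Tuple[RegionID, RegionID]:
    """The two bilateral PB glomeruli whose PEI types feed the wedge's dual.

    A static cue must enter through both hemispheres at once: the two PEI
    pathways converge symmetrically on the same dual region, whereas a
    one-sided input would engage the shifter and move the bump.
    """
    if wedge.neuropil != "EB":
        raise ValueError("expected an EB wedge")
    d = dual_of_wedge(wedge, dual_offset)
    g_right = next(g for g in range(8) if pei_dual_index("R", g) == d)
    g_left = next(g for g in range(8) if pei_dual_index("L", g) == d)
    return pb(f"R{g_right}"), pb(f"L{g_left}")


# ---------------------------------------------------------------------------
# protocol data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputEpoch:
    """A timed Poisson drive to a set of target populations.

    ``target`` selects populations: ``("pb_region", "R5")`` hits every pool
    with a dendrite in that glomerulus, ``("class", "R_PEN")`` a whole class,
    ``("type", "EIP", 3)`` one pool.  ``pool_total`` marks rates quoted as
    the summed input over a pool's upstream group (divided by pool size at
    resolution); otherwise the rate is per neuron.
    """

    target: Tuple
    rate_hz: float
    g_max_ns: float
    t_start_ms: float
    t_end_ms: float
    receptor: str = "ACh"
    pool_total: bool = False
    group: str = "cue"  # cue | rotation | ring; ACh weight scaling applies
                        # to cue and rotation drives only

    def __post_init__(self):
        if self.t_start_ms >= self.t_end_ms:
            raise ValueError("epoch must have t_start < t_end")
        if self.rate_hz < 0:
            raise ValueError("rate must be nonnegative")


@dataclass
class OrientationTrace:
    """Expected bump azimuth (deg) on a regular time grid (ms), unwrapped."""

    t_ms: np.ndarray
    azimuth_deg: np.ndarray

    def at(self, t_ms: np.ndarray) -> np.ndarray:
        return np.interp(t_ms, self.t_ms, self.azimuth_deg)


@dataclass
class Protocol:
    epochs: List[InputEpoch]
    truth: OrientationTrace
    T_total_ms: float
    circuit: str = "full"
    lesions: Dict[str, float] = field(default_factory=dict)  # class -> nA
    label: str = ""

    def validate(self) -> None:
        for e in self.epochs:
            if e.t_end_ms > self.T_total_ms + 1e-9 or e.t_start_ms < 0:
                raise ValueError("epoch outside [0, T_total]")
        # gating exclusivity: R_PEI and R_PEN drives may only overlap inside
        # the pre-cessation handover windows (both off there, by design)
        pei = [(e.t_start_ms, e.t_end_ms) for e in self.epochs
               if e.target == ("class", "R_PEI")]
        pen = [(e.t_start_ms, e.t_end_ms) for e in self.epochs
               if e.target == ("class", "R_PEN")]
        for a0, a1 in pei:
            for b0, b1 in pen:
                if max(a0, b0) < min(a1, b1):
                    raise ValueError("R_PEI and R_PEN drives overlap")


# ---------------------------------------------------------------------------
# epoch builders
# ---------------------------------------------------------------------------

def _cue_epochs(azimuth_deg: float, t0: float, t1: float, cfg: ModelConfig,
                rate_scale: float = 1.0) -> List[InputEpoch]:
    wedge = azimuth_to_eb_region(azimuth_deg)
    r, l = cue_to_pb_targets(wedge, cfg.dual_offset)
    rate = cfg.cue_rate_hz * rate_scale
    return [InputEpoch(("pb_region", r.label), rate, cfg.cue_g_ns, t0, t1),
            InputEpoch(("pb_region", l.label), rate, cfg.cue_g_ns, t0, t1)]


def make_rotation_epoch(direction: str, t_start_ms: float, duration_ms: float,
                        rate_hz: Optional[float] = None,
                        g_max_ns: Optional[float] = None,
                        config: Optional[ModelConfig] = None) -> InputEpoch:
    """Unilateral PB drive standing in for the self-motion signal.

    CCW body rotation drives the right glomeruli (R0-R8), CW the left.  The
    quoted rate is the total over the upstream group of each pool.
    """
    cfg = config or default_config()
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if direction not in ("CW", "CCW"):
        raise ValueError("direction must be CW or CCW")
    side = "R" if direction == "CCW" else "L"
    return InputEpoch(("pb_side", side),
                      cfg.unilateral_rate_hz if rate_hz is None else rate_hz,
                      cfg.unilateral_g_ns if g_max_ns is None else g_max_ns,
                      t_start_ms, t_start_ms + duration_ms,
                      pool_total=True, group="rotation")


def _ring_epoch(ring: str, t0: float, t1: float, cfg: ModelConfig
                ) -> Optional[InputEpoch]:
    if t1 - t0 <= 0:
        return None
    return InputEpoch(("class", ring), cfg.ring_drive_rate_hz,
                      cfg.ring_drive_g_ns, t0, t1, group="ring")


def _r_eip_epoch(T: float, cfg: ModelConfig) -> List[InputEpoch]:
    if cfg.r_eip_drive_rate_hz > 0:
        return [InputEpoch(("class", "R_EIP"), cfg.r_eip_drive_rate_hz,
                           cfg.r_eip_drive_g_ns, 0.0, T, group="ring")]
    return []


def _segments_to_epochs(segments: Sequence[Tuple[str, float]], t_walk0: float,
                        T: float, cfg: ModelConfig, azimuth0: float,
                        dt_truth_ms: float = 10.0
                        ) -> Tuple[List[InputEpoch], OrientationTrace]:
    """Convert (kind, duration_ms) segments into drive epochs + truth trace.

    ``kind`` is "forward", "CW" or "CCW".  Ring gating follows the handover
    rule: the R_PEN drive of a forward segment ends 150 ms before the next
    rotation starts, and the R_PEI drive of a rotation ends 150 ms before
    the rotation ends (clamped for very short segments).
    """
    pre = cfg.pre_cessation_ms
    speed = cfg.rotation_speed_deg_s
    epochs: List[InputEpoch] = []
    t = t_walk0
    bounds = []
    for kind, dur in segments:
        bounds.append((kind, t, t + dur))
        t += dur
    for i, (kind, t0, t1) in enumerate(bounds):
        if kind == "forward":
            next_is_rotation = (i + 1 < len(bounds)
                                and bounds[i + 1][0] != "forward")
            end = t1 - pre if next_is_rotation else t1
            ep = _ring_epoch("R_PEN", t0, max(t0, min(end, t1)), cfg)
            if ep:
                epochs.append(ep)
        else:
            epochs.append(make_rotation_epoch(kind, t0, t1 - t0, config=cfg))
            ep = _ring_epoch("R_PEI", t0, max(t0, t1 - pre), cfg)
            if ep:
                epochs.append(ep)
    # truth trace over [0, T]
    tt = np.arange(0.0, T + dt_truth_ms / 2, dt_truth_ms)
    az = np.full_like(tt, azimuth0)
    for kind, t0, t1 in bounds:
        if kind == "forward":
            continue
        sgn = +1.0 if kind == "CW" else -1.0  # CW body -> bump azimuth grows
        dur_in = np.clip(tt - t0, 0.0, t1 - t0)
        az = az + sgn * speed * dur_in / 1000.0
    return epochs, OrientationTrace(tt, az)


# ---------------------------------------------------------------------------
# task conditions
# ---------------------------------------------------------------------------

def make_condition(condition: int, cue_azimuth_deg: float = 40.0,
                   config: Optional[ModelConfig] = None,
                   circuit: str = "c-ring",
                   options: Optional[dict] = None) -> Protocol:
    """Build one of the three spatial-orientation task protocols.

    1. static cue-off: 1 s cue, then nothing (bump persistence).
    2. dynamic cue-on: 1 s static cue, then the cue sweeps at
       ``cue_speed_deg_s`` (default 22.5, clockwise) for ``move_ms``, then
       reverses for another ``move_ms`` (``phases`` controls how many
       sweeps; ``second_cue_deg``/``second_cue_scale`` add a dimmer
       simultaneous cue in condition 1).
    3. dynamic cue-off: 1 s cue, then darkness with body-rotation
       ``segments`` = [(kind, duration_ms), ...], kinds forward/CW/CCW.
    """
    cfg = config or default_config()
    opts = dict(options or {})
    known = {"T_total_ms", "cue_speed_deg_s", "move_ms", "phases",
             "second_cue_deg", "second_cue_scale", "segments",
             "cue_rate_scale", "cue_ms"}
    unknown = set(opts) - known
    if unknown:
        raise ValueError(f"unknown options: {sorted(unknown)}")
    if circuit not in CIRCUIT_CLASSES:
        raise ValueError(f"unknown circuit {circuit!r}")
    cue_ms = float(opts.get("cue_ms", 1000.0))
    cue_scale = float(opts.get("cue_rate_scale", 1.0))

    if condition == 1:
        T = float(opts.get("T_total_ms", 10000.0))
        epochs = _cue_epochs(cue_azimuth_deg, 0.0, cue_ms, cfg, cue_scale)
        if "second_cue_deg" in opts:
            s = float(opts.get("second_cue_scale", cfg.dim_cue_fraction))
            epochs += _cue_epochs(float(opts["second_cue_deg"]), 0.0, cue_ms,
                                  cfg, s * cue_scale)
        ep = _ring_epoch("R_PEN", 0.0, T, cfg)
        if ep:
            epochs.append(ep)
        epochs += _r_eip_epoch(T, cfg)
        tt = np.arange(0.0, T + 5.0, 10.0)
        truth = OrientationTrace(tt, np.full_like(tt, cue_azimuth_deg))
        proto = Protocol(epochs, truth, T, circuit, label="condition1")

    elif condition == 2:
        speed = float(opts.get("cue_speed_deg_s", 22.5))
        move = float(opts.get("move_ms", 16000.0))
        phases = int(opts.get("phases", 2))
        T = float(opts.get("T_total_ms", cue_ms + phases * move))
        # continuous cue azimuth: clockwise first (azimuth decreasing)
        tt = np.arange(0.0, T + 5.0, 10.0)
        az = np.full_like(tt, cue_azimuth_deg)
        sgn = -1.0
        t0 = cue_ms
        for _ in range(phases):
            dur_in = np.clip(tt - t0, 0.0, move)
            az = az + sgn * speed * dur_in / 1000.0
            t0 += move
            sgn = -sgn
        truth = OrientationTrace(tt, az)
        # epochs: one per dwell interval of the cue in a wedge
        epochs = []
        seg_start = 0.0
        cur = azimuth_to_eb_region(az[0])
        for k in range(1, len(tt)):
            w = azimuth_to_eb_region(az[k])
            if w != cur or k == len(tt) - 1:
                t_end = tt[k] if k < len(tt) - 1 else T
                r, l = cue_to_pb_targets(cur, cfg.dual_offset)
                rate = cfg.cue_rate_hz * cue_scale
                epochs.append(InputEpoch(("pb_region", r.label), rate,
                                         cfg.cue_g_ns, seg_start, t_end))
                epochs.append(InputEpoch(("pb_region", l.label), rate,
                                         cfg.cue_g_ns, seg_start, t_end))
                seg_start, cur = tt[k], w
        ep = _ring_epoch("R_PEN", 0.0, T, cfg)
        if ep:
            epochs.append(ep)
        epochs += _r_eip_epoch(T, cfg)
        proto = Protocol(epochs, truth, T, circuit, label="condition2")

    elif condition == 3:
        segments = list(opts.get("segments",
                                 [("forward", 2000.0), ("CW", 3000.0),
                                  ("CCW", 3000.0)]))
        T = float(opts.get("T_total_ms",
                           cue_ms + sum(d for _, d in segments)))
        epochs = _cue_epochs(cue_azimuth_deg, 0.0, cue_ms, cfg, cue_scale)
        # the cue period is a forward (non-rotating) state
        segs = [("forward", cue_ms)] + segments
        seg_epochs, truth = _segments_to_epochs(segs, 0.0, T, cfg,
                                                cue_azimuth_deg)
        epochs += seg_epochs
        epochs += _r_eip_epoch(T, cfg)
        proto = Protocol(epochs, truth, T, circuit, label="condition3")
    else:
        raise ValueError("condition must be 1, 2 or 3")

    proto.validate()
    return proto


def make_random_walk(T_total_s: float, seed: int,
                     config: Optional[ModelConfig] = None,
                     circuit: str = "full",
                     cue_azimuth_deg: float = 40.0) -> Protocol:
    """Random-walk protocol: cue for 1 s, then darkness with alternating
    forward walking (0.2-2 s, uniform) and rotations (direction fair coin,
    angle uniform on (0, 90] deg at 58.5 deg/s)."""
    if T_total_s <= 0:
        raise ValueError("T_total must be positive")
    cfg = config or default_config()
    rng = np.random.default_rng(seed)
    T = T_total_s * 1000.0
    speed = cfg.rotation_speed_deg_s

    segs: List[Tuple[str, float]] = [("forward", 1000.0)]  # cue period
    t = 1000.0
    forward_turn = True
    while t < T:
        if forward_turn:
            dur = rng.uniform(200.0, 2000.0)
            kind = "forward"
        else:
            angle = rng.uniform(0.0, 90.0)
            dur = angle / speed * 1000.0
            kind = "CW" if rng.random() < 0.5 else "CCW"
        dur = min(dur, T - t)
        if dur > 0:
            segs.append((kind, dur))
        t += dur
        forward_turn = not forward_turn

    epochs, truth = _segments_to_epochs(segs, 0.0, T, cfg, cue_azimuth_deg)
    epochs = _cue_epochs(cue_azimuth_deg, 0.0, 1000.0, cfg) + epochs
    epochs += _r_eip_epoch(T, cfg)
    proto = Protocol(epochs, truth, T, circuit, label="random_walk")
    proto.validate()
    return proto


def make_lesion(protocol: Protocol, ring_type: str,
                config: Optional[ModelConfig] = None) -> Protocol:
    """Copy of the protocol with a hyperpolarizing current silencing one
    ring-neuron class for the whole trial."""
    if ring_type not in ("R_EIP", "R_PEI", "R_PEN"):
        raise ValueError("ring_type must be one of R_EIP, R_PEI, R_PEN")
    cfg = config or default_config()
    lesions = dict(protocol.lesions)
    lesions[ring_type] = cfg.lesion_current_nA
    return dataclasses.replace(protocol, lesions=lesions,
                               label=protocol.label + f"+lesion:{ring_type}")
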