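"""Scripted, seeded reproductions of the circuit-level experiments.

Each suite builds a circuit variant (C-ring: EIP+PEI+R_EIP; P-ring:
EIP+PEN+R_EIP; full: all six classes), runs seeded trials of the relevant
task protocol, and summarizes the bump metrics.  Results carry their seeds
and a config hash so every table can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ebpb import analysis, protocols
from ebpb.config import ModelConfig, default_config
from ebpb.connectome import Connectome, build_connectome
from ebpb.engine import Network, SpikeData, assemble_network, run
from ebpb.protocols import CIRCUIT_CLASSES, Protocol, make_condition


def config_hash(cfg: ModelConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def trial_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass
class ExperimentResult:
    experiment: str
    trials: pd.DataFrame
    summary: Dict[str, float]
    seeds: List[int]
    config_hash: str
    extras: dict = field(default_factory=dict)


def build_circuit(circuit: str, config: Optional[ModelConfig] = None,
                  pool_size: Optional[int] = None
                  ) -> Tuple[Connectome, Network]:
    cfg = config or default_config()
    conn = build_connectome(cfg).subset(CIRCUIT_CLASSES[circuit])
    return conn, assemble_network(conn, cfg, pool_size)


def run_trial(network: Network, conn: Connectome, protocol: Protocol,
              seed: int, config: Optional[ModelConfig] = None
              ) -> Tuple[SpikeData, analysis.RateTrace, analysis.BumpTrajectory]:
    cfg = config or network.config
    spikes = run(network, protocol, seed=seed)
    rates = analysis.eb_region_rates(spikes, conn, config=cfg)
    traj = analysis.bump_trajectory(rates, cfg)
    return spikes, rates, traj


# ---------------------------------------------------------------------------
# condition-level measurements
# ---------------------------------------------------------------------------

def measure_condition1(circuit: str, n_trials: int, seed: int,
                       config: Optional[ModelConfig] = None,
                       T_total_ms: float = 10000.0,
                       cue_deg: float = 40.0) -> pd.DataFrame:
    """Static-cue trials: persistence, post-offset FWHM and center drift."""
    cfg = config or default_config()
    conn, net = build_circuit(circuit, cfg)
    proto = make_condition(1, cue_deg, cfg, circuit,
                           {"T_total_ms": T_total_ms})
    rows = []
    for s in trial_seeds(seed, n_trials):
        _, rates, traj = run_trial(net, conn, proto, s, cfg)
        post = (traj.t_ms >= 1000.0)
        okpost = post & traj.ok
        persists = bool(traj.ok[post][-5:].all()) if post.sum() >= 5 else False
        fwhm = float(np.nanmean(traj.fwhm_deg[okpost])) if okpost.any() else np.nan
        dev, dev_sd = (np.nan, np.nan)
        if okpost.any():
            dev, dev_sd = analysis.bump_deviation(traj, proto.truth,
                                                  (1000.0, T_total_ms))
        height = float(np.nanmean(traj.height[okpost])) if okpost.any() else 0.0
        rows.append(dict(seed=s, persists=persists, fwhm_deg=fwhm,
                         deviation_rad=dev, deviation_sd=dev_sd,
                         height=height))
    return pd.DataFrame(rows)


def measure_condition2(circuit: str, n_trials: int, seed: int,
                       config: Optional[ModelConfig] = None,
                       cue_speed_deg_s: float = 22.5,
                       move_ms: float = 16000.0, phases: int = 2,
                       cue_deg: float = 40.0) -> pd.DataFrame:
    """Moving-cue trials: tracking deviation, width, loss events."""
    cfg = config or default_config()
    conn, net = build_circuit(circuit, cfg)
    proto = make_condition(2, cue_deg, cfg, circuit,
                           {"cue_speed_deg_s": cue_speed_deg_s,
                            "move_ms": move_ms, "phases": phases})
    rows = []
    for s in trial_seeds(seed, n_trials):
        _, rates, traj = run_trial(net, conn, proto, s, cfg)
        dev, dev_sd = analysis.bump_deviation(traj, proto.truth,
                                              (1000.0, proto.T_total_ms))
        m = traj.ok & (traj.t_ms >= 1000.0)
        fwhm = float(np.nanmean(traj.fwhm_deg[m])) if m.any() else np.nan
        lost = analysis.track_loss(traj, proto.truth, cfg, t_start_ms=1000.0)
        rows.append(dict(seed=s, deviation_rad=dev, deviation_sd=dev_sd,
                         fwhm_rad=np.deg2rad(fwhm), lost=lost))
    return pd.DataFrame(rows)


def measure_rotation(circuit: str, n_trials: int, seed: int,
                     config: Optional[ModelConfig] = None,
                     direction: str = "CCW", rotate_ms: float = 2500.0,
                     rate_hz: Optional[float] = None,
                     measure_s: float = 2.0,
                     cue_deg: float = 40.0) -> pd.DataFrame:
    """Condition-3 trials: 1 s cue, then unilateral drive; bump speed over
    the first ``measure_s`` seconds after cue offset."""
    cfg = config or default_config()
    conn, net = build_circuit(circuit, cfg)
    opts = {"segments": [(direction, rotate_ms)]}
    proto = make_condition(3, cue_deg, cfg, circuit, opts)
    if rate_hz is not None:
        eps = [e for e in proto.epochs]
        proto.epochs = [
            e if e.group != "rotation" else
            protocols.InputEpoch(e.target, rate_hz, e.g_max_ns, e.t_start_ms,
                                 e.t_end_ms, e.receptor, e.pool_total, e.group)
            for e in eps]
    rows = []
    for s in trial_seeds(seed, n_trials):
        _, rates, traj = run_trial(net, conn, proto, s, cfg)
        speed = analysis.bump_speed(traj, (1000.0, 1000.0 + measure_s * 1000.0))
        rows.append(dict(seed=s, speed_deg_s=speed, direction=direction,
                         rate_hz=rate_hz if rate_hz is not None
                         else cfg.unilateral_rate_hz))
    return pd.DataFrame(rows)


def measure_random_walk(circuit: str, n_trials: int, seed: int,
                        T_s: float = 120.0,
                        config: Optional[ModelConfig] = None
                        ) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Random-walk trials; returns per-trial table plus the trial-averaged
    deviation-vs-time curve (time grid in s)."""
    cfg = config or default_config()
    conn, net = build_circuit(circuit, cfg)
    grid_s = None
    devs = []
    rows = []
    for i, s in enumerate(trial_seeds(seed, n_trials)):
        proto = protocols.make_random_walk(T_s, seed=s, config=cfg,
                                           circuit=circuit)
        _, rates, traj = run_trial(net, conn, proto, s, cfg)
        diff = np.abs(analysis.wrap_deg(
            traj.center_deg - proto.truth.at(traj.t_ms)))
        diff[~traj.ok] = np.nan
        if grid_s is None:
            grid_s = traj.t_ms / 1000.0
        devs.append(np.deg2rad(diff))
        ok_m = traj.ok & (traj.t_ms >= 1000.0)
        rows.append(dict(seed=s, mean_dev_rad=float(np.nanmean(
            np.deg2rad(diff[ok_m]))) if ok_m.any() else np.nan,
            ok_fraction=float(traj.ok.mean())))
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dev_curve = np.nanmean(np.vstack(devs), axis=0)
    return pd.DataFrame(rows), grid_s, dev_curve


def drift_coefficient(grid_s: np.ndarray, dev_curve: np.ndarray,
                      t0_s: float = 1.0) -> analysis.DriftFit:
    """Square-root drift fit to the trial-averaged deviation curve, with
    time measured from cue offset."""
    m = (grid_s >= t0_s) & np.isfinite(dev_curve)
    return analysis.fit_sqrt_drift(grid_s[m] - t0_s, dev_curve[m])


# ---------------------------------------------------------------------------
# figure-level suites
# ---------------------------------------------------------------------------

def run_cring_suite(n_trials: int = 10, seed: int = 0,
                    config: Optional[ModelConfig] = None,
                    quick: bool = False) -> ExperimentResult:
    """Symmetric-circuit suite: persistence, two-cue competition, tracking
    at one and two wedges per second, and the no-shift control."""
    cfg = config or default_config()
    T1 = 5000.0 if quick else 10000.0
    move = 4000.0 if quick else 16000.0
    c1 = measure_condition1("c-ring", n_trials, seed, cfg, T_total_ms=T1)
    c2 = measure_condition2("c-ring", n_trials, seed + 1, cfg,
                            move_ms=move, phases=2)
    c2_fast = measure_condition2("c-ring", n_trials, seed + 2, cfg,
                                 cue_speed_deg_s=45.0, move_ms=move / 2,
                                 phases=2)
    rot = measure_rotation("c-ring", max(3, n_trials // 2), seed + 3, cfg)
    # two-cue competition
    conn, net = build_circuit("c-ring", cfg)
    proto2 = make_condition(1, 40.0, cfg, "c-ring",
                            {"second_cue_deg": 40.0 + 157.5,
                             "T_total_ms": T1})
    two_cue_rows = []
    for s in trial_seeds(seed + 4, max(3, n_trials // 2)):
        _, rates, traj = run_trial(net, conn, proto2, s, cfg)
        m = traj.ok & (traj.t_ms >= 1000.0)
        dev = analysis.bump_deviation(traj, proto2.truth, (1000.0, T1))[0] \
            if m.any() else np.nan
        two_cue_rows.append(dict(seed=s, dev_to_bright_rad=dev,
                                 single_bump=bool(m.any())))
    two = pd.DataFrame(two_cue_rows)
    trials = pd.concat([c1.assign(task="cond1"), c2.assign(task="cond2"),
                        c2_fast.assign(task="cond2_fast"),
                        rot.assign(task="cond3"), two.assign(task="two_cue")],
                       ignore_index=True)
    summary = dict(
        persist_fraction=float(c1["persists"].mean()),
        fwhm_deg=float(np.nanmean(c1["fwhm_deg"])),
        cond2_deviation_rad=float(c2["deviation_rad"].mean()),
        cond2_fwhm_rad=float(c2["fwhm_rad"].mean()),
        loss_fraction_22=float(c2["lost"].mean()),
        loss_fraction_45=float(c2_fast["lost"].mean()),
        cond3_abs_speed=float(rot["speed_deg_s"].abs().mean()),
        two_cue_dev_rad=float(np.nanmean(two["dev_to_bright_rad"])),
    )
    return ExperimentResult("c-ring", trials, summary,
                            trial_seeds(seed, n_trials), config_hash(cfg))


def run_pring_suite(n_trials: int = 10, seed: int = 0,
                    config: Optional[ModelConfig] = None,
                    quick: bool = False,
                    rate_sweep: Sequence[float] = (1575.0, 2350.0, 3150.0,
                                                   3950.0, 4700.0)
                    ) -> ExperimentResult:
    """Shifter-circuit suite: tracking, rotation gain and direction,
    speed-vs-input regression, PB asymmetry."""
    cfg = config or default_config()
    move = 4000.0 if quick else 16000.0
    c2 = measure_condition2("p-ring", n_trials, seed + 1, cfg,
                            move_ms=move, phases=2)
    rot_ccw = measure_rotation("p-ring", n_trials, seed + 3, cfg, "CCW")
    rot_cw = measure_rotation("p-ring", n_trials, seed + 4, cfg, "CW")
    sweep_rows = []
    for r in rate_sweep:
        df = measure_rotation("p-ring", max(3, n_trials // 2), seed + 5, cfg,
                              "CCW", rate_hz=r)
        sweep_rows.append(dict(rate_hz=r,
                               speed=float(df["speed_deg_s"].abs().mean())))
    sweep = pd.DataFrame(sweep_rows)
    slope = float(np.polyfit(sweep["rate_hz"], sweep["speed"], 1)[0])
    # PB asymmetry
    conn, net = build_circuit("p-ring", cfg)
    static = make_condition(1, 40.0, cfg, "p-ring", {"T_total_ms": 4000.0})
    rotp = make_condition(3, 40.0, cfg, "p-ring",
                          {"segments": [("CCW", 3000.0)]})
    s0 = trial_seeds(seed + 6, 2)
    spk_static, _, _ = run_trial(net, conn, static, s0[0], cfg)
    spk_rot, _, _ = run_trial(net, conn, rotp, s0[1], cfg)
    prof_static = analysis.pb_bump_profiles(spk_static, conn, (1500.0, 3500.0), cfg)
    prof_rot = analysis.pb_bump_profiles(spk_rot, conn, (1500.0, 3500.0), cfg)
    trials = pd.concat([c2.assign(task="cond2"),
                        rot_ccw.assign(task="rot_ccw"),
                        rot_cw.assign(task="rot_cw")], ignore_index=True)
    summary = dict(
        cond2_deviation_rad=float(c2["deviation_rad"].mean()),
        cond2_fwhm_rad=float(c2["fwhm_rad"].mean()),
        rot_speed_ccw=float(rot_ccw["speed_deg_s"].mean()),
        rot_speed_cw=float(rot_cw["speed_deg_s"].mean()),
        cw_fraction_under_right_drive=float(
            (rot_ccw["speed_deg_s"] < 0).mean()),
        sweep_slope=slope,
        pb_height_ratio_static=(prof_static["R"]["height"] /
                                prof_static["L"]["height"]
                                if prof_static["L"]["ok"] else np.nan),
        pb_height_ratio_rot=(prof_rot["R"]["height"] /
                             prof_rot["L"]["height"]
                             if prof_rot["L"]["ok"] else np.nan),
    )
    return ExperimentResult("p-ring", trials, summary,
                            trial_seeds(seed, n_trials), config_hash(cfg),
                            extras=dict(sweep=sweep))


def _classify_run(traj: analysis.BumpTrajectory, truth, cfg: ModelConfig,
                  rot_windows: List[Tuple[float, float, str]]) -> dict:
    """Qualitative classification used by the ring-neuron add/lesion suite."""
    post = traj.t_ms >= 1000.0
    okfrac = float(traj.ok[post].mean()) if post.any() else 0.0
    has_bump = okfrac > 0.5
    fwhm = float(np.nanmean(traj.fwhm_deg[post & traj.ok])) if has_bump else np.nan
    shifts = []
    for (t0, t1, direction) in rot_windows:
        try:
            sp = analysis.bump_speed(traj, (t0, t1))
        except ValueError:
            shifts.append(np.nan)
            continue
        shifts.append(sp if direction == "CW" else -sp)
    # positive entries mean motion in the commanded direction
    moved = bool(np.any(np.asarray(shifts) > 15.0)) if shifts else False
    return dict(bump=has_bump, fwhm_deg=fwhm, shifts=shifts, moves=moved,
                ok_fraction=okfrac)


def run_ring_neuron_suite(seed: int = 0,
                          config: Optional[ModelConfig] = None,
                          n_trials: int = 3) -> ExperimentResult:
    """Add one ring-neuron type at a time, then lesion one at a time, on the
    forward/CW/CCW task; classify bump presence, width and mobility."""
    cfg = config or default_config()
    segments = [("forward", 2000.0), ("CW", 3000.0), ("CCW", 3000.0)]
    rot_windows = [(3000.0, 6000.0, "CW"), (6000.0, 9000.0, "CCW")]
    full_classes = set(CIRCUIT_CLASSES["full"])
    variants: Dict[str, dict] = {}

    def run_variant(name, classes=None, lesion=None):
        conn = build_connectome(cfg)
        if classes is not None:
            conn = conn.subset(classes)
        net = assemble_network(conn, cfg)
        rows = []
        for s in trial_seeds(seed + zlib.crc32(name.encode()) % 1000, n_trials):
            proto = make_condition(3, 40.0, cfg, "full",
                                   {"segments": segments})
            proto.circuit = "full"
            if lesion:
                proto = protocols.make_lesion(proto, lesion, cfg)
            _, rates, traj = run_trial(net, conn, proto, s, cfg)
            rows.append(_classify_run(traj, proto.truth, cfg, rot_windows))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            variants[name] = dict(
                bump=bool(np.mean([r["bump"] for r in rows]) > 0.5),
                moves=bool(np.mean([r["moves"] for r in rows]) > 0.5),
                fwhm_deg=float(np.nanmean([r["fwhm_deg"] for r in rows])))

    base = ("EIP", "PEI", "PEN")
    run_variant("none", classes=base)
    run_variant("R_EIP_only", classes=base + ("R_EIP",))
    run_variant("R_PEI_only", classes=base + ("R_PEI",))
    run_variant("R_PEN_only", classes=base + ("R_PEN",))
    run_variant("full", classes=tuple(full_classes))
    run_variant("lesion_R_EIP", classes=tuple(full_classes), lesion="R_EIP")
    run_variant("lesion_R_PEI", classes=tuple(full_classes), lesion="R_PEI")
    run_variant("lesion_R_PEN", classes=tuple(full_classes), lesion="R_PEN")

    trials = pd.DataFrame([dict(variant=k, **v) for k, v in variants.items()])
    summary = {f"{k}_bump": float(v["bump"]) for k, v in variants.items()}
    summary.update({f"{k}_moves": float(v["moves"]) for k, v in variants.items()})
    return ExperimentResult("ring-suite", trials, summary,
                            trial_seeds(seed, n_trials), config_hash(cfg),
                            extras=dict(variants=variants))


def run_random_walk_suite(n_trials: int = 20, T_s: float = 120.0,
                          seed: int = 0,
                          config: Optional[ModelConfig] = None,
                          circuits: Sequence[str] = ("full", "p-ring")
                          ) -> ExperimentResult:
    """Random-walk drift comparison between circuit variants."""
    cfg = config or default_config()
    frames = []
    summary = {}
    extras = {}
    for circuit in circuits:
        df, grid, curve = measure_random_walk(circuit, n_trials, seed, T_s, cfg)
        fit = drift_coefficient(grid, curve)
        frames.append(df.assign(circuit=circuit))
        summary[f"a_{circuit.replace('-', '_')}"] = fit.a
        extras[circuit] = dict(grid_s=grid, dev_curve=curve, fit=fit)
    return ExperimentResult("random-walk", pd.concat(frames, ignore_index=True),
                            summary, trial_seeds(seed, n_trials),
                            config_hash(cfg), extras=extras)


def run_nmda_suite(seed: int = 0, config: Optional[ModelConfig] = None,
                   n_trials: int = 3) -> ExperimentResult:
    """NMDA kinetics suite: time-constant reduction (with weight
    rescaling), magnesium-block removal, saturation removal."""
    cfg = config or default_config()
    segments = [("forward", 2000.0), ("CW", 3000.0), ("CCW", 3000.0)]
    rot_windows = [(3000.0, 6000.0, "CW"), (6000.0, 9000.0, "CCW")]

    def variant_cfg(tau=None, scale=1.0, mg=True, sat=True, sat_scale=1.0):
        c = cfg.replace(nmda_weight_scale=cfg.nmda_weight_scale * scale * sat_scale)
        rec = dict(c.receptors)
        nm = dict(kind="NMDA", tau_ms=tau if tau else rec["NMDA"].tau_ms,
                  E_rev_mV=0.0, alpha=rec["NMDA"].alpha,
                  Mg_conc=rec["NMDA"].Mg_conc, mg_block_enabled=mg,
                  saturation_enabled=sat)
        from ebpb.config import ReceptorParams
        rec["NMDA"] = ReceptorParams(**nm)
        c.receptors = rec
        return c

    cases = {
        "baseline": variant_cfg(),
        "tau50_x1.2": variant_cfg(tau=50.0, scale=1.2),
        "tau10_x1.2": variant_cfg(tau=10.0, scale=1.2),
        "mg_off": variant_cfg(mg=False),
        "saturation_off": variant_cfg(sat=False, sat_scale=0.12),
    }
    results = {}
    for name, c in cases.items():
        conn = build_connectome(c)
        net = assemble_network(conn, c)
        rows = []
        for s in trial_seeds(seed + zlib.crc32(name.encode()) % 1000, n_trials):
            proto = make_condition(3, 40.0, c, "full", {"segments": segments})
            _, rates, traj = run_trial(net, conn, proto, s, c)
            cls = _classify_run(traj, proto.truth, c, rot_windows)
            # sustained bump before rotation onset
            pre = (traj.t_ms >= 1500.0) & (traj.t_ms <= 3000.0)
            cls["bump_pre_rotation"] = bool(traj.ok[pre].mean() > 0.5)
            post = (traj.t_ms >= 4000.0)
            cls["bump_post_rotation"] = bool(traj.ok[post].mean() > 0.5)
            rows.append(cls)
        results[name] = dict(
            bump_pre=bool(np.mean([r["bump_pre_rotation"] for r in rows]) > 0.5),
            bump_post=bool(np.mean([r["bump_post_rotation"] for r in rows]) > 0.5),
            moves=bool(np.mean([r["moves"] for r in rows]) > 0.5))
    trials = pd.DataFrame([dict(case=k, **v) for k, v in results.items()])
    summary = {f"{k}_pass": float(v["bump_pre"] and v["bump_post"])
               for k, v in results.items()}
    return ExperimentResult("nmda", trials, summary, trial_seeds(seed, n_trials),
                            config_hash(cfg), extras=dict(cases=results))


# ---------------------------------------------------------------------------
# weight calibration
# ---------------------------------------------------------------------------

CALIBRATION_CHANNELS = [("PEI", "EIP"), ("EIP", "PEI"), ("EIP", "R_EIP"),
                        ("R_EIP", "EIP"), ("EIP", "PEN"), ("PEN", "EIP")]


def calibration_objective(cfg: ModelConfig, seed: int,
                          n_trials: int = 2) -> Tuple[float, dict]:
    """Penalty for missing the circuit-level contracts.

    Targets: condition-1 persistence, post-offset FWHM near 58.4 deg, no
    shift in the C-ring under unilateral drive, and a clockwise shift near
    58.5 deg/s in the P-ring at the default drive.
    """
    report: dict = {}
    pen = 0.0
    c1 = measure_condition1("c-ring", n_trials, seed, cfg, T_total_ms=6000.0)
    persist = float(c1["persists"].mean())
    fwhm = float(np.nanmean(c1["fwhm_deg"]))
    report["persist"] = persist
    report["fwhm_deg"] = fwhm
    pen += 10.0 * (1.0 - persist)
    if np.isfinite(fwhm):
        pen += abs(fwhm - 58.4) / 58.4
    else:
        pen += 5.0
    rotc = measure_rotation("c-ring", n_trials, seed + 1, cfg,
                            rotate_ms=2500.0)
    c_speed = float(rotc["speed_deg_s"].abs().mean())
    report["cring_speed"] = c_speed
    pen += max(0.0, (c_speed - 5.0) / 58.5)
    rotp = measure_rotation("p-ring", n_trials, seed + 2, cfg,
                            rotate_ms=2500.0)
    p_speed = float(rotp["speed_deg_s"].mean())  # negative = clockwise
    report["pring_speed"] = p_speed
    if p_speed >= 0:
        pen += 5.0
    pen += abs(-p_speed - 58.5) / 58.5
    report["penalty"] = pen
    return pen, report


def calibrate_weights(targets: Optional[dict] = None,
                      search_config: Optional[dict] = None,
                      seed: int = 0,
                      config: Optional[ModelConfig] = None
                      ) -> Tuple[Dict[Tuple[str, str], float], List[dict]]:
    """Coordinate descent on the base-weight channels.

    Multiplicative steps per channel, early stop when a full sweep yields no
    improvement.  Deterministic given the seed.  Returns the best weights
    and the objective trace.
    """
    cfg = (config or default_config())
    sc = dict(factors=(0.8, 1.25), max_sweeps=3, n_trials=2)
    sc.update(search_config or {})
    weights = dict(cfg.base_weights)
    trace: List[dict] = []
    best_pen, rep = calibration_objective(cfg.replace(base_weights=weights), seed,
                                          sc["n_trials"])
    trace.append(dict(rep, step="init", penalty=best_pen))
    for sweep in range(sc["max_sweeps"]):
        improved = False
        for chan in CALIBRATION_CHANNELS:
            for f in sc["factors"]:
                trial = dict(weights)
                trial[chan] = weights[chan] * f
                pen, rep = calibration_objective(
                    cfg.replace(base_weights=trial), seed, sc["n_trials"])
                trace.append(dict(rep, step=f"{chan[0]}->{chan[1]} x{f}",
                                  penalty=pen))
                if pen < best_pen - 1e-3:
                    best_pen, weights, improved = pen, trial, True
        if not improved:
            break
    return weights, trace
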