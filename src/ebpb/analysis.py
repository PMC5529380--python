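"""Bump analysis: calcium-like rates, circular Gaussian fits, drift metrics.

Population firing rates are computed by convolving the pooled spike train
with a causal exponential kernel (decay d = 721.5 ms, i.e. a 500 ms
half-life) that mimics the response of a slow calcium indicator, and
normalizing by pool size:

    r(t) = (1/N) * sum_{t_i <= t} exp(-(t - t_i)/d)

The EB activity map assigns to each of the 16 wedges the mean rate of the
EIP pools whose dendrites cover it.  A circular (wrapped) Gaussian with
optional baseline is fit to the 16-point profile at each analysis step; its
peak is the bump center, 2 sqrt(2 ln 2) sigma its FWHM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from ebpb.config import ModelConfig, default_config
from ebpb.connectome import Connectome, EB_WEDGE_ORDER, N_WEDGES
from ebpb.engine import SpikeData
from ebpb.protocols import OrientationTrace, WEDGE_DEG, position_to_azimuth

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class RateTrace:
    t_ms: np.ndarray
    r: np.ndarray          # (n_series, n_t) or (n_t,)
    d_ms: float
    pool_size: int
    labels: Optional[List[str]] = None


@dataclass
class BumpTrajectory:
    t_ms: np.ndarray
    center_deg: np.ndarray   # wrapped to [0, 360)
    fwhm_deg: np.ndarray
    height: np.ndarray
    ok: np.ndarray           # bool


@dataclass
class DriftFit:
    a: float                 # y = sqrt(a x)
    residual: float


def exponential_rate(spike_times_ms: np.ndarray, t_grid_ms: np.ndarray,
                     N: int, d_ms: float) -> np.ndarray:
    """Causal exponential-kernel rate of one pooled spike train, exactly
    evaluated at each grid point."""
    if d_ms <= 0:
        raise ValueError("kernel decay must be positive")
    ts = np.sort(np.asarray(spike_times_ms, float))
    r = np.zeros(len(t_grid_ms))
    acc = 0.0
    prev_t = -np.inf
    j = 0
    for k, t in enumerate(t_grid_ms):
        if np.isfinite(prev_t):
            acc *= math.exp(-(t - prev_t) / d_ms)
        j2 = np.searchsorted(ts, t, side="right")
        if j2 > j:
            acc += float(np.exp(-(t - ts[j:j2]) / d_ms).sum())
        j = j2
        r[k] = acc / N
        prev_t = t
    return r


def firing_rate(spikes: SpikeData, pool_name: str, d_ms: Optional[float] = None,
                t_grid_ms: Optional[np.ndarray] = None,
                config: Optional[ModelConfig] = None) -> RateTrace:
    """Kernel rate of one pool (see module docstring)."""
    cfg = config or default_config()
    d = cfg.rate_kernel_d_ms if d_ms is None else d_ms
    if t_grid_ms is None:
        t_grid_ms = np.arange(0.0, spikes.T_total_ms + 1e-9, cfg.fit_interval_ms)
    r = exponential_rate(spikes.pool_times(pool_name), t_grid_ms,
                         spikes.pool_size, d)
    return RateTrace(t_grid_ms, r, d, spikes.pool_size, [pool_name])


def eb_region_rates(spikes: SpikeData, connectome: Connectome,
                    d_ms: Optional[float] = None,
                    t_grid_ms: Optional[np.ndarray] = None,
                    config: Optional[ModelConfig] = None) -> RateTrace:
    """Activity of the 16 EB wedges: mean rate of the EIP pools whose
    dendritic domains cover each wedge."""
    cfg = config or default_config()
    d = cfg.rate_kernel_d_ms if d_ms is None else d_ms
    if t_grid_ms is None:
        t_grid_ms = np.arange(0.0, spikes.T_total_ms + 1e-9, cfg.fit_interval_ms)
    eips = [t for t in connectome.types if t.neuron_class == "EIP"]
    pool_rates = {}
    for t in eips:
        pool_rates[t.name] = exponential_rate(
            spikes.pool_times(t.name), t_grid_ms, spikes.pool_size, d)
    out = np.zeros((N_WEDGES, len(t_grid_ms)))
    for w_i, wedge in enumerate(EB_WEDGE_ORDER):
        members = [t.name for t in eips
                   if any(r.neuropil == "EB" and r.label == wedge
                          for r in t.dendritic_regions)]
        if members:
            out[w_i] = np.mean([pool_rates[m] for m in members], axis=0)
    return RateTrace(t_grid_ms, out, d, spikes.pool_size,
                     list(EB_WEDGE_ORDER))


# ---------------------------------------------------------------------------
# bump fitting
# ---------------------------------------------------------------------------

def _wrapped_gauss(x, A, mu, sigma, b):
    dx = np.mod(x - mu + N_WEDGES / 2, N_WEDGES) - N_WEDGES / 2
    return b + A * np.exp(-0.5 * (dx / sigma) ** 2)


def fit_bump(region_rates: np.ndarray, config: Optional[ModelConfig] = None
             ) -> Tuple[float, float, float, bool]:
    """Fit a circular Gaussian to one 16-wedge profile.

    Returns (center_deg, fwhm_deg, height, ok).  The profile is rotated so
    its argmax sits mid-array before fitting, avoiding the wrap
    discontinuity; ``ok`` is False for flat or sub-threshold profiles or a
    failed fit.
    """
    cfg = config or default_config()
    y = np.asarray(region_rates, float)
    if y.shape != (N_WEDGES,):
        raise ValueError("expected 16 wedge rates")
    if not np.all(np.isfinite(y)) or np.ptp(y) <= 0:
        return (math.nan, math.nan, 0.0, False)
    k = int(np.argmax(y))
    shift = N_WEDGES // 2 - k
    y_rot = np.roll(y, shift)
    x = np.arange(N_WEDGES, dtype=float)
    b0 = float(np.min(y_rot))
    A0 = float(y_rot[N_WEDGES // 2] - b0)
    p0 = [A0, float(N_WEDGES // 2), 1.5, b0]
    lo = [0.0, N_WEDGES / 2 - 2.0, 0.3, 0.0]
    hi = [np.inf, N_WEDGES / 2 + 2.0, 7.0, max(b0 * 2, A0, 1e-9)]
    if not cfg.bump_fit_baseline:
        p0, lo, hi = p0[:3], lo[:3], hi[:3]
        model = lambda x, A, mu, sigma: _wrapped_gauss(x, A, mu, sigma, 0.0)
    else:
        model = _wrapped_gauss
    try:
        popt, _ = curve_fit(model, x, y_rot, p0=p0, bounds=(lo, hi),
                            maxfev=2000)
    except (RuntimeError, ValueError):
        return (math.nan, math.nan, 0.0, False)
    A, mu, sigma = popt[0], popt[1], popt[2]
    b = popt[3] if cfg.bump_fit_baseline else 0.0
    center = position_to_azimuth(mu - shift)
    fwhm = FWHM_FACTOR * sigma * WEDGE_DEG
    # a bump must stand out of the baseline (rejects uniform/runaway states)
    # and be localized (a half-circle "bump" is not a heading estimate)
    ok = bool(A >= cfg.bump_min_height and A >= 0.5 * b and fwhm < 180.0)
    return (float(center), float(fwhm), float(A), ok)


def bump_trajectory(region_rates: RateTrace,
                    config: Optional[ModelConfig] = None) -> BumpTrajectory:
    """Per-time-step circular Gaussian fits over an EB rate map."""
    nt = len(region_rates.t_ms)
    c = np.full(nt, np.nan)
    w = np.full(nt, np.nan)
    h = np.zeros(nt)
    ok = np.zeros(nt, bool)
    for i in range(nt):
        c[i], w[i], h[i], ok[i] = fit_bump(region_rates.r[:, i], config)
    return BumpTrajectory(region_rates.t_ms, c, w, h, ok)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def wrap_deg(x: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180]."""
    return (np.asarray(x, float) + 180.0) % 360.0 - 180.0


def bump_deviation(traj: BumpTrajectory, truth: OrientationTrace,
                   window_ms: Optional[Tuple[float, float]] = None
                   ) -> Tuple[float, float]:
    """Mean absolute circular deviation (rad) between bump center and the
    expected azimuth, with its within-trial s.d.; fit failures excluded."""
    m = traj.ok.copy()
    if window_ms is not None:
        m &= (traj.t_ms >= window_ms[0]) & (traj.t_ms <= window_ms[1])
    if not np.any(m):
        raise ValueError("no successful bump fits in evaluation window")
    diff = np.abs(wrap_deg(traj.center_deg[m] - truth.at(traj.t_ms[m])))
    dev = np.deg2rad(diff)
    return float(dev.mean()), float(dev.std())


def unwrap_centers(t_ms: np.ndarray, center_deg: np.ndarray, ok: np.ndarray,
                   max_jump_deg: float = 90.0
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-angle continuation of the bump center; samples after a jump
    larger than ``max_jump_deg`` are dropped as fit failures."""
    t_ok = t_ms[ok]
    c_ok = center_deg[ok]
    if len(c_ok) == 0:
        return t_ok, c_ok
    out = [c_ok[0]]
    ts = [t_ok[0]]
    for i in range(1, len(c_ok)):
        step = float(wrap_deg(c_ok[i] - out[-1]))
        if abs(step) > max_jump_deg:
            continue
        out.append(out[-1] + step)
        ts.append(t_ok[i])
    return np.asarray(ts), np.asarray(out)


def bump_speed(traj: BumpTrajectory, window_ms: Tuple[float, float]
               ) -> float:
    """Signed bump angular velocity (deg/s): least-squares slope of the
    unwrapped center within the window."""
    m = (traj.t_ms >= window_ms[0]) & (traj.t_ms <= window_ms[1])
    ts, cs = unwrap_centers(traj.t_ms[m], traj.center_deg[m], traj.ok[m])
    if len(ts) < 2:
        raise ValueError("insufficient successful fits for a speed estimate")
    slope = np.polyfit(ts / 1000.0, cs, 1)[0]
    return float(slope)


def track_loss(traj: BumpTrajectory, truth: OrientationTrace,
               config: Optional[ModelConfig] = None,
               t_start_ms: float = 0.0) -> bool:
    """Loss-of-tracking event: the fitted center strays more than the
    configured angle from the cue, or the fit fails, for longer than the
    configured dwell time."""
    cfg = config or default_config()
    m = traj.t_ms >= t_start_ms
    t = traj.t_ms[m]
    bad = ~traj.ok[m]
    diff = np.abs(wrap_deg(traj.center_deg[m] - truth.at(t)))
    bad |= diff > cfg.loss_angle_deg
    if len(t) < 2:
        return False
    dt = np.median(np.diff(t))
    need = int(np.ceil(cfg.loss_time_ms / dt))
    run = 0
    for b in bad:
        run = run + 1 if b else 0
        if run >= need:
            return True
    return False


def fit_sqrt_drift(t_s: np.ndarray, dev_rad: np.ndarray) -> DriftFit:
    """Least-squares fit of y = sqrt(a x): linear regression of y on
    sqrt(x) through the origin, a = slope^2."""
    x = np.sqrt(np.asarray(t_s, float))
    y = np.asarray(dev_rad, float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("require t >= 0 and deviations >= 0")
    denom = float((x * x).sum())
    c = float((x * y).sum() / denom) if denom > 0 else 0.0
    resid = float(((y - c * x) ** 2).sum())
    return DriftFit(a=c * c, residual=resid)


# ---------------------------------------------------------------------------
# PB profiles
# ---------------------------------------------------------------------------

def pb_bump_profiles(spikes: SpikeData, connectome: Connectome,
                     window_ms: Tuple[float, float],
                     config: Optional[ModelConfig] = None) -> Dict[str, dict]:
    """Per-side PB activity profiles from PEN pools, peak-aligned.

    Returns, per side, the 9-glomerulus mean-rate vector (time-averaged
    over the window), the profile aligned to its peak, and a Gaussian fit
    height (NaN when the side is silent).
    """
    cfg = config or default_config()
    grid = np.arange(window_ms[0], window_ms[1] + 1e-9, cfg.fit_interval_ms)
    out: Dict[str, dict] = {}
    for side in ("R", "L"):
        prof = np.zeros(9)
        for t in connectome.types:
            if t.neuron_class != "PEN":
                continue
            (r,) = list(t.dendritic_regions)
            if not r.label.startswith(side):
                continue
            g = int(r.label[1:])
            rate = exponential_rate(spikes.pool_times(t.name), grid,
                                    spikes.pool_size, cfg.rate_kernel_d_ms)
            prof[g] += float(rate.mean())
        if prof.max() <= 0:
            out[side] = dict(profile=prof, aligned=prof, height=math.nan,
                             ok=False)
            continue
        k = int(np.argmax(prof))
        aligned = np.roll(prof, 4 - k)
        x = np.arange(9, dtype=float)
        try:
            popt, _ = curve_fit(
                lambda x, A, mu, s, b: b + A * np.exp(-0.5 * ((x - mu) / s) ** 2),
                x, aligned, p0=[aligned[4], 4.0, 1.5, aligned.min()],
                bounds=([0, 2, 0.3, 0], [np.inf, 6, 8, np.inf]), maxfev=2000)
            height, ok = float(popt[0]), True
        except (RuntimeError, ValueError):
            height, ok = math.nan, False
        out[side] = dict(profile=prof, aligned=aligned, height=height, ok=ok)
    return out
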