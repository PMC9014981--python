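"""Synthetic precision center-out sessions with ground truth.

Generates complete sessions — cursor kinematics, spike trains and the
generating parameters — with the statistical structure the analysis pipeline
assumes, so every downstream stage can be validated by parameter recovery:

* trials to 8 directions x 3 target sizes (large / narrow / shallow annular
  sectors), balanced across the session;
* each trial's cursor path is a sum of straight submovement displacement
  segments, each with a Gaussian bell-shaped speed profile of configured
  full-width-half-max; corrective submovements have peak speed equal to a
  configured fraction (default 1/3) of the trial's initial peak speed;
* trials flagged for correction are constructed to miss the target (angular
  miss or radial over/undershoot), so the corrective movement's acceleration
  phase starts outside the peripheral target and is classifiable;
* each unit's firing rate is baseline plus, for every submovement, a
  Gaussian bump that leads the speed peak by a unit-specific lag, scaled by
  the submovement's peak speed and by cosine tuning to movement direction;
  spikes are an inhomogeneous Poisson process sampled at 1-ms resolution.

A single seed fans out to per-trial and per-unit substreams, so adding
trials or units does not perturb the ones already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .kinematics import (CursorTrace, TargetGeometry, TARGET_SPECS,
                         WORKSPACE_CENTER)
from .ci_dynamics import SpikeData

__all__ = [
    "SimConfig",
    "GTSubmovement",
    "UnitParams",
    "GroundTruth",
    "Session",
    "simulate_session",
    "FWHM_TO_SIGMA",
]

# FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator.

    Kinematic defaults follow the behavior of trained macaques in the
    precision center-out task: initial bell-shaped submovements with
    ~250-ms full-width-half-max and peak speeds around 1350 px/s,
    corrective submovements with ~200-ms FWHM and peak speeds about one
    third of the initial, and inter-peak intervals with mean ~570 ms.
    Neural defaults give each unit a firing-rate bump leading every speed
    peak by a unit-specific lag in [-200, 0] ms, amplitude proportional to
    peak speed, and cosine tuning to movement direction.
    """

    n_trials: int = 200
    sample_rate: float = 100.0          # Hz, cursor sampling
    n_directions: int = 8               # 45-deg spacing
    size_classes: tuple = ("large", "narrow", "shallow")
    p_extra_submovement: float = 0.3    # P(>=1 corrective per trial)
    max_correctives: int = 3
    initial_peak_speed_mean: float = 1350.0   # px/s
    initial_peak_speed_sd: float = 200.0      # px/s
    initial_peak_speed_min: float = 1000.0    # px/s, lower clip
    corrective_amplitude_ratio: float = 1.0 / 3.0
    corrective_speed_jitter: float = 0.08     # lognormal sd on the ratio
    submovement_fwhm_initial_ms: float = 250.0
    submovement_fwhm_corrective_ms: float = 200.0
    inter_peak_interval_mean_ms: float = 570.0
    # minimum separation; chosen so consecutive bell profiles stay
    # resolvable under the 50%-prominence rule (distinct submovements,
    # as observed behaviorally)
    inter_peak_interval_shift_ms: float = 420.0
    inter_peak_interval_shape: float = 3.0        # gamma shape
    # population scale comparable to multielectrode-array sessions
    # (single- plus multiunit recordings on ~100 channels)
    n_units: int = 100
    baseline_rate_range: tuple = (2.0, 15.0)      # spikes/s
    lag_range_ms: tuple = (-200.0, 0.0)           # unit lead times
    tuning_depth_range: tuple = (0.0, 0.5)
    amplitude_gain: float = 0.025   # (spikes/s) per (px/s), population scale
    unit_gain_range: tuple = (0.5, 1.5)           # per-unit multiplier
    trial_gain_noise_sd: float = 0.0   # lognormal sd of per-trial gain, off
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (0.0 < self.corrective_amplitude_ratio < 1.0):
            raise ValueError("corrective_amplitude_ratio must be in (0, 1)")
        if (self.submovement_fwhm_initial_ms <= 0
                or self.submovement_fwhm_corrective_ms <= 0):
            raise ValueError("submovement FWHM must be positive")
        if not (0.0 <= self.p_extra_submovement <= 1.0):
            raise ValueError("p_extra_submovement must be a probability")


@dataclass
class GTSubmovement:
    """Generating parameters of one submovement (session clock, ms)."""

    trial_id: int
    peak_time_ms: float
    class_: str                 # 'initial' | 'corrective'
    peak_speed: float           # px/s, before any filtering
    sigma_ms: float             # Gaussian speed-bump width
    direction_rad: float        # movement direction of the displacement
    gain_factor: float = 1.0    # per-trial neural gain multiplier


@dataclass
class UnitParams:
    unit_id: int
    baseline: float             # spikes/s
    lag_ms: float               # negative: bump leads the speed peak
    pref_dir_rad: float
    tuning_depth: float
    gain: float                 # per-unit multiplier on amplitude_gain


@dataclass
class GroundTruth:
    submovements: list          # of GTSubmovement
    units: list                 # of UnitParams

    def peaks_for_trial(self, trial_id: int) -> list:
        return [s for s in self.submovements if s.trial_id == trial_id]


@dataclass
class Session:
    traces: list                # of CursorTrace
    spikes: SpikeData
    ground_truth: GroundTruth
    config: SimConfig
    duration_ms: float


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------

def _unit_vec(angle_rad: float) -> np.ndarray:
    return np.array([math.cos(angle_rad), math.sin(angle_rad)])


def _plan_trial(rng: np.random.Generator, cfg: SimConfig,
                geometry: TargetGeometry):
    """Plan the submovement segments of one trial (local time, ms).

    Returns a list of dicts with keys t_peak, amp, sigma_ms, start, end.
    """
    span, inner, outer = TARGET_SPECS[geometry.size_class]
    theta_t = math.radians(geometry.direction_deg)
    center = np.array(WORKSPACE_CENTER)

    n_corr = 0
    while (n_corr < cfg.max_correctives
           and rng.random() < cfg.p_extra_submovement):
        n_corr += 1

    a_init = max(rng.normal(cfg.initial_peak_speed_mean,
                            cfg.initial_peak_speed_sd),
                 cfg.initial_peak_speed_min)
    sigma_i = cfg.submovement_fwhm_initial_ms * FWHM_TO_SIGMA / 1000.0  # s
    d_init = a_init * sigma_i * math.sqrt(2.0 * math.pi)  # px

    # Aim the initial movement. Trials flagged for correction are built to
    # miss: if the sampled extent already falls outside the target's radial
    # span the radial miss suffices, otherwise the aim is offset past the
    # target's angular half-span.
    if n_corr == 0:
        delta = math.radians(rng.normal(0.0, 2.0))
    else:
        if d_init > outer + 15.0 or d_init < inner - 15.0:
            delta = math.radians(rng.normal(0.0, 2.0))
        else:
            sign = rng.choice([-1.0, 1.0])
            delta = sign * math.radians(span / 2.0 + rng.uniform(3.0, 8.0))
    start = center.copy()
    end = start + d_init * _unit_vec(theta_t + delta)

    t_peak = rng.uniform(350.0, 500.0)
    segments = [dict(t_peak=t_peak, amp=a_init, sigma_ms=sigma_i * 1000.0,
                     start=start, end=end)]

    sigma_c = cfg.submovement_fwhm_corrective_ms * FWHM_TO_SIGMA / 1000.0
    mid_r = 0.5 * (inner + outer)
    for k in range(n_corr):
        a_corr = (cfg.corrective_amplitude_ratio * a_init
                  * math.exp(rng.normal(0.0, cfg.corrective_speed_jitter)))
        d_corr = a_corr * sigma_c * math.sqrt(2.0 * math.pi)
        gap = (cfg.inter_peak_interval_shift_ms
               + rng.gamma(cfg.inter_peak_interval_shape,
                           (cfg.inter_peak_interval_mean_ms
                            - cfg.inter_peak_interval_shift_ms)
                           / cfg.inter_peak_interval_shape))
        t_peak = t_peak + gap
        start = segments[-1]["end"]
        if k < n_corr - 1:
            # intermediate correction must end outside the target so the
            # next correction's acceleration phase starts outside: step
            # away from the target midpoint, rotating the direction until
            # the endpoint clears the target region
            target_mid = np.array(geometry.center_point())
            away = start - target_mid
            norm = np.linalg.norm(away)
            base = (math.atan2(away[1], away[0]) if norm > 1e-9
                    else theta_t + math.pi)
            base += math.radians(rng.normal(0.0, 10.0))
            end = start + d_corr * _unit_vec(base)
            for step_deg in (0, 30, -30, 60, -60, 90, -90, 120, -120, 180):
                cand = start + d_corr * _unit_vec(
                    base + math.radians(step_deg))
                if not bool(geometry.contains(cand[0], cand[1])):
                    end = cand
                    break
        else:
            aim_angle = theta_t + math.radians(rng.normal(0.0, 1.5))
            aim = center + mid_r * _unit_vec(aim_angle)
            direction = aim - start
            norm = np.linalg.norm(direction)
            direction = (direction / norm if norm > 1e-9
                         else _unit_vec(theta_t))
            end = start + d_corr * direction
        segments.append(dict(t_peak=t_peak, amp=a_corr,
                             sigma_ms=sigma_c * 1000.0,
                             start=start, end=end))
    return segments


def _refine_peaks(segments):
    """Local maxima of the trial's combined speed profile near each bump.

    With overlapping bumps (or partially cancelling displacement
    directions) the true kinematic speed peak shifts slightly from each
    bump's nominal center; ground truth records the actual peak time and
    speed of the summed velocity, evaluated analytically on a 1-ms grid.
    Returns a list of ``(t_peak_ms, peak_speed)`` per segment.
    """
    out = []
    for seg in segments:
        sig = seg["sigma_ms"]
        t = np.arange(seg["t_peak"] - 1.5 * sig, seg["t_peak"] + 1.5 * sig,
                      1.0)
        v = np.zeros((len(t), 2))
        for other in segments:
            disp = other["end"] - other["start"]
            so = other["sigma_ms"]
            z = (t - other["t_peak"]) / so
            pdf = np.exp(-0.5 * z * z) / (so * math.sqrt(2.0 * math.pi))
            v += disp[None, :] * pdf[:, None]
        speed = np.hypot(v[:, 0], v[:, 1]) * 1000.0   # px/ms -> px/s
        j = int(np.argmax(speed))
        out.append((float(t[j]), float(speed[j])))
    return out


def _render_trace(trial_id: int, segments, geometry: TargetGeometry,
                  t0_ms: float, dt_ms: float,
                  tail_ms: float = 600.0) -> CursorTrace:
    """Sample the cursor path of one trial on the session 10-ms grid."""
    t_end = segments[-1]["t_peak"] + tail_ms
    n = int(math.ceil(t_end / dt_ms)) + 1
    t_local = np.arange(n) * dt_ms
    pos = np.tile(np.array(WORKSPACE_CENTER), (n, 1))
    from scipy.stats import norm as _norm
    for seg in segments:
        disp = seg["end"] - seg["start"]
        frac = _norm.cdf((t_local - seg["t_peak"]) / seg["sigma_ms"])
        pos = pos + frac[:, None] * disp[None, :]
    return CursorTrace(trial_id=trial_id, t=t0_ms + t_local,
                       x=pos[:, 0], y=pos[:, 1], target=geometry,
                       instruction_ms=t0_ms + 50.0)


# ---------------------------------------------------------------------------
# Neural generation
# ---------------------------------------------------------------------------

def _unit_rate(unit: UnitParams, cfg: SimConfig, gts, duration_ms: int
               ) -> np.ndarray:
    """Instantaneous rate of one unit on a 1-ms grid (spikes/s)."""
    rate = np.full(duration_ms, unit.baseline)
    t = np.arange(duration_ms, dtype=float)
    for s in gts:
        center = s.peak_time_ms + unit.lag_ms
        sig = s.sigma_ms
        lo = max(int(center - 5 * sig), 0)
        hi = min(int(center + 5 * sig) + 1, duration_ms)
        if hi <= lo:
            continue
        tune = 1.0 + unit.tuning_depth * math.cos(
            s.direction_rad - unit.pref_dir_rad)
        amp = (unit.gain * cfg.amplitude_gain * s.peak_speed
               * s.gain_factor * tune)
        rate[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sig) ** 2)
    return np.maximum(rate, 0.0)


def _sample_spikes(rng: np.random.Generator, rate: np.ndarray) -> np.ndarray:
    """Inhomogeneous Poisson spike times (ms) from a 1-ms piecewise rate."""
    counts = rng.poisson(rate * 1e-3)
    idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
    times = idx + rng.random(idx.size)
    return np.sort(times)


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def simulate_session(config: SimConfig) -> Session:
    """Generate a full synthetic session (kinematics, spikes, ground truth).

    Deterministic for a fixed ``config.seed``: the root seed sequence is
    split into behavior and neural branches, each spawned per trial / per
    unit, so earlier trials are unchanged when ``n_trials`` grows.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_beh, ss_neur = root.spawn(2)
    trial_seeds = ss_beh.spawn(config.n_trials)
    unit_seeds = ss_neur.spawn(config.n_units)

    dt_ms = 1000.0 / config.sample_rate
    directions = [360.0 * k / config.n_directions
                  for k in range(config.n_directions)]
    combos = [(d, s) for s in config.size_classes for d in directions]

    traces = []
    gts: list[GTSubmovement] = []
    t0 = 0.0
    for i in range(config.n_trials):
        rng = np.random.Generator(np.random.PCG64(trial_seeds[i]))
        direction, size = combos[i % len(combos)]
        geometry = TargetGeometry(direction_deg=direction, size_class=size)
        segments = _plan_trial(rng, config, geometry)
        gain_factor = (math.exp(rng.normal(0.0, config.trial_gain_noise_sd))
                       if config.trial_gain_noise_sd > 0 else 1.0)
        # variable final hold + intertrial period, so trial lengths (and
        # hence the session's temporal structure) are not periodic
        tail = rng.uniform(600.0, 1200.0)
        trace = _render_trace(i, segments, geometry, t0, dt_ms,
                              tail_ms=tail)
        traces.append(trace)
        refined = _refine_peaks(segments)
        for j, seg in enumerate(segments):
            disp = seg["end"] - seg["start"]
            gts.append(GTSubmovement(
                trial_id=i,
                peak_time_ms=t0 + refined[j][0],
                class_="initial" if j == 0 else "corrective",
                peak_speed=refined[j][1],
                sigma_ms=seg["sigma_ms"],
                direction_rad=float(math.atan2(disp[1], disp[0])),
                gain_factor=gain_factor,
            ))
        t0 = trace.t[-1] + dt_ms

    duration_ms = int(math.ceil(t0))
    units = []
    spike_lists = []
    for u in range(config.n_units):
        rng = np.random.Generator(np.random.PCG64(unit_seeds[u]))
        unit = UnitParams(
            unit_id=u,
            baseline=rng.uniform(*config.baseline_rate_range),
            lag_ms=rng.uniform(*config.lag_range_ms),
            pref_dir_rad=rng.uniform(-math.pi, math.pi),
            tuning_depth=rng.uniform(*config.tuning_depth_range),
            gain=rng.uniform(*config.unit_gain_range),
        )
        units.append(unit)
        rate = _unit_rate(unit, config, gts, duration_ms)
        spike_lists.append(_sample_spikes(rng, rate))

    spikes = SpikeData(unit_ids=list(range(config.n_units)),
                       spike_times=spike_lists,
                       t_start_ms=0.0, t_stop_ms=float(duration_ms))
    gt = GroundTruth(submovements=gts, units=units)
    return Session(traces=traces, spikes=spikes, ground_truth=gt,
                   config=config, duration_ms=float(duration_ms))
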