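"""Cursor kinematics: speed computation and submovement segmentation.

A trial's 2-D cursor trace (100 Hz) is low-pass filtered, differentiated, and
decomposed into discrete submovements at local speed maxima. Peaks must
exceed an absolute speed threshold (250 px/s) and a relative prominence
criterion (prominence >= 50% of peak height, where prominence is the height
above the larger of the two adjacent troughs and a trough is the minimum
before encountering a larger peak). The first submovement that ends at least
150 px from the workspace center is the initial movement; later peaks are
corrective only if part of their acceleration phase (preceding trough to
peak) lies outside the peripheral target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _signal

__all__ = [
    "WORKSPACE_CENTER",
    "CENTER_RADIUS_PX",
    "TARGET_SPECS",
    "TargetGeometry",
    "CursorTrace",
    "SpeedSeries",
    "Submovement",
    "compute_speed",
    "find_speed_peaks",
    "half_max_duration",
    "classify_submovements",
    "segment_trial",
    "profile_similarity",
    "trough_peak_ratio",
]

# Workspace: 1000 x 1000 px, home target at the center.
WORKSPACE_CENTER = (500.0, 500.0)
CENTER_RADIUS_PX = 75.0

# Peripheral target annular sectors, keyed by size class:
# (angular span deg, inner radius px, outer radius px)
TARGET_SPECS = {
    "large": (45.0, 250.0, 450.0),
    "shallow": (45.0, 325.0, 375.0),
    "narrow": (15.0, 250.0, 450.0),
}

# Segmentation defaults
SPEED_THRESHOLD_PXPS = 250.0
PROMINENCE_FRACTION = 0.5
INITIAL_MIN_DISTANCE_PX = 150.0
SUBMOVEMENT_WINDOW_MS = 200.0
FILTER_CUTOFF_HZ = 10.0


@dataclass(frozen=True)
class TargetGeometry:
    """Annular-sector peripheral target in polar coordinates about center."""

    direction_deg: float
    size_class: str

    @property
    def span_deg(self) -> float:
        return TARGET_SPECS[self.size_class][0]

    @property
    def inner_px(self) -> float:
        return TARGET_SPECS[self.size_class][1]

    @property
    def outer_px(self) -> float:
        return TARGET_SPECS[self.size_class][2]

    def contains(self, x, y) -> np.ndarray:
        """Vectorized membership test for workspace coordinates (px)."""
        dx = np.asarray(x, dtype=float) - WORKSPACE_CENTER[0]
        dy = np.asarray(y, dtype=float) - WORKSPACE_CENTER[1]
        r = np.hypot(dx, dy)
        ang = np.degrees(np.arctan2(dy, dx))
        dang = (ang - self.direction_deg + 180.0) % 360.0 - 180.0
        return ((r >= self.inner_px) & (r <= self.outer_px)
                & (np.abs(dang) <= self.span_deg / 2.0))

    def center_point(self) -> tuple[float, float]:
        """Radial midpoint of the target, workspace coordinates."""
        r = 0.5 * (self.inner_px + self.outer_px)
        th = math.radians(self.direction_deg)
        return (WORKSPACE_CENTER[0] + r * math.cos(th),
                WORKSPACE_CENTER[1] + r * math.sin(th))


@dataclass
class CursorTrace:
    """Uniformly sampled 2-D cursor positions for one trial.

    Times are milliseconds on the session clock; positions in pixels.
    """

    trial_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    target: TargetGeometry
    instruction_ms: Optional[float] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])

    def validate_uniform(self, rtol: float = 1e-6) -> None:
        dt = np.diff(self.t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > rtol * dt[0] + 1e-9:
            raise ValueError("non-uniform sampling")


@dataclass
class SpeedSeries:
    """Filtered cursor speed (px/s) on the trace's time base."""

    t: np.ndarray
    speed: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class Submovement:
    """One detected speed peak and its classification."""

    trial_id: int
    peak_time: float            # ms
    peak_index: int
    peak_speed: float           # px/s
    prominence: float           # px/s
    onset: Optional[float]      # ms, half-max crossing before peak
    offset: Optional[float]     # ms, half-max crossing after peak
    class_: str                 # 'initial' | 'corrective' | 'rejected'
    reject_reason: Optional[str] = None
    trough_time: Optional[float] = None  # preceding speed trough, ms
    window: tuple[float, float] = field(default=None)

    def __post_init__(self):
        if self.window is None:
            self.window = (self.peak_time - SUBMOVEMENT_WINDOW_MS,
                           self.peak_time + SUBMOVEMENT_WINDOW_MS)

    @property
    def fwhm_ms(self) -> Optional[float]:
        if self.onset is None or self.offset is None:
            return None
        return self.offset - self.onset

    @property
    def accepted(self) -> bool:
        return self.class_ in ("initial", "corrective")


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------

_FIVE_POINT = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0


def _five_point_derivative(v: np.ndarray, dt_s: float) -> np.ndarray:
    """Five-point central difference; 2nd-order one-sided/central at edges."""
    n = len(v)
    d = np.empty(n)
    # interior: (v[i-2] - 8 v[i-1] + 8 v[i+1] - v[i+2]) / (12 dt)
    d[2:-2] = np.convolve(v, _FIVE_POINT[::-1], mode="valid") / dt_s
    d[0] = (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * dt_s)
    d[1] = (v[2] - v[0]) / (2.0 * dt_s)
    d[-2] = (v[-1] - v[-3]) / (2.0 * dt_s)
    d[-1] = (3.0 * v[-1] - 4.0 * v[-2] + v[-3]) / (2.0 * dt_s)
    return d


def compute_speed(trace: CursorTrace,
                  cutoff_hz: float = FILTER_CUTOFF_HZ) -> SpeedSeries:
    """Filtered cursor speed from a uniformly sampled trace.

    x and y are filtered independently with a first-order low-pass
    Butterworth (default 10 Hz), applied forward and backward for zero phase
    lag (reflect padding at the edges), then differentiated with the
    five-point central difference and combined as the Euclidean norm.
    """
    trace.validate_uniform()
    if len(trace.t) < 5:
        raise ValueError("need at least 5 samples to compute speed")
    dt_s = trace.dt_ms / 1000.0
    fs = 1.0 / dt_s
    b, a = _signal.butter(1, cutoff_hz, fs=fs)
    xf = _signal.filtfilt(b, a, trace.x, padtype="even")
    yf = _signal.filtfilt(b, a, trace.y, padtype="even")
    vx = _five_point_derivative(xf, dt_s)
    vy = _five_point_derivative(yf, dt_s)
    return SpeedSeries(t=trace.t.copy(), speed=np.hypot(vx, vy), vx=vx, vy=vy)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def find_speed_peaks(speed: SpeedSeries,
                     min_height: float = SPEED_THRESHOLD_PXPS,
                     prominence_frac: float = PROMINENCE_FRACTION):
    """Candidate submovement peaks passing height and prominence criteria.

    A local maximum qualifies if its speed exceeds ``min_height`` and its
    prominence (height above the larger of the two adjacent troughs, each
    trough being the minimum before encountering a larger sample) is at
    least ``prominence_frac`` of the absolute peak height. Plateau ties go
    to the earliest sample. Returns a list of dicts with keys
    ``index, time, height, prominence, window``.
    """
    s = np.asarray(speed.speed, dtype=float)
    idx, props = _signal.find_peaks(s, plateau_size=(None, None))
    if len(idx) == 0:
        return []
    # earliest sample of a plateau
    idx = props["left_edges"]
    prominences = _signal.peak_prominences(s, idx)[0]
    out = []
    for i, p in zip(idx, prominences):
        h = s[i]
        if h > min_height and p >= prominence_frac * h:
            t = float(speed.t[i])
            out.append({
                "index": int(i),
                "time": t,
                "height": float(h),
                "prominence": float(p),
                "window": (t - SUBMOVEMENT_WINDOW_MS,
                           t + SUBMOVEMENT_WINDOW_MS),
            })
    return out


def half_max_duration(speed: SpeedSeries, peak_index: int):
    """Half-maximum crossings flanking a peak, by linear interpolation.

    Returns ``(onset_ms, offset_ms, fwhm_ms)``; a crossing that is not found
    within the trace is returned as None (open-ended) and fwhm is then None.
    The nearest crossing on each side is used: the last sample below half
    height before the peak, the first after it.
    """
    s = speed.speed
    t = speed.t
    half = s[peak_index] / 2.0
    onset = offset = None
    for j in range(peak_index - 1, -1, -1):
        if s[j] < half:
            # crossing between j and j+1
            frac = (half - s[j]) / (s[j + 1] - s[j])
            onset = float(t[j] + frac * (t[j + 1] - t[j]))
            break
    for j in range(peak_index + 1, len(s)):
        if s[j] < half:
            frac = (half - s[j]) / (s[j - 1] - s[j])
            offset = float(t[j] - frac * (t[j] - t[j - 1]))
            break
    fwhm = (offset - onset) if (onset is not None and offset is not None) \
        else None
    return onset, offset, fwhm


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _position_at(trace: CursorTrace, t_ms: float) -> tuple[float, float]:
    x = float(np.interp(t_ms, trace.t, trace.x))
    y = float(np.interp(t_ms, trace.t, trace.y))
    return x, y


def classify_submovements(peaks, trace: CursorTrace, speed: SpeedSeries,
                          geometry: Optional[TargetGeometry] = None,
                          initial_min_distance: float = INITIAL_MIN_DISTANCE_PX
                          ) -> list[Submovement]:
    """Assign initial / corrective / rejected classes to candidate peaks.

    The initial submovement is the first peak whose movement end (cursor
    position at the half-max offset) lies at least ``initial_min_distance``
    px from the workspace center; earlier peaks are rejected as
    pre-initial. Each later peak is corrective if any sample of its
    acceleration phase — from the preceding speed trough to the peak — lies
    outside the peripheral target, otherwise rejected as within-target.
    Trials with no qualifying initial peak yield only rejected entries.
    """
    if geometry is None:
        geometry = trace.target
    subs: list[Submovement] = []
    initial_found = False
    prev_peak_index = None
    for pk in peaks:
        i = pk["index"]
        onset, offset, _ = half_max_duration(speed, i)
        trough_time = None
        if prev_peak_index is not None:
            seg = speed.speed[prev_peak_index:i + 1]
            trough_rel = int(np.argmin(seg))
            trough_time = float(speed.t[prev_peak_index + trough_rel])
        common = dict(trial_id=trace.trial_id, peak_time=pk["time"],
                      peak_index=i, peak_speed=pk["height"],
                      prominence=pk["prominence"], onset=onset, offset=offset,
                      trough_time=trough_time, window=pk["window"])
        if not initial_found:
            end_t = offset if offset is not None else pk["time"]
            ex, ey = _position_at(trace, end_t)
            dist = math.hypot(ex - WORKSPACE_CENTER[0],
                              ey - WORKSPACE_CENTER[1])
            if dist >= initial_min_distance:
                subs.append(Submovement(class_="initial", **common))
                initial_found = True
            else:
                subs.append(Submovement(class_="rejected",
                                        reject_reason="pre-initial", **common))
        else:
            t0 = trough_time if trough_time is not None else pk["time"]
            mask = (trace.t >= t0) & (trace.t <= pk["time"])
            outside = ~geometry.contains(trace.x[mask], trace.y[mask])
            if np.any(outside):
                subs.append(Submovement(class_="corrective", **common))
            else:
                subs.append(Submovement(
                    class_="rejected", reject_reason="within-target",
                    **common))
        prev_peak_index = i
    return subs


def segment_trial(trace: CursorTrace,
                  cutoff_hz: float = FILTER_CUTOFF_HZ,
                  min_height: float = SPEED_THRESHOLD_PXPS,
                  prominence_frac: float = PROMINENCE_FRACTION
                  ) -> tuple[SpeedSeries, list[Submovement]]:
    """Convenience: speed -> peaks -> classified submovements for one trial."""
    speed = compute_speed(trace, cutoff_hz=cutoff_hz)
    peaks = find_speed_peaks(speed, min_height=min_height,
                             prominence_frac=prominence_frac)
    return speed, classify_submovements(peaks, trace, speed)


# ---------------------------------------------------------------------------
# Profile comparisons
# ---------------------------------------------------------------------------

def profile_window(speed: SpeedSeries, peak_index: int,
                   window_ms: float = SUBMOVEMENT_WINDOW_MS) -> np.ndarray:
    """Speed samples in [-window, +window] around a peak (NaN-padded)."""
    k = int(round(window_ms / speed.dt_ms))
    out = np.full(2 * k + 1, np.nan)
    lo = peak_index - k
    hi = peak_index + k + 1
    src_lo = max(lo, 0)
    src_hi = min(hi, len(speed.speed))
    out[src_lo - lo:src_hi - lo] = speed.speed[src_lo:src_hi]
    return out


def profile_similarity(speed_a: SpeedSeries, peak_index_a: int,
                       speed_b: SpeedSeries, peak_index_b: int,
                       window_ms: float = SUBMOVEMENT_WINDOW_MS
                       ) -> Optional[float]:
    """Pearson correlation of two peak-aligned speed profiles.

    Profiles are the samples from -window to +window around each peak
    (41 samples at 100 Hz for the default 200-ms window). Returns None when
    either profile is incomplete or has zero variance.
    """
    pa = profile_window(speed_a, peak_index_a, window_ms)
    pb = profile_window(speed_b, peak_index_b, window_ms)
    if np.any(np.isnan(pa)) or np.any(np.isnan(pb)):
        return None
    if np.std(pa) == 0 or np.std(pb) == 0:
        return None
    return float(np.corrcoef(pa, pb)[0, 1])


def trough_peak_ratio(speed: SpeedSeries, sub_a: Submovement,
                      sub_b: Submovement) -> Optional[float]:
    """Minimum speed between two consecutive peaks over the first peak.

    Returns None when the interior minimum does not exist (merged bumps
    whose speed is monotone between the peak samples).
    """
    i, j = sub_a.peak_index, sub_b.peak_index
    if j <= i + 1:
        return None
    seg = speed.speed[i:j + 1]
    k = int(np.argmin(seg))
    if k == 0 or k == len(seg) - 1:
        return None
    return float(seg[k] / sub_a.peak_speed)
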