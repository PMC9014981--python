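"""Condition-independent rotational dynamics and the CI phase.

The population's condition-independent (CI) activity — the trial-averaged
firing-rate modulation common to all target conditions — is extracted by
averaging unit rates across submovements, reduced with PCA, and fitted with
a skew-symmetric linear dynamical system (jPCA) whose most-rotational
eigenplane defines the CI plane. The projections CIx / CIy are turned into
an instantaneous phase CIphi via the Hilbert transform: CIphi is the
circular mean of the analytic phase of CIx and of CIy + pi/2. Because
corrective submovements are not time-locked to trial events, the plane is
refined iteratively: average rates by CIphi bins instead of time, refit
jPCA on the phase-averaged trajectory, and repeat.

Conventions: +CIx points at the plane angle with the largest population
mean firing rate, and the rotation sign is fixed so CIphi increases on
average (CIy lags CIx by pi/2). One CIphi cycle accompanies each
submovement, with CIphi = 0 leading the speed peak by roughly the mean
unit lead time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal
from scipy import linalg as _linalg
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SpikeData",
    "RateMatrix",
    "CIPlane",
    "PhaseSeries",
    "bin_smooth_sqrt",
    "ci_average_by_event",
    "fit_jpca",
    "skew_symmetric_lstsq",
    "align_plane",
    "project_plane",
    "project_and_phase",
    "phase_average",
    "iterate_ciphase",
    "crossval_ciphase",
    "plane_angle_deg",
    "IterationResult",
    "CrossvalResult",
]

DEFAULT_BIN_MS = 10.0
DEFAULT_SMOOTH_SIGMA_MS = 30.0
DEFAULT_EVENT_WINDOW_MS = (-500.0, 300.0)
DEFAULT_N_PC = 6
DEFAULT_N_ITER = 3
DEFAULT_PHASE_BINS = 36
DEFAULT_ANGLE_BINS = 100  # alignment granularity, 3.6 deg


@dataclass
class SpikeData:
    """Spike times (ms on the session clock) for each recorded unit."""

    unit_ids: list
    spike_times: list           # one float array per unit, sorted, ms
    t_start_ms: float
    t_stop_ms: float

    def __post_init__(self):
        self.spike_times = [np.asarray(s, dtype=float)
                            for s in self.spike_times]
        if len(self.unit_ids) != len(self.spike_times):
            raise ValueError("unit_ids and spike_times length mismatch")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


@dataclass
class RateMatrix:
    """Smoothed firing rates, units x time bins (spikes/s)."""

    unit_ids: list
    bin_times: np.ndarray       # bin centers, ms
    rates: np.ndarray           # units x bins
    smoothed_sigma_ms: Optional[float] = None
    sqrt_transformed: bool = False

    def __post_init__(self):
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (len(self.unit_ids), len(self.bin_times)):
            raise ValueError("rates must be units x bins")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    @property
    def bin_ms(self) -> float:
        return float(self.bin_times[1] - self.bin_times[0])

    @property
    def n_bins(self) -> int:
        return len(self.bin_times)

    def raw_rates(self) -> np.ndarray:
        """Rates on the original spikes/s scale (undo the sqrt transform)."""
        return self.rates ** 2 if self.sqrt_transformed else self.rates

    def take_bins(self, index: np.ndarray) -> "RateMatrix":
        return RateMatrix(unit_ids=self.unit_ids,
                          bin_times=self.bin_times[index],
                          rates=self.rates[:, index],
                          smoothed_sigma_ms=self.smoothed_sigma_ms,
                          sqrt_transformed=self.sqrt_transformed)


def bin_smooth_sqrt(spikes: SpikeData, bin_ms: float = DEFAULT_BIN_MS,
                    sigma_ms: float = DEFAULT_SMOOTH_SIGMA_MS,
                    sqrt: bool = True) -> RateMatrix:
    """Bin spikes, smooth, and square-root transform.

    Spike counts in ``bin_ms`` bins are converted to spikes/s, smoothed with
    a Gaussian kernel (sigma in ms, truncated at +/-4 sigma, kernel mass
    renormalized; reflecting boundaries), then square-root transformed to
    equalize the variance of high- and low-rate units. Units with no spikes
    yield an all-zero row.
    """
    edges = np.arange(spikes.t_start_ms, spikes.t_stop_ms + bin_ms, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    rates = np.empty((spikes.n_units, len(centers)))
    scale = 1000.0 / bin_ms
    for i, st in enumerate(spikes.spike_times):
        counts, _ = np.histogram(st, bins=edges)
        rates[i] = counts * scale
    if sigma_ms and sigma_ms > 0:
        rates = gaussian_filter1d(rates, sigma=sigma_ms / bin_ms, axis=1,
                                  mode="reflect", truncate=4.0)
    if sqrt:
        rates = np.sqrt(np.maximum(rates, 0.0))
    return RateMatrix(unit_ids=list(spikes.unit_ids), bin_times=centers,
                      rates=rates, smoothed_sigma_ms=sigma_ms,
                      sqrt_transformed=sqrt)


def ci_average_by_event(rates: RateMatrix, event_times_ms,
                        window_ms=DEFAULT_EVENT_WINDOW_MS):
    """Event-triggered average of unit rates: the CI trajectory.

    Averages each unit's rate across all events (submovement speed peaks)
    at each lag in ``window_ms``, regardless of condition. Events whose
    window extends past the session edges are dropped.

    Returns ``(traj, lags_ms, n_used, n_dropped)`` with ``traj`` of shape
    units x window bins.
    """
    event_times_ms = np.asarray(event_times_ms, dtype=float)
    if event_times_ms.size == 0:
        raise ValueError("need at least one event")
    bin_ms = rates.bin_ms
    lo = int(round(window_ms[0] / bin_ms))
    hi = int(round(window_ms[1] / bin_ms))
    lags = np.arange(lo, hi + 1)
    centers = rates.bin_times
    idx = np.searchsorted(centers, event_times_ms)
    idx = np.clip(idx, 0, len(centers) - 1)
    ok = (idx + lo >= 0) & (idx + hi < rates.n_bins)
    used = idx[ok]
    if used.size == 0:
        raise ValueError("no events with a complete window inside the "
                         "session")
    traj = np.zeros((rates.rates.shape[0], len(lags)))
    for i in used:
        traj += rates.rates[:, i + lo:i + hi + 1]
    traj /= used.size
    return traj, lags * bin_ms, int(used.size), int((~ok).sum())


# ---------------------------------------------------------------------------
# jPCA
# ---------------------------------------------------------------------------

def skew_symmetric_lstsq(x: np.ndarray, xdot: np.ndarray) -> np.ndarray:
    """Least-squares skew-symmetric M minimizing ||xdot - M x||_F.

    Closed form via the stationarity condition M S + S M = C with
    S = x xT (symmetric) and C = xdot xT - x xdotT (skew), solved as a
    Sylvester equation. ``x`` and ``xdot`` are k x T.
    """
    s = x @ x.T
    c = xdot @ x.T - x @ xdot.T
    m = _linalg.solve_sylvester(s, s, c)
    return 0.5 * (m - m.T)


@dataclass
class CIPlane:
    """Fitted CI plane: PCA basis plus the most-rotational jPC plane."""

    unit_mean: np.ndarray       # units,
    pca_basis: np.ndarray       # units x k, orthonormal columns
    plane: np.ndarray           # k x 2 orthonormal columns (b_x, b_y)
    m_skew: np.ndarray          # k x k skew dynamics matrix (per second)
    eigvals: np.ndarray         # eigenvalues of m_skew
    rotation_hz: float          # |imag| of the plane's eigenvalue / 2 pi
    alignment_deg: Optional[float] = None
    sign_flipped: bool = False

    def basis_in_unit_space(self) -> np.ndarray:
        """units x 2 orthonormal basis of the CI plane in unit space."""
        b = self.pca_basis @ self.plane
        q, _ = np.linalg.qr(b)
        return q


def fit_jpca(traj: np.ndarray, n_pc: int = DEFAULT_N_PC,
             dt_s: float = DEFAULT_BIN_MS / 1000.0,
             periodic: bool = False) -> CIPlane:
    """Fit PCA + skew-symmetric dynamics; return the most-rotational plane.

    ``traj`` is units x time (or units x phase-bins with ``periodic=True``
    for trajectories indexed by a circular variable, where the finite
    difference wraps around). Columns are centered by the per-unit mean,
    projected on the top ``n_pc`` principal components, the derivative is
    estimated by central differences, and the skew-symmetric least-squares
    dynamics matrix is eigendecomposed; the plane spans the real and
    imaginary parts of the eigenvector pair with the largest |imag|.
    """
    traj = np.asarray(traj, dtype=float)
    n_units, n_t = traj.shape
    if n_t < 3:
        raise ValueError("need at least 3 time points")
    mean = traj.mean(axis=1)
    centered = traj - mean[:, None]
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0)
    rank = int((sv > tol).sum())
    k = min(n_pc, rank, n_units)
    if k < n_pc:
        warnings.warn(f"covariance rank {rank} < n_pc={n_pc}; "
                      f"using {k} components")
    if k < 2:
        raise ValueError("trajectory rank < 2; no plane to fit")
    basis = u[:, :k]
    x = basis.T @ centered                        # k x T
    if periodic:
        xdot = (np.roll(x, -1, axis=1) - np.roll(x, 1, axis=1)) / (2.0 * dt_s)
        xmid = x
    else:
        xdot = (x[:, 2:] - x[:, :-2]) / (2.0 * dt_s)
        xmid = x[:, 1:-1]
    m = skew_symmetric_lstsq(xmid, xdot)
    eigvals, eigvecs = np.linalg.eig(m)
    # every eigenplane of a skew matrix rotates; the CI plane is the one
    # holding the most rotational activity, i.e. the conjugate pair whose
    # 2-D invariant subspace captures the most trajectory variance (a
    # low-amplitude harmonic can spin faster, so |imag| alone misleads)
    order = np.argsort(-eigvals.imag)
    best_q, best_var, best_j = None, -1.0, 0
    seen = set()
    for j in order:
        w = eigvals[j].imag
        if w <= 0 or round(w, 12) in seen:
            continue
        seen.add(round(w, 12))
        v = eigvecs[:, j]
        q, _ = np.linalg.qr(np.column_stack([v.real, v.imag]))
        var = float(np.var(q.T @ x, axis=1).sum())
        if var > best_var:
            best_q, best_var, best_j = q, var, j
    if best_q is None:       # no rotational pair (k==2 degenerate); fall back
        v = eigvecs[:, 0]
        best_q, _ = np.linalg.qr(np.column_stack([v.real, v.imag]))
        best_j = 0
    q = best_q
    rotation_hz = abs(eigvals[best_j].imag) / (2.0 * math.pi)
    return CIPlane(unit_mean=mean, pca_basis=basis, plane=q, m_skew=m,
                   eigvals=eigvals, rotation_hz=rotation_hz)


def plane_angle_deg(plane_a: CIPlane, plane_b: CIPlane) -> float:
    """Largest principal angle (degrees) between two CI planes."""
    a = plane_a.basis_in_unit_space()
    b = plane_b.basis_in_unit_space()
    angles = _linalg.subspace_angles(a, b)
    return float(np.degrees(np.max(angles)))


# ---------------------------------------------------------------------------
# Alignment and phase
# ---------------------------------------------------------------------------

def project_plane(rates: RateMatrix, plane: CIPlane):
    """Project population rates onto the plane: returns (cix, ciy)."""
    centered = rates.rates - plane.unit_mean[:, None]
    x = plane.pca_basis.T @ centered
    proj = plane.plane.T @ x
    return proj[0], proj[1]


def align_plane(plane: CIPlane, rates: RateMatrix,
                n_angle_bins: int = DEFAULT_ANGLE_BINS) -> CIPlane:
    """Fix the plane's in-plane rotation and rotation-sign conventions.

    The rotation sign is set so the phase angle increases on average
    (counter-clockwise; CIy lags CIx by pi/2). Then the population-average
    firing rate (pre-sqrt mean across units) is binned by each sample's
    angle in the plane (default 100 bins of 3.6 degrees) and the axes are
    rotated so +CIx points at the bin with the largest average rate.
    """
    cix, ciy = project_plane(rates, plane)
    cix = cix - cix.mean()
    ciy = ciy - ciy.mean()
    b = plane.plane.copy()
    flipped = False
    ang = np.arctan2(ciy, cix)
    dphi = np.angle(np.exp(1j * np.diff(ang)))
    if np.mean(dphi) < 0:
        b = np.column_stack([b[:, 0], -b[:, 1]])
        ciy = -ciy
        ang = np.arctan2(ciy, cix)
        flipped = True

    pop_rate = rates.raw_rates().mean(axis=0)
    if np.ptp(pop_rate) < 1e-12:
        warnings.warn("population rate is constant; plane alignment "
                      "undefined, keeping identity")
        return CIPlane(unit_mean=plane.unit_mean, pca_basis=plane.pca_basis,
                       plane=b, m_skew=plane.m_skew, eigvals=plane.eigvals,
                       rotation_hz=plane.rotation_hz, alignment_deg=0.0,
                       sign_flipped=flipped)
    edges = np.linspace(-math.pi, math.pi, n_angle_bins + 1)
    which = np.clip(np.digitize(ang, edges) - 1, 0, n_angle_bins - 1)
    sums = np.bincount(which, weights=pop_rate, minlength=n_angle_bins)
    counts = np.bincount(which, minlength=n_angle_bins)
    means = np.full(n_angle_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    if not nz.all():
        # circular linear interpolation across empty bins
        centers = (edges[:-1] + edges[1:]) / 2.0
        means[~nz] = np.interp(centers[~nz],
                               np.concatenate([centers[nz] - 2 * math.pi,
                                               centers[nz],
                                               centers[nz] + 2 * math.pi]),
                               np.tile(means[nz], 3))
    alpha = float((edges[:-1] + edges[1:])[int(np.nanargmax(means))] / 2.0)
    ca, sa = math.cos(alpha), math.sin(alpha)
    rotated = np.column_stack([ca * b[:, 0] + sa * b[:, 1],
                               -sa * b[:, 0] + ca * b[:, 1]])
    return CIPlane(unit_mean=plane.unit_mean, pca_basis=plane.pca_basis,
                   plane=rotated, m_skew=plane.m_skew, eigvals=plane.eigvals,
                   rotation_hz=plane.rotation_hz,
                   alignment_deg=math.degrees(alpha), sign_flipped=flipped)


@dataclass
class PhaseSeries:
    """CIx/CIy projections and the instantaneous CI phase."""

    bin_times: np.ndarray
    cix: np.ndarray
    ciy: np.ndarray
    phi_x: np.ndarray
    phi_y: np.ndarray
    ci_phi: np.ndarray          # rad in (-pi, pi]; NaN where undefined
    fold: np.ndarray = None     # fold label per bin (-1: not cross-validated)

    def __post_init__(self):
        if self.fold is None:
            self.fold = np.full(len(self.bin_times), -1, dtype=int)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.ci_phi)


MIN_SEGMENT_BINS = 10
DEFAULT_TREND_SIGMA_MS = 400.0


def _segments_or_default(n_bins: int, segments) -> list:
    if segments is None:
        return [(0, n_bins)]
    return [(int(a), int(b)) for a, b in segments]


def project_and_phase(rates: RateMatrix, plane: CIPlane, segments=None,
                      trend_sigma_ms: Optional[float] =
                      DEFAULT_TREND_SIGMA_MS) -> PhaseSeries:
    """Project onto the CI plane and compute CIphi via Hilbert transform.

    ``segments`` is an optional list of ``(start, stop)`` bin-index ranges
    of contiguous recording (e.g. per trial); the analytic signal is
    computed independently per segment. Instantaneous phase from the
    analytic signal is only meaningful for a locally zero-mean signal, so
    each segment's slow trend — a Gaussian-smoothed copy with
    ``trend_sigma_ms`` (default 400 ms, about half a rotation cycle) — is
    subtracted first; with ``trend_sigma_ms=None`` only the segment mean
    is removed. Segments shorter than 10 bins get NaN phase. CIphi is the
    circular mean of phi_x and phi_y + pi/2.
    """
    cix_raw, ciy_raw = project_plane(rates, plane)
    n = rates.n_bins
    cix = np.full(n, np.nan)
    ciy = np.full(n, np.nan)
    phi_x = np.full(n, np.nan)
    phi_y = np.full(n, np.nan)
    ci_phi = np.full(n, np.nan)
    trend_bins = (trend_sigma_ms / rates.bin_ms
                  if trend_sigma_ms else None)
    for a, b in _segments_or_default(n, segments):
        if b - a < MIN_SEGMENT_BINS:
            continue
        if trend_bins:
            sx = cix_raw[a:b] - gaussian_filter1d(cix_raw[a:b], trend_bins,
                                                  mode="reflect")
            sy = ciy_raw[a:b] - gaussian_filter1d(ciy_raw[a:b], trend_bins,
                                                  mode="reflect")
        else:
            sx = cix_raw[a:b] - cix_raw[a:b].mean()
            sy = ciy_raw[a:b] - ciy_raw[a:b].mean()
        cix[a:b] = sx
        ciy[a:b] = sy
        px = np.angle(_signal.hilbert(sx))
        py = np.angle(_signal.hilbert(sy))
        phi_x[a:b] = px
        phi_y[a:b] = py
        ci_phi[a:b] = np.angle(np.exp(1j * px) + np.exp(1j * (py + np.pi / 2)))
    return PhaseSeries(bin_times=rates.bin_times.copy(), cix=cix, ciy=ciy,
                       phi_x=phi_x, phi_y=phi_y, ci_phi=ci_phi)


def phase_average(rates: RateMatrix, ci_phi: np.ndarray,
                  n_phase_bins: int = DEFAULT_PHASE_BINS) -> np.ndarray:
    """Occupancy-weighted mean unit rates in CIphi bins.

    Returns a units x n_phase_bins trajectory indexed by phase (a circular
    variable); empty bins are filled by circular linear interpolation.
    """
    valid = ~np.isnan(ci_phi)
    if valid.sum() < n_phase_bins:
        raise ValueError("too few valid phase samples to phase-average")
    edges = np.linspace(-math.pi, math.pi, n_phase_bins + 1)
    which = np.clip(np.digitize(ci_phi[valid], edges) - 1, 0,
                    n_phase_bins - 1)
    counts = np.bincount(which, minlength=n_phase_bins)
    traj = np.zeros((rates.rates.shape[0], n_phase_bins))
    r = rates.rates[:, valid]
    for b in range(n_phase_bins):
        if counts[b] > 0:
            traj[:, b] = r[:, which == b].mean(axis=1)
    if not (counts > 0).all():
        centers = (edges[:-1] + edges[1:]) / 2.0
        nz = counts > 0
        for i in range(traj.shape[0]):
            traj[i, ~nz] = np.interp(
                centers[~nz],
                np.concatenate([centers[nz] - 2 * math.pi, centers[nz],
                                centers[nz] + 2 * math.pi]),
                np.tile(traj[i, nz], 3))
    return traj


@dataclass
class IterationResult:
    plane: CIPlane
    phase: PhaseSeries
    plane_angles_deg: list      # principal angle between successive planes
    n_events_used: int


def iterate_ciphase(rates: RateMatrix, event_times_ms,
                    n_iter: int = DEFAULT_N_ITER,
                    n_phase_bins: int = DEFAULT_PHASE_BINS,
                    window_ms=DEFAULT_EVENT_WINDOW_MS,
                    n_pc: int = DEFAULT_N_PC,
                    n_angle_bins: int = DEFAULT_ANGLE_BINS,
                    segments=None) -> IterationResult:
    """Iterative CI-plane / CI-phase estimation.

    Iteration 0 fits jPCA on the event-aligned CI average (rates averaged
    across submovement speed peaks in ``window_ms``); each further
    iteration re-averages the unit rates within CIphi bins and refits jPCA
    on that phase-averaged trajectory. Three iterations are run by default
    to ensure convergence; the principal angle between successive planes is
    reported, with a warning if it grows (oscillating fit).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    traj, _, n_used, _ = ci_average_by_event(rates, event_times_ms,
                                             window_ms)
    plane = align_plane(fit_jpca(traj, n_pc=n_pc,
                                 dt_s=rates.bin_ms / 1000.0),
                        rates, n_angle_bins)
    phase = project_and_phase(rates, plane, segments)
    angles = []
    for _ in range(1, n_iter):
        traj = phase_average(rates, phase.ci_phi, n_phase_bins)
        new_plane = align_plane(fit_jpca(traj, n_pc=n_pc, periodic=True),
                                rates, n_angle_bins)
        angles.append(plane_angle_deg(plane, new_plane))
        plane = new_plane
        phase = project_and_phase(rates, plane, segments)
    if len(angles) >= 2 and angles[-1] > angles[-2] + 1.0:
        warnings.warn("CI plane principal angle increased between "
                      "iterations; returning last iterate")
    return IterationResult(plane=plane, phase=phase,
                           plane_angles_deg=angles, n_events_used=n_used)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossvalResult:
    phase: PhaseSeries          # test-set CIphi assembled across folds
    fold_planes: list           # CIPlane per fold
    fold_of_trial: dict         # trial_id -> fold index


def _trial_bin_ranges(rates: RateMatrix, trial_spans):
    """Map trial (t0, t1) spans in ms to (start, stop) bin-index ranges."""
    out = {}
    for trial_id, t0, t1 in trial_spans:
        a = int(np.searchsorted(rates.bin_times, t0, side="left"))
        b = int(np.searchsorted(rates.bin_times, t1, side="right"))
        out[trial_id] = (a, b)
    return out


def crossval_ciphase(rates: RateMatrix, trial_spans, event_times_ms,
                     event_trial_ids, k: int = 5, seed: int = 0,
                     **iter_kwargs) -> CrossvalResult:
    """K-fold cross-validated CI phase.

    Trials (``trial_spans``: iterable of ``(trial_id, t0_ms, t1_ms)``) are
    partitioned into ``k`` seeded folds. For each fold the CI plane is fit
    with :func:`iterate_ciphase` on the other k-1 folds' trials (each trial
    a contiguous Hilbert segment) and the held-out trials are projected
    into that plane; the test phases are assembled into one session-long
    PhaseSeries with per-bin fold labels.
    """
    trial_spans = list(trial_spans)
    trial_ids = [t[0] for t in trial_spans]
    if k < 2:
        raise ValueError("k must be >= 2 for cross-validation")
    if k > len(trial_ids):
        raise ValueError("k exceeds the number of trials")
    event_times_ms = np.asarray(event_times_ms, dtype=float)
    event_trial_ids = np.asarray(event_trial_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trial_ids))
    folds = [sorted(order[i::k]) for i in range(k)]
    ranges = _trial_bin_ranges(rates, trial_spans)

    n = rates.n_bins
    combined = PhaseSeries(bin_times=rates.bin_times.copy(),
                           cix=np.full(n, np.nan), ciy=np.full(n, np.nan),
                           phi_x=np.full(n, np.nan),
                           phi_y=np.full(n, np.nan),
                           ci_phi=np.full(n, np.nan),
                           fold=np.full(n, -1, dtype=int))
    fold_planes = []
    fold_of_trial = {}
    for f, test_idx in enumerate(folds):
        test_ids = {trial_ids[i] for i in test_idx}
        train_ids = [tid for tid in trial_ids if tid not in test_ids]
        for tid in test_ids:
            fold_of_trial[tid] = f
        # concatenated training rates, one segment per trial
        train_segments = []
        cols = []
        pos = 0
        for tid in train_ids:
            a, b = ranges[tid]
            cols.append(np.arange(a, b))
            train_segments.append((pos, pos + (b - a)))
            pos += b - a
        cols = np.concatenate(cols)
        train_rates = rates.take_bins(cols)
        train_mask = np.isin(event_trial_ids,
                             np.asarray(train_ids))
        res = iterate_ciphase(train_rates,
                              event_times_ms[train_mask],
                              segments=train_segments, **iter_kwargs)
        fold_planes.append(res.plane)
        # project held-out trials with the fold's plane
        test_segments = [ranges[tid] for tid in sorted(test_ids)]
        test_phase = project_and_phase(rates, res.plane,
                                       segments=test_segments)
        for a, b in test_segments:
            sl = slice(a, b)
            combined.cix[sl] = test_phase.cix[sl]
            combined.ciy[sl] = test_phase.ciy[sl]
            combined.phi_x[sl] = test_phase.phi_x[sl]
            combined.phi_y[sl] = test_phase.phi_y[sl]
            combined.ci_phi[sl] = test_phase.ci_phi[sl]
            combined.fold[sl] = f
    return CrossvalResult(phase=combined, fold_planes=fold_planes,
                          fold_of_trial=fold_of_trial)
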