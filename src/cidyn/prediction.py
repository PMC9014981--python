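"""Submovement-timing prediction: CI phase versus rate regression.

Two single-trial predictors of when a submovement's peak speed occurs are
compared. The dynamical-systems predictor uses the upward zero crossing of
CIphi; the comparator regresses peak speed on window-averaged unit firing
rates (one neural dimension, no per-unit lags) and uses the local peaks of
that weighted rate signal. Both are evaluated on the same submovements
within a -300 to +100 ms window around each speed peak: a submovement with
no prediction in the window is "unaligned"; the spread (SD) of aligned
offsets and the aligned fraction measure precision, compared with a
variance-ratio F test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .ci_dynamics import RateMatrix, PhaseSeries
from .circstats import circ_corr_cl

__all__ = [
    "EVAL_WINDOW_MS",
    "RateRegressionModel",
    "TimingEval",
    "FTestResult",
    "fit_rate_regression",
    "rate_model_predict_times",
    "ciphase_predict_times",
    "variance_ratio_test",
    "speed_phase_correlation",
    "session_speed_on_bins",
]

EVAL_WINDOW_MS = (-300.0, 100.0)


@dataclass
class RateRegressionModel:
    """OLS of submovement peak speed on window-averaged unit rates."""

    weights: np.ndarray
    intercept: float
    window_ms: tuple = EVAL_WINDOW_MS
    r2: float = float("nan")

    def signal(self, rates: RateMatrix) -> np.ndarray:
        """The 1-D weighted-rate signal over the session."""
        return self.weights @ rates.rates + self.intercept


def _window_mean_rates(rates: RateMatrix, peak_times_ms,
                       window_ms) -> np.ndarray:
    bt = rates.bin_times
    out = np.empty((len(peak_times_ms), rates.rates.shape[0]))
    for i, tp in enumerate(peak_times_ms):
        a = np.searchsorted(bt, tp + window_ms[0], side="left")
        b = np.searchsorted(bt, tp + window_ms[1], side="right")
        if b <= a:
            out[i] = np.nan
        else:
            out[i] = rates.rates[:, a:b].mean(axis=1)
    return out


def fit_rate_regression(rates: RateMatrix, submovements,
                        window_ms=EVAL_WINDOW_MS) -> RateRegressionModel:
    """Fit the firing-rate comparator model.

    Ordinary least squares of each submovement's peak speed on the per-unit
    firing rates averaged from 300 ms before to 100 ms after its speed
    peak. No per-unit time lags are fitted. Rank-deficient designs fall
    back to the minimum-norm solution with a warning.
    """
    subs = [s for s in submovements if s.accepted]
    if len(subs) < 2:
        raise ValueError("need at least 2 accepted submovements")
    peak_times = [s.peak_time for s in subs]
    y = np.array([s.peak_speed for s in subs])
    x = _window_mean_rates(rates, peak_times, window_ms)
    keep = ~np.isnan(x).any(axis=1)
    x, y = x[keep], y[keep]
    design = np.column_stack([x, np.ones(len(x))])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient regression design; "
                      "minimum-norm solution used")
    pred = design @ coef
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return RateRegressionModel(weights=coef[:-1], intercept=float(coef[-1]),
                               window_ms=tuple(window_ms), r2=r2)


@dataclass
class TimingEval:
    """Per-submovement predicted timing offsets for one model."""

    model: str
    offsets_ms: np.ndarray      # NaN where unaligned
    classes: np.ndarray         # 'initial' | 'corrective' per submovement

    @property
    def aligned(self) -> np.ndarray:
        return ~np.isnan(self.offsets_ms)

    def aligned_fraction(self, class_: Optional[str] = None) -> float:
        m = self._mask(class_)
        return float(self.aligned[m].mean()) if m.any() else float("nan")

    def sigma_ms(self, class_: Optional[str] = None) -> float:
        m = self._mask(class_) & self.aligned
        if m.sum() < 2:
            return float("nan")
        return float(np.std(self.offsets_ms[m], ddof=1))

    def offsets(self, class_: Optional[str] = None) -> np.ndarray:
        m = self._mask(class_) & self.aligned
        return self.offsets_ms[m]

    def _mask(self, class_):
        if class_ is None:
            return np.ones(len(self.offsets_ms), dtype=bool)
        return self.classes == class_


def _pick_offset(cand_offsets: np.ndarray) -> float:
    """Tie rule for several candidate predictions in the window:
    the latest candidate at or before the speed peak, else the earliest
    after it."""
    before = cand_offsets[cand_offsets <= 0]
    if before.size:
        return float(before.max())
    return float(cand_offsets.min())


def rate_model_predict_times(model: RateRegressionModel, rates: RateMatrix,
                             submovements,
                             window_ms=EVAL_WINDOW_MS) -> TimingEval:
    """Predict peak-speed times from peaks of the weighted rate signal.

    The prediction for each submovement is the time of a local maximum of
    the 1-D regression signal within ``window_ms`` of the speed peak; the
    maximum nearest the peak (latest before, else earliest after) is used
    when there are several, and submovements with none are unaligned.
    """
    subs = [s for s in submovements if s.accepted]
    sig = model.signal(rates)
    idx, props = _signal.find_peaks(sig, plateau_size=(None, None))
    peak_times = rates.bin_times[props["left_edges"]] if len(idx) else \
        np.empty(0)
    offsets = np.full(len(subs), np.nan)
    for i, s in enumerate(subs):
        rel = peak_times - s.peak_time
        cand = rel[(rel >= window_ms[0]) & (rel <= window_ms[1])]
        if cand.size:
            offsets[i] = _pick_offset(cand)
    return TimingEval(model="rate", offsets_ms=offsets,
                      classes=np.array([s.class_ for s in subs]))


def _upward_zero_crossings(t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Times where CIphi crosses 0 upward (wrap transitions excluded)."""
    a, b = phi[:-1], phi[1:]
    good = ~np.isnan(a) & ~np.isnan(b)
    cross = good & (a < 0) & (b >= 0) & ((b - a) < math.pi)
    i = np.nonzero(cross)[0]
    frac = -phi[i] / (phi[i + 1] - phi[i])
    return t[i] + frac * (t[i + 1] - t[i])


def ciphase_predict_times(phase: PhaseSeries, submovements,
                          window_ms=EVAL_WINDOW_MS) -> TimingEval:
    """Predict peak-speed times from CIphi = 0 upward crossings.

    Wrap-aware: jumps across +/-pi are not crossings. Several crossings in
    the window resolve to the one nearest the speed peak (latest before,
    else earliest after); none leaves the submovement unaligned.
    """
    subs = [s for s in submovements if s.accepted]
    crossings = _upward_zero_crossings(phase.bin_times, phase.ci_phi)
    offsets = np.full(len(subs), np.nan)
    for i, s in enumerate(subs):
        rel = crossings - s.peak_time
        cand = rel[(rel >= window_ms[0]) & (rel <= window_ms[1])]
        if cand.size:
            offsets[i] = _pick_offset(cand)
    return TimingEval(model="ciphase", offsets_ms=offsets,
                      classes=np.array([s.class_ for s in subs]))


@dataclass
class FTestResult:
    sigma1_ms: float
    sigma2_ms: float
    f: float
    dof: tuple
    p: float
    ci95: tuple


def variance_ratio_test(eval_a: TimingEval, eval_b: TimingEval,
                        class_: Optional[str] = None) -> FTestResult:
    """Two-sided F test on the ratio of aligned-offset variances.

    F = sigma_a^2 / sigma_b^2 with (n_a - 1, n_b - 1) degrees of freedom,
    assuming approximately normal offsets; the 95% confidence interval for
    the variance ratio is F / F_{0.975} .. F / F_{0.025}.
    """
    xa = eval_a.offsets(class_)
    xb = eval_b.offsets(class_)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 aligned offsets per model")
    s1 = float(np.std(xa, ddof=1))
    s2 = float(np.std(xb, ddof=1))
    f = (s1 / s2) ** 2
    d1, d2 = len(xa) - 1, len(xb) - 1
    cdf = _stats.f.cdf(f, d1, d2)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    ci = (f / _stats.f.ppf(0.975, d1, d2), f / _stats.f.ppf(0.025, d1, d2))
    return FTestResult(sigma1_ms=s1, sigma2_ms=s2, f=float(f), dof=(d1, d2),
                       p=p, ci95=(float(ci[0]), float(ci[1])))


@dataclass
class SpeedPhaseCorrelation:
    r: float
    p: float
    phase_of_max_speed: float   # rad
    n: int


def speed_phase_correlation(ci_phi: np.ndarray, speed: np.ndarray,
                            n_phase_bins: int = 36) -> SpeedPhaseCorrelation:
    """Circular-linear correlation between CIphi and cursor speed.

    Pairs with NaN in either variable are dropped. Also reports the phase
    bin with the largest mean speed.
    """
    ci_phi = np.asarray(ci_phi, dtype=float)
    speed = np.asarray(speed, dtype=float)
    ok = ~np.isnan(ci_phi) & ~np.isnan(speed)
    phi, s = ci_phi[ok], speed[ok]
    if phi.size < 3:
        raise ValueError("too few paired samples")
    r, p = circ_corr_cl(phi, s)
    edges = np.linspace(-math.pi, math.pi, n_phase_bins + 1)
    which = np.clip(np.digitize(phi, edges) - 1, 0, n_phase_bins - 1)
    sums = np.bincount(which, weights=s, minlength=n_phase_bins)
    counts = np.bincount(which, minlength=n_phase_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return SpeedPhaseCorrelation(r=r, p=p,
                                 phase_of_max_speed=float(
                                     centers[int(np.argmax(means))]),
                                 n=int(phi.size))


def session_speed_on_bins(traces, speeds, bin_times: np.ndarray
                          ) -> np.ndarray:
    """Interpolate per-trial filtered speed onto rate-matrix bin centers.

    Bins outside every trial's span are NaN. ``speeds`` are the
    :class:`~cidyn.kinematics.SpeedSeries` matching ``traces``.
    """
    out = np.full(len(bin_times), np.nan)
    for trace, sp in zip(traces, speeds):
        m = (bin_times >= sp.t[0]) & (bin_times <= sp.t[-1])
        out[m] = np.interp(bin_times[m], sp.t, sp.speed)
    return out
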