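"""Session file formats, pipeline configuration, and the end-to-end driver.

Sessions are stored as plain CSV + JSON in a directory:

* ``kinematics.csv`` — ``trial_id,t_ms,x_px,y_px`` (positions to 1e-3 px)
* ``targets.csv``    — ``trial_id,direction_deg,size_class``
* ``spikes.csv``     — ``unit_id,t_ms`` (times stored exactly)
* ``session.json``   — unit ids, session bounds, trial count
* ``ground_truth.json`` / ``config.json`` — simulator provenance, if any

All times are ms from session start; positions are pixels in the
1000 x 1000 workspace centered at (500, 500).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import kinematics as kin
from . import ci_dynamics as cid
from . import prediction as pred
from . import circstats as cs
from .synth import (SimConfig, Session, GroundTruth, GTSubmovement,
                    UnitParams, simulate_session)
from .kinematics import CursorTrace, TargetGeometry
from .ci_dynamics import SpikeData

__all__ = [
    "write_session",
    "read_session",
    "submovements_to_frame",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("cidyn")

KINEMATICS_COLUMNS = ["trial_id", "t_ms", "x_px", "y_px"]
TARGETS_COLUMNS = ["trial_id", "direction_deg", "size_class"]
SPIKES_COLUMNS = ["unit_id", "t_ms"]


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{fname}: missing required column '{c}'")


def write_session(session: Session, path) -> None:
    """Write a session to a directory of CSV/JSON files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    tgt_rows = []
    for tr in session.traces:
        rows.append(pd.DataFrame({
            "trial_id": tr.trial_id,
            "t_ms": tr.t,
            "x_px": np.round(tr.x, 3),
            "y_px": np.round(tr.y, 3),
        }))
        tgt_rows.append((tr.trial_id, tr.target.direction_deg,
                         tr.target.size_class))
    kin_df = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=KINEMATICS_COLUMNS))
    kin_df.to_csv(path / "kinematics.csv", index=False)
    pd.DataFrame(tgt_rows, columns=TARGETS_COLUMNS).to_csv(
        path / "targets.csv", index=False)

    sp = session.spikes
    sp_rows = []
    for uid, times in zip(sp.unit_ids, sp.spike_times):
        sp_rows.append(pd.DataFrame({"unit_id": uid, "t_ms": times}))
    sp_df = (pd.concat(sp_rows, ignore_index=True) if sp_rows
             else pd.DataFrame(columns=SPIKES_COLUMNS))
    sp_df.to_csv(path / "spikes.csv", index=False)

    meta = {
        "unit_ids": list(sp.unit_ids),
        "t_start_ms": sp.t_start_ms,
        "t_stop_ms": sp.t_stop_ms,
        "n_trials": len(session.traces),
        "duration_ms": session.duration_ms,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1,
                                                  sort_keys=True))
    if session.ground_truth is not None:
        gt = {
            "submovements": [asdict(s) for s in
                             session.ground_truth.submovements],
            "units": [asdict(u) for u in session.ground_truth.units],
        }
        (path / "ground_truth.json").write_text(
            json.dumps(gt, indent=1, sort_keys=True))
    if session.config is not None:
        (path / "config.json").write_text(
            json.dumps(asdict(session.config), indent=1, sort_keys=True))


def read_session(path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    kin_df = pd.read_csv(path / "kinematics.csv",
                         float_precision="round_trip")
    _require_columns(kin_df, KINEMATICS_COLUMNS, "kinematics.csv")
    tgt_df = pd.read_csv(path / "targets.csv")
    _require_columns(tgt_df, TARGETS_COLUMNS, "targets.csv")
    sp_df = pd.read_csv(path / "spikes.csv",
                        float_precision="round_trip")
    _require_columns(sp_df, SPIKES_COLUMNS, "spikes.csv")
    meta = json.loads((path / "session.json").read_text())

    targets = {int(r.trial_id): TargetGeometry(float(r.direction_deg),
                                               str(r.size_class))
               for r in tgt_df.itertuples()}
    traces = []
    for tid, g in kin_df.groupby("trial_id", sort=True):
        tid = int(tid)
        if tid not in targets:
            raise ValueError(f"targets.csv: no target for trial {tid}")
        traces.append(CursorTrace(trial_id=tid,
                                  t=g["t_ms"].to_numpy(float),
                                  x=g["x_px"].to_numpy(float),
                                  y=g["y_px"].to_numpy(float),
                                  target=targets[tid]))
    spikes_by_unit = {int(uid): g["t_ms"].to_numpy(float)
                      for uid, g in sp_df.groupby("unit_id", sort=True)}
    unit_ids = [int(u) for u in meta["unit_ids"]]
    spike_times = [np.sort(spikes_by_unit.get(u, np.empty(0)))
                   for u in unit_ids]
    spikes = SpikeData(unit_ids=unit_ids, spike_times=spike_times,
                       t_start_ms=float(meta["t_start_ms"]),
                       t_stop_ms=float(meta["t_stop_ms"]))

    gt = None
    gt_path = path / "ground_truth.json"
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        gt = GroundTruth(
            submovements=[GTSubmovement(**s) for s in raw["submovements"]],
            units=[UnitParams(**u) for u in raw["units"]])
    config = None
    cfg_path = path / "config.json"
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        raw = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in raw.items()}
        config = SimConfig(**raw)
    return Session(traces=traces, spikes=spikes, ground_truth=gt,
                   config=config, duration_ms=float(meta["duration_ms"]))


def submovements_to_frame(submovements) -> pd.DataFrame:
    rows = [{
        "trial_id": s.trial_id,
        "class": s.class_,
        "peak_time_ms": s.peak_time,
        "peak_speed": s.peak_speed,
        "prominence": s.prominence,
        "onset_ms": s.onset if s.onset is not None else np.nan,
        "offset_ms": s.offset if s.offset is not None else np.nan,
        "reject_reason": s.reject_reason or "",
    } for s in submovements]
    return pd.DataFrame(rows, columns=["trial_id", "class", "peak_time_ms",
                                       "peak_speed", "prominence",
                                       "onset_ms", "offset_ms",
                                       "reject_reason"])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters: 10-Hz filter, 250 px/s threshold,
    50% prominence, 150-px initial rule, 30-ms smoothing, 6 PCs,
    3 iterations, 5 folds, -300..+100 ms evaluation window."""

    # kinematics
    filter_cutoff_hz: float = 10.0
    peak_threshold_pxps: float = 250.0
    prominence_fraction: float = 0.5
    initial_min_distance_px: float = 150.0
    # neural
    smooth_sigma_ms: float = 30.0
    bin_ms: float = 10.0
    n_pc: int = 6
    n_iter: int = 3
    n_angle_bins: int = 100
    n_phase_bins: int = 36
    k_folds: int = 5
    # evaluation
    eval_window_ms: tuple = (-300.0, 100.0)
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        sim_raw = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in sim_raw.items()}
        if "eval_window_ms" in raw:
            raw["eval_window_ms"] = tuple(raw["eval_window_ms"])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def segment_session(session: Session, cfg: PipelineConfig):
    """Segment every trial; returns (speeds, submovements) pooled lists."""
    speeds, subs = [], []
    for tr in session.traces:
        sp = kin.compute_speed(tr, cutoff_hz=cfg.filter_cutoff_hz)
        peaks = kin.find_speed_peaks(sp,
                                     min_height=cfg.peak_threshold_pxps,
                                     prominence_frac=cfg.prominence_fraction)
        subs.extend(kin.classify_submovements(
            peaks, tr, sp,
            initial_min_distance=cfg.initial_min_distance_px))
        speeds.append(sp)
    return speeds, subs


def _phase_at_times(phase: cid.PhaseSeries, times_ms) -> np.ndarray:
    idx = np.clip(np.searchsorted(phase.bin_times, times_ms),
                  0, len(phase.bin_times) - 1)
    return phase.ci_phi[idx]


def _angle_at_times(series_t, values, times_ms) -> np.ndarray:
    idx = np.clip(np.searchsorted(series_t, times_ms), 0, len(series_t) - 1)
    return values[idx]


def run_pipeline(cfg: PipelineConfig, out_dir=None,
                 session: Optional[Session] = None) -> dict:
    """Simulate (unless a session is given), segment, extract cross-validated
    CI phase, evaluate both timing models, and return a report dict.

    With ``out_dir`` set, writes session files, ``submovements.csv``,
    ``phase.csv``, ``plane.json`` and ``report.json``.
    """
    if session is None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        log.info("simulating session: %s", sim)
        session = simulate_session(sim)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_session(session, out / "session")

    # --- segment -----------------------------------------------------------
    speeds, subs = segment_session(session, cfg)
    accepted = [s for s in subs if s.accepted]
    if not accepted:
        raise RuntimeError("segment stage produced no accepted submovements")
    classes = np.array([s.class_ for s in accepted])
    fwhm = np.array([s.fwhm_ms for s in accepted
                     if s.fwhm_ms is not None], dtype=float)
    log.info("segment: %d accepted submovements (%d initial, %d corrective)",
             len(accepted), (classes == "initial").sum(),
             (classes == "corrective").sum())

    # --- CI phase (cross-validated) ---------------------------------------
    rates = cid.bin_smooth_sqrt(session.spikes, bin_ms=cfg.bin_ms,
                                sigma_ms=cfg.smooth_sigma_ms)
    rates_raw = cid.RateMatrix(unit_ids=rates.unit_ids,
                               bin_times=rates.bin_times,
                               rates=rates.raw_rates(),
                               smoothed_sigma_ms=rates.smoothed_sigma_ms,
                               sqrt_transformed=False)
    trial_spans = [(tr.trial_id, tr.t[0], tr.t[-1])
                   for tr in session.traces]
    event_times = np.array([s.peak_time for s in accepted])
    event_trials = np.array([s.trial_id for s in accepted])
    cv = cid.crossval_ciphase(rates, trial_spans, event_times, event_trials,
                              k=cfg.k_folds, seed=cfg.seed,
                              n_iter=cfg.n_iter,
                              n_phase_bins=cfg.n_phase_bins,
                              n_pc=cfg.n_pc,
                              n_angle_bins=cfg.n_angle_bins)
    phase = cv.phase

    # --- evaluate ----------------------------------------------------------
    eval_ci = pred.ciphase_predict_times(phase, accepted,
                                         window_ms=cfg.eval_window_ms)
    model = pred.fit_rate_regression(rates_raw, accepted,
                                     window_ms=cfg.eval_window_ms)
    eval_rate = pred.rate_model_predict_times(model, rates_raw, accepted,
                                              window_ms=cfg.eval_window_ms)
    speed_bins = pred.session_speed_on_bins(session.traces, speeds,
                                            rates.bin_times)
    corr = pred.speed_phase_correlation(phase.ci_phi, speed_bins,
                                        n_phase_bins=cfg.n_phase_bins)
    phi_at_peak = _phase_at_times(phase, event_times)
    phi_ok = ~np.isnan(phi_at_peak)
    rayleigh_z, rayleigh_p = cs.rayleigh_test(phi_at_peak[phi_ok])
    phi_summary = cs.circ_mean_sd(phi_at_peak[phi_ok])

    report = {
        "seed": cfg.seed,
        "n_trials": len(session.traces),
        "n_units": session.spikes.n_units,
        "segment": {
            "n_submovements": len(accepted),
            "n_initial": int((classes == "initial").sum()),
            "n_corrective": int((classes == "corrective").sum()),
            "n_rejected": len(subs) - len(accepted),
            "median_fwhm_ms": float(np.median(fwhm)) if fwhm.size else None,
        },
        "ci_phase": {
            "fold_rotation_hz": [p.rotation_hz for p in cv.fold_planes],
            "rayleigh_z_at_peak": rayleigh_z,
            "rayleigh_p_at_peak": rayleigh_p,
            "ci_phi_at_peak_mean_pi": phi_summary.mean_pi,
            "ci_phi_at_peak_sd_pi": phi_summary.sd_pi,
        },
        "evaluation": {
            "speed_phase_correlation_r": corr.r,
            "speed_phase_correlation_p": corr.p,
            "phase_of_max_speed_pi": corr.phase_of_max_speed / math.pi,
        },
    }
    for class_ in ("initial", "corrective"):
        ftest = pred.variance_ratio_test(eval_ci, eval_rate, class_)
        report["evaluation"][class_] = {
            "sigma_ciphase_ms": eval_ci.sigma_ms(class_),
            "sigma_rate_ms": eval_rate.sigma_ms(class_),
            "aligned_fraction_ciphase": eval_ci.aligned_fraction(class_),
            "aligned_fraction_rate": eval_rate.aligned_fraction(class_),
            "mean_offset_ciphase_ms": float(
                np.mean(eval_ci.offsets(class_))),
            "mean_offset_rate_ms": float(np.mean(eval_rate.offsets(class_))),
            "f_ratio": ftest.f,
            "f_p": ftest.p,
            "f_ci95": list(ftest.ci95),
        }

    if out is not None:
        submovements_to_frame(subs).to_csv(out / "submovements.csv",
                                           index=False)
        pd.DataFrame({
            "t_ms": phase.bin_times,
            "CIx": phase.cix, "CIy": phase.ciy,
            "phi_x": phase.phi_x, "phi_y": phase.phi_y,
            "ci_phi": phase.ci_phi, "fold": phase.fold,
        }).to_csv(out / "phase.csv", index=False)
        plane0 = cv.fold_planes[0]
        (out / "plane.json").write_text(json.dumps({
            "pca_basis": plane0.pca_basis.tolist(),
            "plane": plane0.plane.tolist(),
            "eigvals_imag": plane0.eigvals.imag.tolist(),
            "rotation_hz": plane0.rotation_hz,
            "alignment_deg": plane0.alignment_deg,
        }, indent=1, sort_keys=True))
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    return report
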