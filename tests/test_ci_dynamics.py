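"""jPCA, plane alignment, Hilbert CI phase and the iterative refinement."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from cidyn import ci_dynamics as cid
from cidyn.ci_dynamics import (SpikeData, RateMatrix, bin_smooth_sqrt,
                               ci_average_by_event, fit_jpca,
                               skew_symmetric_lstsq, align_plane,
                               project_and_phase, phase_average,
                               iterate_ciphase, crossval_ciphase,
                               plane_angle_deg, CIPlane)
from cidyn.synth import SimConfig, simulate_session


# ------------------------------------------------------------ rates

def test_empty_unit_gives_zero_row():
    sp = SpikeData(unit_ids=[0, 1], spike_times=[np.array([500.0]),
                                                 np.empty(0)],
                   t_start_ms=0.0, t_stop_ms=2000.0)
    rm = bin_smooth_sqrt(sp)
    assert np.all(rm.rates[1] == 0.0)
    assert rm.sqrt_transformed


def test_single_spike_kernel_mass_conserved():
    sp = SpikeData(unit_ids=[0], spike_times=[np.array([1000.0])],
                   t_start_ms=0.0, t_stop_ms=2000.0)
    rm = bin_smooth_sqrt(sp, sqrt=False)
    # one spike in one 10-ms bin = 100 spikes/s for one bin; smoothing
    # redistributes but conserves the mass
    assert rm.rates[0].sum() == pytest.approx(100.0, rel=1e-6)


def test_constant_rate_unit_recovers_rate():
    rng = np.random.default_rng(0)
    rate = 20.0
    dur = 200_000.0
    spikes = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur / 1000)))
    sp = SpikeData([0], [spikes], 0.0, dur)
    rm = bin_smooth_sqrt(sp, sqrt=False)
    se = math.sqrt(rate / (dur / 1000.0))
    assert abs(rm.rates[0].mean() - rate) < 3 * se


# ------------------------------------------------------------ CI average

def _ramp_rates(n_units=4, n_bins=400):
    t = np.arange(n_bins) * 10.0 + 5.0
    rates = np.vstack([np.sin(2 * np.pi * t / 800.0 + k)
                       for k in range(n_units)])
    return RateMatrix(list(range(n_units)), t, rates)


def test_identical_segments_average_to_segment():
    rm = _ramp_rates()
    # events every 800 ms: each segment of the periodic signal is identical
    events = np.arange(1000.0, 3000.0, 800.0)
    traj, lags, n_used, _ = ci_average_by_event(rm, events,
                                                window_ms=(-400, 390))
    single, _, _, _ = ci_average_by_event(rm, events[:1],
                                          window_ms=(-400, 390))
    assert n_used == len(events)
    assert np.allclose(traj, single, atol=1e-9)


def test_one_event_average_is_that_segment():
    rm = _ramp_rates()
    traj, lags, n_used, n_drop = ci_average_by_event(rm, [2000.0],
                                                     window_ms=(-100, 100))
    i = np.searchsorted(rm.bin_times, 2000.0)
    assert np.allclose(traj, rm.rates[:, i - 10:i + 11])


def test_edge_events_dropped_and_counted():
    rm = _ramp_rates()
    with pytest.raises(ValueError):
        ci_average_by_event(rm, [0.0], window_ms=(-500, 300))
    _, _, n_used, n_drop = ci_average_by_event(rm, [5.0, 2000.0],
                                               window_ms=(-500, 300))
    assert n_used == 1 and n_drop == 1


# ------------------------------------------------------------ jPCA

def brute_force_skew_lstsq(x, xdot):
    """Design-matrix least squares over the skew-symmetric basis."""
    k, t = x.shape
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    a = np.zeros((k * t, len(pairs)))
    for p, (i, j) in enumerate(pairs):
        a[i * t:(i + 1) * t, p] = x[j]
        a[j * t:(j + 1) * t, p] = -x[i]
    b = xdot.reshape(-1)
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    m = np.zeros((k, k))
    for p, (i, j) in enumerate(pairs):
        m[i, j] = coef[p]
        m[j, i] = -coef[p]
    return m


def test_skew_lstsq_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(50):
        k = int(rng.integers(4, 7))
        t = int(rng.integers(20, 60))
        x = rng.normal(size=(k, t))
        xdot = rng.normal(size=(k, t))
        m_closed = skew_symmetric_lstsq(x, xdot)
        m_brute = brute_force_skew_lstsq(x, xdot)
        assert np.allclose(m_closed, m_brute,
                           atol=1e-6 * max(1.0, np.abs(m_brute).max()))


def test_skew_lstsq_matches_numerical_minimization():
    rng = np.random.default_rng(11)
    for _ in range(5):
        k, t = 4, 30
        x = rng.normal(size=(k, t))
        xdot = rng.normal(size=(k, t))
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]

        def unpack(m_vec):
            m = np.zeros((k, k))
            for p, (i, j) in enumerate(pairs):
                m[i, j] = m_vec[p]
                m[j, i] = -m_vec[p]
            return m

        def fun(m_vec):
            r = xdot - unpack(m_vec) @ x
            return 0.5 * float((r * r).sum())

        def jac(m_vec):
            r = xdot - unpack(m_vec) @ x
            g = -r @ x.T
            return np.array([g[i, j] - g[j, i] for (i, j) in pairs])

        res = minimize(fun, np.zeros(len(pairs)), jac=jac, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        m_opt = unpack(res.x)
        m_closed = skew_symmetric_lstsq(x, xdot)
        scale = max(1.0, np.abs(m_opt).max())
        assert np.allclose(m_closed, m_opt, atol=1e-6 * scale)


def test_exact_skew_model_recovered():
    rng = np.random.default_rng(3)
    k = 5
    a = rng.normal(size=(k, k))
    m0 = a - a.T
    x = rng.normal(size=(k, 40))
    m = skew_symmetric_lstsq(x, m0 @ x)
    assert np.allclose(m, m0, atol=1e-9)


def planted_rotation(rng, n_units=20, omega_hz=1.5, t_n=400, dt_s=0.005,
                     noise=1e-3):
    t = np.arange(t_n) * dt_s
    latent = np.vstack([np.cos(2 * np.pi * omega_hz * t),
                        np.sin(2 * np.pi * omega_hz * t)])
    e = np.linalg.qr(rng.normal(size=(n_units, 2)))[0]
    traj = 5.0 * e @ latent + noise * rng.normal(size=(n_units, t_n))
    return traj, e, omega_hz


def test_planted_rotation_recovered():
    rng = np.random.default_rng(2)
    for _ in range(10):
        traj, e, omega = planted_rotation(rng)
        plane = fit_jpca(traj, dt_s=0.005)
        got = plane.basis_in_unit_space()
        from scipy.linalg import subspace_angles
        ang = np.degrees(subspace_angles(got, e)).max()
        assert ang < 5.0
        assert plane.rotation_hz == pytest.approx(omega, rel=0.02)


def test_jpca_properties_and_rank_warning():
    rng = np.random.default_rng(1)
    traj, _, _ = planted_rotation(rng, n_units=10)
    plane = fit_jpca(traj)
    b = plane.plane
    assert np.allclose(b.T @ b, np.eye(2), atol=1e-9)
    assert np.allclose(plane.m_skew, -plane.m_skew.T, atol=1e-9)
    assert np.allclose(plane.eigvals.real, 0.0, atol=1e-8)
    # rank-2 data cannot support 6 PCs
    with pytest.warns(UserWarning, match="rank"):
        fit_jpca(5.0 * np.linalg.qr(rng.normal(size=(10, 2)))[0]
                 @ np.vstack([np.cos(np.arange(100) * 0.1),
                              np.sin(np.arange(100) * 0.1)]), n_pc=6)


# ------------------------------------------------------------ alignment

def _plane_for(rates, events):
    traj, *_ = ci_average_by_event(rates, events, window_ms=(-400, 300))
    return fit_jpca(traj, dt_s=rates.bin_ms / 1000.0)


def _rotation_session(phase_offset=0.0, n_units=12, omega_hz=1.25,
                      dur_ms=60_000.0, seed=0, amp=6.0):
    """Population whose summed rate peaks at a known plane angle."""
    rng = np.random.default_rng(seed)
    t = np.arange(5.0, dur_ms, 10.0)
    w = 2 * np.pi * omega_hz / 1000.0
    phases = np.linspace(0, 2 * np.pi, n_units, endpoint=False)
    rates = np.vstack([10.0 + amp * np.cos(w * t - ph + phase_offset)
                       for ph in phases])
    # make the summed rate peak once per cycle by boosting one unit
    rates[0] += 4.0 * np.cos(w * t + phase_offset)
    return RateMatrix(list(range(n_units)), t, rates)


def test_alignment_sign_convention_positive_phase_velocity():
    rm = _rotation_session()
    events = np.arange(2000.0, 50_000.0, 800.0)
    plane = align_plane(_plane_for(rm, events), rm)
    ph = project_and_phase(rm, plane)
    dphi = np.angle(np.exp(1j * np.diff(ph.ci_phi[200:-200])))
    assert np.nanmean(dphi) > 0


def test_alignment_puts_cix_at_max_rate_angle():
    rm = _rotation_session()
    events = np.arange(2000.0, 50_000.0, 800.0)
    plane = align_plane(_plane_for(rm, events), rm)
    cix, ciy = cid.project_plane(rm, plane)
    ang = np.arctan2(ciy, cix)
    pop = rm.rates.mean(axis=0)
    # population-rate maxima should sit near angle 0 (+CIx)
    peak_angles = ang[np.argsort(pop)[-500:]]
    mean_ang = np.angle(np.exp(1j * peak_angles).mean())
    assert abs(mean_ang) < 2 * np.pi / 25


def test_alignment_gauge_invariance():
    """An in-plane rotation of the starting basis does not change the
    aligned projections."""
    rm = _rotation_session()
    events = np.arange(2000.0, 50_000.0, 800.0)
    base = _plane_for(rm, events)
    th = 1.1
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    twisted = CIPlane(unit_mean=base.unit_mean, pca_basis=base.pca_basis,
                      plane=base.plane @ rot, m_skew=base.m_skew,
                      eigvals=base.eigvals, rotation_hz=base.rotation_hz)
    a = align_plane(base, rm)
    b = align_plane(twisted, rm)
    # same subspace, and the in-plane alignment agrees to one angle bin
    assert plane_angle_deg(a, b) < 1e-6
    g = a.plane.T @ b.plane          # in-plane rotation between the bases
    residual_angle = abs(math.atan2(g[1, 0], g[0, 0]))
    assert residual_angle <= 2 * np.pi / cid.DEFAULT_ANGLE_BINS + 1e-9


def test_constant_rates_alignment_warns_identity():
    rm = RateMatrix([0, 1, 2], np.arange(5.0, 3000.0, 10.0),
                    np.ones((3, 300)))
    plane = CIPlane(unit_mean=np.zeros(3),
                    pca_basis=np.eye(3)[:, :2], plane=np.eye(2),
                    m_skew=np.zeros((2, 2)), eigvals=np.zeros(2),
                    rotation_hz=0.0)
    with pytest.warns(UserWarning, match="alignment"):
        align_plane(plane, rm)


# ------------------------------------------------------------ phase

def _sinusoid_phase(omega_hz=1.5, dur_s=20.0):
    t = np.arange(0, dur_s * 1000, 10.0)
    w = 2 * np.pi * omega_hz / 1000.0
    rates = np.vstack([np.cos(w * t), np.sin(w * t)])
    rm = RateMatrix([0, 1], t + 5.0, rates)
    plane = CIPlane(unit_mean=np.zeros(2), pca_basis=np.eye(2),
                    plane=np.eye(2), m_skew=np.zeros((2, 2)),
                    eigvals=np.zeros(2), rotation_hz=omega_hz)
    return project_and_phase(rm, plane), t, w


def test_phase_of_pure_rotation_is_omega_t():
    ph, t, w = _sinusoid_phase()
    expected = np.angle(np.exp(1j * w * t))
    interior = slice(100, -100)
    err = np.abs(np.angle(np.exp(1j * (ph.ci_phi[interior]
                                       - expected[interior]))))
    assert err.max() < 0.05


def test_equal_component_phases_average_exactly():
    ph, t, w = _sinusoid_phase()
    interior = slice(100, -100)
    shifted = np.angle(np.exp(1j * (ph.phi_y[interior] + np.pi / 2)))
    gap = np.abs(np.angle(np.exp(1j * (ph.phi_x[interior] - shifted))))
    # quadrature pair: the two phase estimates agree closely, and the
    # circular mean sits between them (equals them where they coincide)
    assert np.median(gap) < 0.01
    dev = np.abs(np.angle(np.exp(1j * (ph.ci_phi[interior]
                                       - ph.phi_x[interior]))))
    assert np.all(dev <= gap / 2 + 1e-9)


def test_short_segment_phase_missing():
    ph, t, w = _sinusoid_phase()
    rm = RateMatrix([0, 1], t + 5.0,
                    np.vstack([np.cos(w * t), np.sin(w * t)]))
    plane = CIPlane(unit_mean=np.zeros(2), pca_basis=np.eye(2),
                    plane=np.eye(2), m_skew=np.zeros((2, 2)),
                    eigvals=np.zeros(2), rotation_hz=1.5)
    out = project_and_phase(rm, plane, segments=[(0, 5), (5, 300)])
    assert np.all(np.isnan(out.ci_phi[:5]))
    assert not np.any(np.isnan(out.ci_phi[5:300]))


# ------------------------------------------------------------ iteration

@pytest.fixture(scope="module")
def sim_rates():
    cfg = SimConfig(n_trials=120, seed=19)
    session = simulate_session(cfg)
    rates = bin_smooth_sqrt(session.spikes)
    spans = [(tr.trial_id, tr.t[0], tr.t[-1]) for tr in session.traces]
    segs = [(int(np.searchsorted(rates.bin_times, a)),
             int(np.searchsorted(rates.bin_times, b, side="right")))
            for _, a, b in spans]
    events = np.array([g.peak_time_ms
                       for g in session.ground_truth.submovements])
    trials = np.array([g.trial_id
                       for g in session.ground_truth.submovements])
    return session, rates, spans, segs, events, trials


def test_iteration_converges_on_phase_organized_data(sim_rates):
    _, rates, _, segs, events, _ = sim_rates
    res = iterate_ciphase(rates, events, segments=segs)
    assert res.plane_angles_deg[-1] < 2.0


def test_single_iteration_is_event_aligned_jpca(sim_rates):
    _, rates, _, segs, events, _ = sim_rates
    res = iterate_ciphase(rates, events, n_iter=1, segments=segs)
    traj, *_ = ci_average_by_event(rates, events)
    direct = align_plane(fit_jpca(traj, dt_s=rates.bin_ms / 1000.0), rates)
    assert plane_angle_deg(res.plane, direct) < 1e-6
    assert res.plane_angles_deg == []


def test_unit_permutation_leaves_ciphi_invariant(sim_rates):
    _, rates, _, segs, events, _ = sim_rates
    rng = np.random.default_rng(0)
    perm = rng.permutation(rates.rates.shape[0])
    shuffled = RateMatrix([rates.unit_ids[i] for i in perm],
                          rates.bin_times, rates.rates[perm],
                          sqrt_transformed=rates.sqrt_transformed)
    a = iterate_ciphase(rates, events, n_iter=2, segments=segs)
    b = iterate_ciphase(shuffled, events, n_iter=2, segments=segs)
    ok = ~np.isnan(a.phase.ci_phi)
    diff = np.angle(np.exp(1j * (a.phase.ci_phi[ok] - b.phase.ci_phi[ok])))
    assert np.abs(diff).max() < 1e-6


def test_phase_average_shape_and_interpolation():
    rng = np.random.default_rng(0)
    rm = _rotation_session()
    phi = np.linspace(-np.pi, np.pi, rm.n_bins, endpoint=False)
    traj = phase_average(rm, phi, n_phase_bins=24)
    assert traj.shape == (rm.rates.shape[0], 24)
    # leave some bins empty: phases confined to half the circle
    phi_half = np.abs(phi) / 2.0 - np.pi / 2
    traj2 = phase_average(rm, phi_half, n_phase_bins=24)
    assert np.all(np.isfinite(traj2))


# ------------------------------------------------------------ crossval

def test_crossval_k_bounds(sim_rates):
    _, rates, spans, _, events, trials = sim_rates
    with pytest.raises(ValueError, match="k must be"):
        crossval_ciphase(rates, spans, events, trials, k=1)
    with pytest.raises(ValueError, match="exceeds"):
        crossval_ciphase(rates, spans[:3], events, trials, k=5)


def test_crossval_generalizes(sim_rates):
    """Held-out CIphi concentration at true peaks is close to in-sample."""
    _, rates, spans, segs, events, trials = sim_rates
    cv = crossval_ciphase(rates, spans, events, trials, k=5, seed=0)
    ins = iterate_ciphase(rates, events, segments=segs)

    def r_at_peaks(phase):
        idx = np.searchsorted(phase.bin_times, events)
        phi = phase.ci_phi[np.clip(idx, 0, len(phase.bin_times) - 1)]
        phi = phi[~np.isnan(phi)]
        return np.abs(np.exp(1j * phi).mean())

    r_cv = r_at_peaks(cv.phase)
    r_in = r_at_peaks(ins.phase)
    assert r_cv > 0.5
    assert abs(r_cv - r_in) / r_in < 0.10
    assert set(cv.fold_of_trial.values()) == set(range(5))
    # every trial bin got a fold label
    for a, b in segs:
        assert np.all(cv.phase.fold[a:b] >= 0)
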