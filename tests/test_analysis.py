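"""Derived quantities: peak refinement, Tafel round trips, utilization,
mediator curves, sensing calibration."""

import numpy as np
import pytest

import p2dvolt as pv
from p2dvolt.simulate import StateHistory, Voltammogram


def _synthetic_vgram(E, j, kind="synthetic", scan_rate=0.05, c_surface=None):
    t = (E[0] - E) / scan_rate
    zeros = np.zeros_like(E)
    return Voltammogram(t=t, E=E, j_total=j, j_mediated=j, j_direct=zeros,
                        direction=np.ones(E.size, dtype=int), kind=kind,
                        scan_rate=scan_rate, c_surface=c_surface)


def test_peak_refinement_on_exact_parabola():
    E = np.arange(0.2, -1.2, -0.001)
    j = (E + 0.5) ** 2 - 1.0
    E_pk, j_pk = pv.find_cathodic_peak(_synthetic_vgram(E, j))
    assert E_pk == pytest.approx(-0.5, abs=1e-6)
    assert j_pk == pytest.approx(-1.0, abs=1e-9)


def test_peak_error_on_monotone_trace():
    E = np.arange(0.2, -1.2, -0.001)
    with pytest.raises(pv.PeakNotFoundError):
        pv.find_cathodic_peak(_synthetic_vgram(E, np.zeros_like(E)))
    with pytest.raises(pv.PeakNotFoundError):
        pv.find_cathodic_peak(_synthetic_vgram(E, -(0.2 - E)))


@pytest.mark.parametrize("alpha", [0.3, 0.5, 0.64, 0.8])
def test_tafel_round_trip_on_exact_cathodic_samples(params, alpha):
    # Noiseless interfacial Butler-Volmer samples: the regression recovers
    # alpha to 4 decimals, the slope to 0.1% and the rate constant exactly.
    p = params.with_overrides(alpha=alpha)
    k_true = 7.3e-5
    E = np.arange(0.2, -1.2, -0.001)
    eta = E - p.E_eq
    j = -(p.n_electrons * p.F * k_true * p.C_bulk
          * np.exp(-alpha * p.f_thermal * eta))
    fit = pv.tafel_analysis(_synthetic_vgram(E, j, kind="bare"), p)
    assert fit.alpha_est == pytest.approx(alpha, abs=1e-4)
    assert fit.slope == pytest.approx(pv.tafel_slope_mv_per_decade(p),
                                      rel=1e-3)
    assert fit.k0_eff == pytest.approx(k_true, rel=1e-6)
    assert fit.r_squared > 1 - 1e-10


def test_tafel_window_errors(params):
    E = np.arange(0.2, -1.2, -0.3)  # far too few samples in the window
    j = -np.exp(-(E - params.E_eq))
    with pytest.raises(ValueError, match="window"):
        pv.tafel_analysis(_synthetic_vgram(E, j, kind="bare"), params)
    with pytest.raises(ValueError, match="window_low"):
        pv.tafel_analysis(_synthetic_vgram(E, j, kind="bare"), params,
                          window_low=0.2, window_high=0.1)


def _constant_history(theta_value, rate_fields=None, nr=11):
    r = np.linspace(0.0, 2e-7, nr)
    times = np.array([0.0, 1.0, 2.0])
    E = np.array([0.0, -0.35, -0.7])
    theta = np.full((3, nr), theta_value)
    C_s = np.ones((3, nr))
    return StateHistory(times=times, E=E, direction=np.ones(3, dtype=int),
                        x_nodes=np.linspace(0, 1e-4, 5),
                        r_nodes=r, C_e=np.ones((3, 5)), C_s=C_s, theta=theta)


def test_mean_curves_average_constants_exactly(params):
    hist = _constant_history(0.3)
    E, th = pv.mean_theta_curve(hist)
    assert np.allclose(th, 0.3)
    E, rate = pv.mean_rate_curve(hist, params)
    assert np.allclose(rate, params.a_v * params.k0 * 1.0 * 0.3)
    # Linearity of the averaging operator.
    h2 = _constant_history(0.6)
    _, th2 = pv.mean_theta_curve(h2)
    assert np.allclose(th2, 2 * th)


def test_mediator_state_thresholds_on_baseline(baseline_cv):
    _, hist = baseline_cv
    E, th = pv.mean_theta_curve(hist)
    low = (E >= -0.4) & (E <= -0.3)
    high = np.abs(E + 0.8) < 0.02
    assert th[low].max() < 0.2
    assert th[high].mean() > 0.8
    assert np.all((th >= 0.0) & (th <= 1.0))


@pytest.mark.parametrize("phi", [0.3, 1.0, 3.0])
def test_utilization_matches_thiele_effectiveness(params, phi):
    # Frozen-mediator linear kinetics: utilization equals tanh(phi)/phi.
    delta = phi / np.sqrt(params.a_v * params.k0 * params.theta0
                          / params.D_eff)
    curve = pv.utilization_vs_thickness(params, [delta], E_hold=-0.9,
                                        mediator_dynamic=False,
                                        nx=300, nr=80)
    assert curve.utilization[0] == pytest.approx(
        pv.thiele_effectiveness(phi), rel=0.01)


def test_utilization_monotone_and_thin_layer_limit(params):
    thicknesses = [1e-8, 2e-7, 1e-6, 3e-6]
    curve = pv.utilization_vs_thickness(params, thicknesses, E_hold=-0.9,
                                        nx=300, nr=60)
    assert curve.utilization[0] > 0.99            # no internal gradient
    assert np.all(np.diff(curve.utilization) < 0)  # thicker, less utilized


def test_surface_transient_trivial_plateau():
    hist = _constant_history(0.5)
    times, trace, plateau, t_plateau = pv.surface_concentration_transient(hist)
    assert plateau == 1.0 and t_plateau == times[0]
    assert np.allclose(trace, 1.0)


def test_concentration_calibration_deterministic_and_linear(params):
    conc = [7e-3, 5e-2, 1e-1, 2.5e-1, 5e-1, 9.8e-1]
    a = pv.concentration_calibration(params, conc, noise_sigma=6e-3, seed=11,
                                     nx=150, nr=30)
    b = pv.concentration_calibration(params, conc, noise_sigma=6e-3, seed=11,
                                     nx=150, nr=30)
    assert np.array_equal(a.peak_currents, b.peak_currents)
    assert a.lod == b.lod and a.linear_range == b.linear_range
    clean = pv.concentration_calibration(params, conc, noise_sigma=0.0,
                                         nx=150, nr=30)
    assert clean.r_squared > 1 - 1e-6
    assert clean.linear_range == (conc[0], conc[-1])
    with pytest.raises(ValueError, match="decades"):
        pv.concentration_calibration(params, [0.1, 0.2, 0.3, 0.4, 0.5])


def test_scan_rate_study_contracts(params):
    same = pv.scan_rate_study(params, [0.05, 0.05, 0.05], nx=120, nr=24)
    assert np.ptp(same["peak_currents"]) == 0.0  # determinism
    study = pv.scan_rate_study(params, [0.02, 0.08, 0.3], nx=120, nr=24)
    assert np.all(np.diff(study["peak_currents"]) > 0)
    with pytest.raises(ValueError):
        pv.scan_rate_study(params, [0.05])
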