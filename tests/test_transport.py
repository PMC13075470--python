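"""Finite-volume operators: conservation, boundary handling, Thiele oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import p2dvolt as pv
from p2dvolt.oracles import thiele_profile


def test_equilibrium_profiles_have_zero_rates(params):
    xg, rg = pv.build_grids(params, 60, 40)
    C_e = np.full(xg.n_nodes, params.C_bulk)
    assert np.allclose(pv.electrolyte_rhs(C_e, 0.0, params, xg), 0.0)
    C_s = np.full(rg.n_nodes, params.C_bulk)
    theta = np.zeros(rg.n_nodes)
    rates = pv.porous_rhs(C_s, theta, params.C_bulk, params, rg)
    assert np.allclose(rates, 0.0)


def test_linear_profile_interior_rates_vanish(params):
    xg, _ = pv.build_grids(params, 80, 40)
    C_e = params.C_bulk * xg.nodes / params.L_e
    rates = pv.electrolyte_rhs(C_e, 0.0, params, xg)
    assert np.allclose(rates[1:-1], 0.0, atol=1e-8)


def test_discrete_mass_conservation_without_reaction(params):
    # Sum of (rate x cell volume) must equal boundary influx minus the
    # interface sink, to round-off.
    rng = np.random.default_rng(3)
    xg, _ = pv.build_grids(params, 120, 40)
    C_e = params.C_bulk * (0.5 + 0.5 * rng.random(xg.n_nodes))
    C_e[-1] = params.C_bulk
    sink = 2.3e-7
    rates = pv.electrolyte_rhs(C_e, sink, params, xg)
    vol = xg.cell_volumes()
    influx = params.D_mtz * (C_e[-1] - C_e[-2]) / xg.spacing[-1]
    # Dirichlet node excluded: its half cell absorbs the boundary flux.
    total = float(np.sum(rates[:-1] * vol[:-1]))
    assert total == pytest.approx(influx - sink, rel=1e-10)


@pytest.mark.parametrize("phi", [0.3, 1.0, 3.0])
def test_porous_steady_state_matches_thiele_profile(params, phi):
    # Frozen uniform theta; thickness chosen so the Thiele modulus is phi.
    theta0 = 0.5
    delta = phi / np.sqrt(params.a_v * params.k0 * theta0 / params.D_eff)
    p = params.with_overrides(delta_coox=float(delta))
    _, rg = pv.build_grids(p, 16, 400)
    theta = np.full(rg.n_nodes, theta0)
    C_b = 0.8 * p.C_bulk

    def rhs(t, y):
        return pv.porous_rhs(y, theta, C_b, p, rg)

    # Relax to steady state (several diffusion times).
    t_diff = p.porosity * delta ** 2 / p.D_eff
    sol = solve_ivp(rhs, (0.0, 50.0 * t_diff), np.full(rg.n_nodes, C_b),
                    method="BDF", rtol=1e-8, atol=1e-12)
    C_ss = sol.y[:, -1]
    C_ss[-1] = C_b
    expected = thiele_profile(rg.nodes, delta, phi, C_b)
    assert np.max(np.abs(C_ss - expected)) / C_b < 0.01

    # At quasi-steady state the interface flux balances the integrated
    # reaction rate (the stated flux-balance closure).
    xg, _ = pv.build_grids(p, 16, 400)
    C_e = np.full(xg.n_nodes, C_b)
    flux = pv.interface_flux(C_e, C_ss, p, (xg, rg))
    reacted = np.trapezoid(p.a_v * p.k0 * C_ss * theta, rg.nodes)
    assert flux == pytest.approx(reacted, rel=0.01)
    assert flux > 0  # analyte moves into the layer


def test_interface_flux_flat_profiles_and_continuity_guard(params):
    xg, rg = pv.build_grids(params, 20, 20)
    C_e = np.full(xg.n_nodes, params.C_bulk)
    C_s = np.full(rg.n_nodes, params.C_bulk)
    assert pv.interface_flux(C_e, C_s, params, (xg, rg)) == 0.0
    C_s_bad = C_s.copy()
    C_s_bad[-1] = 0.5 * params.C_bulk
    with pytest.raises(RuntimeError, match="continuity"):
        pv.interface_flux(C_e, C_s_bad, params, (xg, rg))


def test_deeper_deficit_with_slower_effective_diffusion(params):
    # Halving D_eff (via porosity) deepens the substrate-side concentration
    # deficit at fixed reaction strength.
    def substrate_deficit(porosity):
        p = params.with_overrides(porosity=porosity)
        phi = p.delta_coox * np.sqrt(p.a_v * p.k0 * 0.5 / p.D_eff)
        return 1.0 - float(thiele_profile(0.0, p.delta_coox, phi, 1.0))

    assert substrate_deficit(0.2) > substrate_deficit(0.4)


def test_surface_flux_matches_cottrell_decay(params):
    # Electrolyte PDE with the surface concentration clamped to zero: the
    # boundary flux must follow the classical diffusion-limited step law.
    xg, _ = pv.build_grids(params, 600, 40)

    def rhs(t, y):
        C = np.concatenate(([0.0], y, [params.C_bulk]))
        flux_in = params.D_mtz * (C[1] - C[0]) / xg.spacing[0]
        return pv.electrolyte_rhs(C, flux_in, params, xg)[1:-1]

    y0 = np.full(xg.n_nodes - 2, params.C_bulk)
    times = np.geomspace(0.1, 10.0, 25)
    sol = solve_ivp(rhs, (0.0, 10.0), y0, method="BDF", rtol=1e-7,
                    atol=1e-10, t_eval=times)
    for k, t in enumerate(times):
        C = np.concatenate(([0.0], sol.y[:, k], [params.C_bulk]))
        flux = params.D_mtz * (C[1] - C[0]) / xg.spacing[0]
        expected = params.C_bulk * np.sqrt(params.D_mtz / (np.pi * t))
        assert flux == pytest.approx(expected, rel=0.02)
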