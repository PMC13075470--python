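"""Local electrochemical source terms.

Pure functions of the local state: the Butler-Volmer interfacial current, the
mediator-activation linkage, the Co3+ coverage dynamics, the mediated
volumetric consumption rate and the Bruggeman effective diffusivity.

Sign convention: cathodic (reduction) current density is negative.  The
overall analyte reduction transfers ``n_electrons`` electrons but the
rate-determining step is a single electron transfer, so the Butler-Volmer
exponentials carry ``alpha*f*eta`` and ``(1-alpha)*f*eta`` with no factor n
(an n-electron exponent would give a ~23 mV/dec Tafel slope instead of the
observed ~92 mV/dec).

The mediation cycle is EC': the electrode drives the Co2+ -> Co3+ activation
step (electrochemical, E) at a rate ``k_ox`` that grows exponentially with
cathodic overpotential, and Co3+ transfers electrons to the analyte and is
regenerated as Co2+ (chemical, C) at a rate ``k_red * theta * C_s/C_bulk``.
The activation step carries its own exchange current density ``j0_med``
(a calibrated closure constant): the analyte interfacial exchange current
``j0`` is orders of magnitude too small to move the mediator population on a
voltammetric timescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "KineticRates",
    "butler_volmer_current",
    "k_ox_from_current",
    "mediator_activation_current",
    "mediator_rhs",
    "volumetric_rate",
    "effective_diffusivity",
    "tafel_slope_mv_per_decade",
]


#: Upper bound on the mediator activation rate, s^-1.  Above this the
#: coverage is slaved to its equilibrium on any resolvable timescale.
K_OX_CAP = 1.0e3


@dataclass(frozen=True)
class KineticRates:
    """Bundle of local rates at one point of the porous layer."""

    j_bv: float          # A m^-2, local Butler-Volmer current (cathodic < 0)
    k_ox: float          # s^-1, mediator activation rate
    r_vol: float         # mol m^-3 s^-1, mediated analyte consumption
    dtheta_dt: float     # s^-1, Co3+ coverage rate of change


def butler_volmer_current(E, C_local, params: ModelParameters):
    """Interfacial Butler-Volmer current density, A m^-2.

    j = j0 * [ -(C_local/C_bulk) * exp(-alpha f eta) + exp((1-alpha) f eta) ]

    with eta = E - E_eq and f = F/(R T).  The cathodic branch is scaled by
    local analyte availability; the anodic branch is unscaled because the
    reduction is irreversible and no oxidized analyte species is modelled.
    Accepts scalars or arrays (broadcast).
    """
    C_local = np.asarray(C_local, dtype=float)
    if np.any(C_local < 0):
        raise ValueError("C_local must be non-negative")
    eta = np.asarray(E, dtype=float) - params.E_eq
    f = params.f_thermal
    a = params.alpha
    j = params.j0 * (-(C_local / params.C_bulk) * np.exp(-a * f * eta)
                     + np.exp((1.0 - a) * f * eta))
    return j if j.ndim else float(j)


def k_ox_from_current(j_bv, params: ModelParameters):
    """Mediator oxidation rate from a faradaic current density.

    k_ox = |j| / (n_eq8 * F * gamma_sites), s^-1.  Always non-negative.
    """
    j = np.asarray(j_bv, dtype=float)
    k = np.abs(j) / (params.n_eq8 * params.F * params.gamma_sites)
    return k if k.ndim else float(k)


def cathodic_partial_current(E, C_local, params: ModelParameters):
    """Reduction branch of the interfacial law: -j0 (C/C_bulk) e^{-alpha f eta}."""
    C_local = np.asarray(C_local, dtype=float)
    eta = np.asarray(E, dtype=float) - params.E_eq
    j = -params.j0 * (np.clip(C_local, 0.0, None) / params.C_bulk) \
        * np.exp(-params.alpha * params.f_thermal * eta)
    return j if j.ndim else float(j)


def mediator_activation_rate(E, C_s, params: ModelParameters):
    """Total Co2+ -> Co3+ activation rate k_ox, s^-1.

    Two contributions:

    * the current linkage ``|j_c| / (n_eq8 F Gamma)`` applied to the cathodic
      partial current of the interfacial Butler-Volmer law (the reduction
      pathway drives the electrochemical half-step of the EC' cycle), which
      carries the single-electron ``exp(-alpha f eta)`` potential dependence
      and gives the kinetically controlled branch its Tafel slope; and
    * a cooperative activation switch ``k_sw * exp(-alpha_sw f eta)`` with
      steepness ``alpha_sw >> alpha``, representing the sharp
      potential-driven activation of the oxide redox phase.  Its steepness is
      a design constant; its amplitude ``k_sw`` is a calibrated closure that
      positions the cathodic peak.
    """
    eta = np.asarray(E, dtype=float) - params.E_eq
    seed = k_ox_from_current(cathodic_partial_current(E, C_s, params), params)
    # Cap the switch rate: far past the activation threshold theta is pinned
    # at its equilibrium and larger rates only stiffen the system (and the
    # exponential would overflow deep in the cathodic window).
    log_sw = np.log(params.k_sw) - params.alpha_sw * params.f_thermal * eta
    switch = np.exp(np.minimum(log_sw, np.log(K_OX_CAP)))
    k = np.minimum(seed + switch, K_OX_CAP)
    return k if np.ndim(k) else float(k)


def mediator_rhs(theta, k_ox, C_s, params: ModelParameters):
    """d(theta)/dt of the Co3+ site fraction, s^-1.

    dtheta/dt = k_ox * (1 - theta) - k_red * theta * C_s / C_bulk

    The first term is the electrochemical activation, the second the chemical
    regeneration by analyte reduction (first order in theta and in the
    normalized local analyte concentration).  For non-negative rates the
    derivative is >= 0 at theta = 0 and <= 0 at theta = 1, confining theta
    to [0, 1].
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    C_s = np.asarray(C_s, dtype=float)
    d = (np.asarray(k_ox, dtype=float) * (1.0 - theta)
         - params.k_red * theta * C_s / params.C_bulk)
    return d if d.ndim else float(d)


def volumetric_rate(C_s, theta, params: ModelParameters):
    """Mediated volumetric analyte consumption, mol m^-3 s^-1.

    R_vol = a_v * k0 * C_s * theta.  The heterogeneous rate constant k0
    (m s^-1) acts on the internal catalytic area, so the specific area per
    volume a_v (m^-1) converts it to a volumetric rate.
    """
    C_s = np.asarray(C_s, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(C_s < 0):
        raise ValueError("C_s must be non-negative")
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    r = params.a_v * params.k0 * C_s * theta
    return r if r.ndim else float(r)


def effective_diffusivity(D: float, porosity: float) -> float:
    """Bruggeman relation D_eff = D * porosity**1.5."""
    if D <= 0:
        raise ValueError("D must be positive")
    if not 0.0 < porosity <= 1.0:
        raise ValueError("porosity must lie in (0, 1]")
    return D * porosity ** 1.5


def tafel_slope_mv_per_decade(params: ModelParameters) -> float:
    """Analytic cathodic Tafel slope 2.303 R T / (alpha F) in mV per decade."""
    return 1000.0 * np.log(10.0) * params.R_gas * params.T / (params.alpha * params.F)
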